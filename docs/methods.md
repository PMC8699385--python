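# Methods

## Model and assumptions

`stratdr` assumes that a heterogeneous disease cohort contains subgroups
that are (i) *clinically addressable* — expressible as a conjunction of
categorical clinical predicates — and (ii) *molecularly coherent* — their
patients share co-occurring gene dysregulation that is rare outside the
subgroup. Stage one finds such subgroups; stage two ranks drugs whose known
regulatory effects oppose the subgroup's dysregulation signature.

### Preprocessing

Expression values v (non-negative counts or normalised units) are
transformed to log2(v + pseudocount); pseudocount defaults to 1 so zero
counts map to 0. Regulation states are per-gene z-scores across the cohort
(sample standard deviation, n−1 denominator, configurable): UP if z > 1,
DOWN if z < −1, NORMAL otherwise. Both inequalities are strict; boundary
values are NORMAL, and zero-variance genes are NORMAL everywhere. The
published description of the down threshold ("z-score < 1") is read as
z < −1: the NORMAL band is explicitly "between 1 and −1", which would be
empty under the literal reading. Items are restricted to differentially
expressed genes with p < 0.05 and |log2FC| > 2; the differential analysis
itself (e.g. EdgeR tumour-vs-normal) is upstream of this package — only its
output table is consumed. Because z-scores are computed independently per
gene, computing them before or after DEG selection is equivalent; the
implementation discretises whatever matrix it is given.

### Contrast patterns

A pattern is a set of (gene, direction) items. With focus subgroup SG1 and
outer population SG2:

* support s₁ (s₂): fraction of SG1 (SG2) patients carrying every item;
* growth: max(s₁,s₂)/min(s₁,s₂), capped at `growth_cap` (default 100) when
  the minimum is 0 — the published setting confidence = 1 forces s₂ = 0 for
  every retained pattern, where the ratio is undefined, and a finite cap
  keeps J-value means finite. The cap exceeds any plausible growth
  threshold, so filtering is unaffected by its exact value;
* confidence: of all patients carrying the pattern, the fraction inside
  SG1 (the rule pattern → subgroup). The source work states only
  "confidence was 1"; rule confidence is the standard reading and the only
  one that makes that setting meaningful alongside growth.

Default thresholds are the published settings: s₁ > 0.70 (strict),
growth > 1.5 (strict), confidence ≥ 1. Enumeration is level-wise with
support-based pruning (support is anti-monotone in the item set). The
output is restricted to *closed* patterns — no enumerated strict superset
with the identical supporting-patient set — so each distinct patient
support set is reported once, by its maximal item sets; `pattern_set`
switches to `maximal` or `all`. Closedness is relative to the enumerated
family, i.e. to itemsets within `max_pattern_len` (default 3; raise it to
the item count for exact closedness, as the oracle-equivalence tests do).

### J-value

The quality of a subgroup's pattern set blends its own mean capped growth
Jorg with a cohort-wide prior, as a Bayesian average:

J = (T·Jorg + M·J̄avg) / (T + M)

J̄avg and M come from R randomly drawn single-predicate clinical subgroups
(default R = 30, seeded): J̄avg is the mean of their Jorg values (subgroups
with no retained pattern contribute a neutral Jorg of 1 — no contrast) and
M their mean patient count. The baseline depends only on the cohort and
thresholds, so it is drawn once per search and shared by all candidates.
T is the population-size preference; it defaults to the focus subgroup's
patient count, favouring larger subgroups at equal pattern contrast, and
can be fixed to a constant (e.g. for rare-disease studies). The original
description gives Jorg only through a typographically corrupted expression;
the arithmetic mean of pattern growth is the location statistic consistent
with the blend, and a sum variant is available for sensitivity analysis.

### Subgroup networks and NCS

Mapping a pattern-item set onto the knowledge graph induces a heterogeneous
network: the item genes plus their direct gene–gene interaction neighbours;
every pathway, biological process, cellular component, molecular function
and disease node adjacent to an *item* gene (neighbour genes do not
contribute their own memberships — a configurable 1-hop policy); and every
drug with at least one regulation edge to an item gene whose direction
opposes the item's (signature reversal; drugs with unlabelled edges never
match). The network contrast score between the focus network and the
outer-population network (mined from the complement with the same
thresholds, roles swapped) is

NCS = 1 − mean over entity types of Jaccard(E_type,focus, E_type,outer)

over all seven types by default; types empty on both sides are skipped, and
NCS = 0 when every type is skipped. NCS lies in [0,1], is symmetric, and is
0 for identical networks. SPCScore = J × NCS; subgroups with
SPCScore > 0 are retained ("statistical significance" of a subgroup is
operationalised as this retention criterion — no specific test is
prescribed by the method; a permutation test could be layered on top).

### Path-expansion search

Depth 1 evaluates every single predicate (the missing-value sentinel is
never a predicate); each depth keeps the top `beam_width` (default 5)
candidates by SPCScore; children extend a parent by one new variable and
survive only if viable and strictly better than a parent. Two design
choices matter and were made deliberately:

* **Pattern-less candidates stay expandable.** A subgroup that meets the
  size constraints but retains no pattern scores 0 and can never be
  reported, but it remains in the frontier (ties broken towards larger
  subgroups, then by definition order). Without this, a planted subgroup
  defined by two predicates would be unreachable whenever neither predicate
  alone carries a ≥70%-support pattern — the common case, since a single
  predicate dilutes the subgroup's items below threshold. A consequence of
  the strict-improvement rule is that at most one pattern-less level can be
  traversed: conjunctions needing two consecutive signal-free refinements
  are not reachable.
* **A child survives if it improves on *any* generating beam parent.**
  Comparing only against the first parent encountered lets one high-scoring
  coarse parent veto a refinement that another parent would admit.

Results are deduplicated by patient set (best score kept), filtered to
SPCScore > `spc_min` (default 0, exclusive) and at least `min_patients`
(default 20) patients, and sorted by score. The whole search is
deterministic given the seed. With a beam at least as wide as the candidate
set, the best retained score equals exhaustive evaluation of all predicate
conjunctions for definitions of up to two predicates (and in practice
deeper); this is asserted against a brute-force oracle on small cohorts.

### DScore drug ranking

Factors are computed exactly as defined in the README. Numerical and
interpretation choices:

* MGF averages over the five structural types; the gene–gene term excludes
  the gene from its own numerator while the denominator is the full network
  gene set (negligible for realistic networks, documented for exactness).
  Types absent from the network contribute 0.
* "Targeted" always means reversal-matched; a direction-agnostic mode
  exists for sensitivity analysis only.
* PA counts a pattern as targeted if the drug reverses at least one of its
  items (`pa_mode="any"`); requiring all items is available. A drug that
  partially disrupts a co-regulation still perturbs it.
* AGF is the sum of MGF over reversed genes (the defining formula is a
  sum; the accompanying prose also says "average", so a mean variant is
  exposed without endorsement).
* IDF defaults to KB-wide scope: nSⱼ counts every gene the drug regulates
  anywhere in the knowledge base. The defining text reads "genes targeted
  in that subgroup network", but the stated rationale — penalise drugs that
  broadly perturb human cells, reward subgroup-specific ones — requires the
  global count, and the literal reading would directly punish the
  subgroup coverage that GP rewards. The literal scope is available via
  `idf_scope="subgroup"`. Drugs with nSⱼ = 0 in scope cannot be scored and
  are skipped with a warning.
* Ties are broken by drug id; ranks run 1..K without gaps; ranking is
  invariant to input order.

## Synthetic data

The generator emulates the minimal statistical structure the method
assumes; defaults are the study conditions used throughout the tests:

| parameter | default | meaning |
|---|---|---|
| n_patients | 120 | cohort size (a ~1/8 scale of a TCGA-sized cohort) |
| clinical_vars | 4 vars, 4/5/3/2 categories | uniform categorical draws |
| planted_definition | 2 predicates | the hidden subgroup definition |
| planted_size | 25 designated (+chance satisfiers ≈ 30 total) | subgroup scale matching the reported 30–37-patient subgroups |
| n_genes | 30 | gene universe |
| planted_items | 3 (2 UP, 1 DOWN) | co-regulated signature |
| effect_size | 2.5 | z-shift of a dysregulated cell (log2 scale, sd units) |
| penetrance | 0.9 | probability a planted item appears in a member |
| background_item_rate | 0.05 | dysregulation rate elsewhere |
| deg_background_rate | 0.5 | share of non-planted genes passing DEG thresholds |
| planted_drug_fidelity | 1.0 | share of planted items the planted drug reverses |
| kb | 15 pathways, 10 BP, 8 CC, 8 MF, 5 diseases, 12 drugs, membership 0.15, gene–gene 0.08 | knowledge-graph density |

Clinical values are uniform except that the designated block satisfies the
planted definition; patients who satisfy it by chance are genuine members
(they receive the planted signal and are recorded in the emitted truth).
Expression is Gaussian with unit variance per gene on the log2 scale;
dysregulated cells (planted or background) carry a clean ±effect_size shift
with the independent noise suppressed, making penetrance the probability
that the *discretised* item appears — the z-threshold then detects a
shifted cell deterministically as long as the shifted fraction per gene
stays well below half the cohort (at 50% the gene's mean absorbs the shift
and detection fails; the defaults keep it near 25%). Raw values are emitted
as 2^log2 − 1 so the standard normalisation recovers the simulated scale.
The planted drug carries only reversal edges to the planted genes (high
IDF); decoys either regulate planted genes in the same direction (excluded
by signature reversal) or reverse one planted item while perturbing ~30% of
background genes (low GP and IDF).

What the generator does *not* model — and what passing tests therefore do
not show about real data: negative-binomial count noise and library-size
effects (irrelevant after z-discretisation), correlation structure beyond
the planted co-occurrence, clinical variables correlated with each other or
with unplanted expression, missing clinical values, and any real biological
content of the knowledge graph. Recovery rates measured here are upper
bounds for cohorts where the subgroup signal is weaker than 2.5 sd or where
clinical predicates only approximate the true subgroup boundary.

## Degenerate inputs and numerical notes

Empty DEG sets, empty item sets, whole-cohort subgroups and pattern-less
subgroups are signalled as non-viable (or rejected with messages), never
silently scored. All comparisons against published thresholds use the
strict/non-strict forms stated above; score equalities (OSM = PA + AGF,
DScore = OSM·IDF·GP, SPCScore = J·NCS) hold to 1e-9 and are asserted in the
tests. Every stochastic component (simulation, random-subgroup baseline)
draws from a `numpy` generator seeded from the caller's seed; identical
seeds give byte-identical files.

## Problem sizes used in the automated checks

Miner-vs-oracle equivalence uses 100 random 20-patient × 8-item instances
with exhaustive 2⁸ enumeration; search-vs-oracle uses 40-patient cohorts
with three 2–3-category variables (35 conjunctions); recovery experiments
use the synthetic defaults over 20 (subgroup) and 50 (drug) seeds. These
sizes give exact oracle comparisons and tight binomial estimates while the
full suite stays in the seconds range.
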
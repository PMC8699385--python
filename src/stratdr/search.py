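"""Beam (path-expansion) search for high-contrast clinical subgroups.

A candidate subgroup is a conjunction of clinical (variable = value)
predicates. Each viable candidate is scored by

    SPCScore = J-value * NCS

where the J-value summarises the contrast of the subgroup's gene expression
patterns (see :mod:`stratdr.mining`) and the network contrast score NCS
compares the heterogeneous networks induced by the subgroup and by the
outer population:

    NCS = 1 - mean over entity types of Jaccard(E_type_focus, E_type_outer)

The search proceeds depth by depth: depth 1 evaluates every single
predicate; each depth keeps the top ``beam_width`` candidates by SPCScore
(floating re-ranking); a child (parent + one new predicate) survives only
if it is viable and strictly improves on its parent's SPCScore
(inclusion/exclusion). Results are deduplicated by patient set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import MISSING
from .kb import NODE_TYPES, KnowledgeGraph, SubgroupNetwork, induce_subgroup_network
from .mining import (
    JValueConfig,
    MiningConfig,
    j_value,
    jorg,
    mine_contrast_patterns,
    pattern_from_dict,
    random_subgroup_baseline,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubgroupDefinition:
    """An ordered conjunction of (variable, category) predicates."""

    predicates: tuple

    def __post_init__(self) -> None:
        if not self.predicates:
            raise ValueError("a subgroup definition needs at least one predicate")
        variables = [v for v, _ in self.predicates]
        if len(set(variables)) != len(variables):
            raise ValueError("a variable may appear at most once in a definition")

    def mask(self, clinical: pd.DataFrame) -> np.ndarray:
        m = np.ones(len(clinical), dtype=bool)
        for var, val in self.predicates:
            m &= (clinical[var] == val).to_numpy()
        return m

    def extend(self, var: str, val: str) -> "SubgroupDefinition":
        return SubgroupDefinition(self.predicates + ((var, val),))

    @property
    def variables(self) -> set:
        return {v for v, _ in self.predicates}

    def label(self) -> str:
        return " & ".join(f"{v}={c}" for v, c in self.predicates)

    def sort_key(self) -> tuple:
        return tuple(self.predicates)


@dataclass
class SearchConfig:
    """Parameters of the path-expansion search."""

    beam_width: int = 5
    max_depth: int = 4
    min_patients: int = 20
    spc_min: float = 0.0
    mining: MiningConfig = field(default_factory=MiningConfig)
    jvalue: JValueConfig = field(default_factory=JValueConfig)
    ncs_types: tuple = NODE_TYPES
    reversal: str = "opposite"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beam_width < 1 or self.max_depth < 1 or self.min_patients < 1:
            raise ValueError("beam_width, max_depth and min_patients must be >= 1")


@dataclass
class SubgroupResult:
    definition: SubgroupDefinition
    patient_ids: frozenset
    patterns: list
    jorg: float
    j_value: float
    ncs: float
    spc_score: float
    network: SubgroupNetwork

    def to_dict(self) -> dict:
        return {
            "predicates": [list(p) for p in self.definition.predicates],
            "patient_ids": sorted(self.patient_ids),
            "patterns": [
                {
                    "items": str(p),
                    "s1": p.s1,
                    "s2": p.s2,
                    "growth": p.growth,
                    "confidence": p.confidence,
                }
                for p in self.patterns
            ],
            "jorg": self.jorg,
            "j_value": self.j_value,
            "ncs": self.ncs,
            "spc_score": self.spc_score,
        }


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

def ncs(focus: SubgroupNetwork, outer: SubgroupNetwork, types=NODE_TYPES) -> float:
    """Network contrast score: 1 - mean per-type Jaccard similarity.

    Types whose entity sets are empty in both networks are skipped; if every
    type is skipped the score is 0 (no network evidence of contrast).
    """
    if not types:
        raise ValueError("at least one entity type is required")
    jaccards = []
    for t in types:
        e1 = focus.entity_sets.get(t, set())
        e2 = outer.entity_sets.get(t, set())
        union = e1 | e2
        if not union:
            continue
        jaccards.append(len(e1 & e2) / len(union))
    if not jaccards:
        return 0.0
    return 1.0 - float(np.mean(jaccards))


def spc_score(j: float, ncs_value: float) -> float:
    """Subgroup contrast score: J-value * NCS."""
    return j * ncs_value


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _network_from_patterns(kb, patterns, reversal):
    items = set().union(*(p.items for p in patterns)) if patterns else set()
    items = {i for i in items if kb.has_node(i.gene, "Gene")}
    if not items:
        return SubgroupNetwork.empty()
    return induce_subgroup_network(kb, items, patterns, reversal=reversal)


def evaluate_subgroup(
    defn: SubgroupDefinition,
    clinical: pd.DataFrame,
    item_df: pd.DataFrame,
    kb: KnowledgeGraph,
    cfg: SearchConfig,
    baseline,
) -> SubgroupResult | None:
    """Score one candidate subgroup; ``None`` marks a non-viable candidate.

    Non-viable: fewer than ``min_patients`` patients, no outer patient, no
    retained contrast pattern, or no pattern gene present in the knowledge
    graph. ``baseline`` is the (random_jorgs, M) pair from
    :func:`stratdr.mining.random_subgroup_baseline`, computed once per
    cohort and shared by all candidates.
    """
    mask = defn.mask(clinical)
    ids = clinical.index[mask]
    if len(ids) < cfg.min_patients or len(ids) == len(clinical):
        return None
    focus_patterns = mine_contrast_patterns(item_df, ids, cfg.mining)
    if not focus_patterns:
        return None
    focus_nw = _network_from_patterns(kb, focus_patterns, cfg.reversal)
    if not focus_nw.gene_items:
        return None
    outer_ids = clinical.index[~mask]
    outer_patterns = mine_contrast_patterns(item_df, outer_ids, cfg.mining)
    outer_nw = _network_from_patterns(kb, outer_patterns, cfg.reversal)

    random_jorgs, M = baseline
    T = cfg.jvalue.T if cfg.jvalue.T is not None else float(len(ids))
    jv = j_value(focus_patterns, T, random_jorgs, M)
    ncs_value = ncs(focus_nw, outer_nw, cfg.ncs_types)
    return SubgroupResult(
        definition=defn,
        patient_ids=frozenset(ids),
        patterns=focus_patterns,
        jorg=jorg(focus_patterns),
        j_value=jv,
        ncs=ncs_value,
        spc_score=spc_score(jv, ncs_value),
        network=focus_nw,
    )


@dataclass(frozen=True)
class _Node:
    """Search-frontier entry: a candidate that may or may not carry patterns.

    Size-viable candidates without retained patterns score 0 (they can never
    be reported) but remain in the frontier so that their refinements are
    still reachable; ties are broken towards larger subgroups, then by
    definition order.
    """

    defn: SubgroupDefinition
    spc: float
    size: int
    result: SubgroupResult | None


def candidate_predicates(clinical: pd.DataFrame):
    """All (variable, category) predicates, missing sentinel excluded."""
    return [
        (var, val)
        for var in clinical.columns
        for val in sorted(clinical[var].unique())
        if val != MISSING
    ]


def path_expansion_search(
    clinical: pd.DataFrame,
    item_df: pd.DataFrame,
    kb: KnowledgeGraph,
    cfg: SearchConfig | None = None,
) -> list:
    """Beam search over predicate conjunctions, best subgroups first.

    Returns every retained :class:`SubgroupResult` with
    ``spc_score > cfg.spc_min``, deduplicated by patient set, sorted by
    SPCScore descending (ties broken by definition order). Deterministic
    given ``cfg.seed``.
    """
    cfg = cfg or SearchConfig()
    rng = np.random.default_rng(cfg.seed)
    baseline = random_subgroup_baseline(clinical, item_df, cfg.mining, cfg.jvalue, rng)
    logger.info(
        "random-subgroup baseline: mean Jorg %.3f, M %.1f",
        float(np.mean(baseline[0])), baseline[1],
    )

    def node(defn: SubgroupDefinition) -> _Node | None:
        n_sel = int(defn.mask(clinical).sum())
        if n_sel < cfg.min_patients or n_sel == len(clinical):
            return None
        res = evaluate_subgroup(defn, clinical, item_df, kb, cfg, baseline)
        return _Node(defn, res.spc_score if res else 0.0, n_sel, res)

    def top(nodes) -> list:
        return sorted(
            nodes, key=lambda nd: (-nd.spc, -nd.size, nd.defn.sort_key())
        )[: cfg.beam_width]

    # depth 1: every single predicate of adequate size enters the frontier;
    # candidates without retained patterns score 0 but stay expandable
    beam = top(
        nd
        for var, val in candidate_predicates(clinical)
        if (nd := node(SubgroupDefinition(((var, val),)))) is not None
    )
    retained = [nd.result for nd in beam if nd.result is not None]

    for depth in range(2, cfg.max_depth + 1):
        cache: dict[frozenset, _Node | None] = {}
        kept: dict[frozenset, _Node] = {}
        for parent in beam:
            for var, val in candidate_predicates(clinical):
                if var in parent.defn.variables:
                    continue
                key = frozenset(parent.defn.predicates + ((var, val),))
                if key not in cache:
                    cache[key] = node(parent.defn.extend(var, val))
                child = cache[key]
                # a child survives if it improves on ANY beam parent that
                # can generate it, not merely the first one encountered
                if child is not None and child.spc > parent.spc:
                    kept.setdefault(key, child)
        children = list(kept.values())
        if not children:
            break
        beam = top(children)
        retained.extend(nd.result for nd in beam if nd.result is not None)
        logger.info(
            "depth %d: beam best %.4f (%s)", depth, beam[0].spc, beam[0].defn.label()
        )

    # dedupe by patient set, keeping the best-scoring definition
    by_patients: dict[frozenset, SubgroupResult] = {}
    for res in sorted(retained, key=lambda r: (-r.spc_score, r.definition.sort_key())):
        by_patients.setdefault(res.patient_ids, res)
    results = [r for r in by_patients.values() if r.spc_score > cfg.spc_min]
    results.sort(key=lambda r: (-r.spc_score, r.definition.sort_key()))
    return results


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def write_results(results, path) -> None:
    payload = {
        "subgroups": {f"sg{r + 1:03d}": res.to_dict() for r, res in enumerate(results)}
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_results(path) -> dict:
    """Load a stratification JSON back into result-shaped dicts.

    Pattern entries are revived as :class:`stratdr.mining.Pattern`; the
    definition as :class:`SubgroupDefinition`.
    """
    with open(path) as fh:
        payload = json.load(fh)
    out = {}
    for sg_id, d in payload["subgroups"].items():
        out[sg_id] = {
            "definition": SubgroupDefinition(tuple(tuple(p) for p in d["predicates"])),
            "patient_ids": frozenset(d["patient_ids"]),
            "patterns": [pattern_from_dict(p) for p in d["patterns"]],
            "jorg": d["jorg"],
            "j_value": d["j_value"],
            "ncs": d["ncs"],
            "spc_score": d["spc_score"],
        }
    return out
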
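"""Synthetic cohorts and knowledge graphs with planted, recoverable structure.

The generator emulates the statistical structure the stratification method
assumes: a clinically defined patient subgroup carrying co-occurring gene
dysregulation, embedded in a cohort with independent background noise, and
a knowledge graph containing one drug that reverses the planted signature
plus decoy drugs that do not.

* Clinical variables are uniform categorical draws, except that a designated
  block of patients is set to satisfy the planted predicate conjunction.
  Any other patient that satisfies it by chance is a genuine subgroup
  member too; the emitted truth records the full satisfying set.
* Expression is Gaussian on the log2 scale (unit variance per gene).
  Planted items shift their gene by +/- ``effect_size`` in subgroup members
  with probability ``penetrance``; background dysregulation of the same
  magnitude occurs anywhere else at ``background_item_rate``. Values are
  emitted as raw non-negative units (2**log2 - 1) so the standard
  log2(v + 1) normalisation recovers the simulated scale.
* The planted drug carries regulation edges opposite to the planted item
  directions. Decoys come in two flavours: same-direction decoys (edges to
  planted genes with the *same* direction, so signature reversal excludes
  them) and promiscuous partial decoys (reverse a single planted item but
  perturb many background genes, attracting a low IDF).

Identical seeds produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import DOWN, UP, GeneItem
from .kb import (
    ANNOTATION_TYPES,
    DISEASE,
    DRUG,
    GENE,
    RELATION_ASSOCIATED,
    RELATION_INTERACTS,
    RELATION_MEMBER_OF,
    RELATION_REGULATES,
    KnowledgeGraph,
)
from .search import SubgroupDefinition

logger = logging.getLogger(__name__)

_ANNOTATION_PREFIX = {
    "Pathway": "PW",
    "BiologicalProcess": "BP",
    "CellularComponent": "CC",
    "MolecularFunction": "MF",
}


@dataclass(frozen=True)
class KBSimConfig:
    """Size and density of the simulated knowledge graph."""

    n_pathways: int = 15
    n_bp: int = 10
    n_cc: int = 8
    n_mf: int = 8
    n_diseases: int = 5
    n_drugs: int = 12
    membership_rate: float = 0.15
    gene_gene_rate: float = 0.08
    decoy_background_rate: float = 0.3


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the planted-structure benchmark.

    Defaults mirror a scaled-down heterogeneous tumour cohort: 120
    patients, a two-predicate planted subgroup of roughly 30, three
    co-regulated planted items with a 2.5-sd expression shift at 90%
    penetrance, 5% background dysregulation, and a knowledge graph with one
    fully faithful reversing drug among 12.
    """

    n_patients: int = 120
    clinical_vars: tuple = (
        ("neoplasm_subdivision", 4),
        ("race", 5),
        ("histology", 3),
        ("age_group", 2),
    )
    planted_definition: tuple = (
        ("neoplasm_subdivision", "cat0"),
        ("race", "cat0"),
    )
    planted_size: int = 25
    n_genes: int = 30
    planted_items: tuple = (("G001", UP), ("G002", DOWN), ("G003", UP))
    effect_size: float = 2.5
    penetrance: float = 0.9
    background_item_rate: float = 0.05
    deg_background_rate: float = 0.5
    planted_drug_fidelity: float = 1.0
    kb: KBSimConfig = field(default_factory=KBSimConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        var_names = {name for name, _ in self.clinical_vars}
        cats = {name: n for name, n in self.clinical_vars}
        for var, val in self.planted_definition:
            if var not in var_names:
                raise ValueError(f"planted variable {var!r} not among clinical_vars")
            if val not in {f"cat{i}" for i in range(cats[var])}:
                raise ValueError(f"planted category {val!r} out of range for {var!r}")
        genes = {f"G{i:03d}" for i in range(self.n_genes)}
        for g, d in self.planted_items:
            if g not in genes:
                raise ValueError(f"planted gene {g!r} outside the gene universe")
            if d not in (UP, DOWN):
                raise ValueError(f"bad planted direction {d!r}")
        for rate in (self.penetrance, self.background_item_rate,
                     self.planted_drug_fidelity, self.deg_background_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if not 2 <= self.planted_size <= self.n_patients - 2:
            raise ValueError("planted_size must leave >= 2 patients on each side")

    @property
    def items(self) -> tuple:
        return tuple(GeneItem(g, d) for g, d in self.planted_items)

    @property
    def definition(self) -> SubgroupDefinition:
        return SubgroupDefinition(tuple(self.planted_definition))


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside a simulated cohort."""

    subgroup_ids: tuple
    definition: SubgroupDefinition
    items: tuple
    drug_id: str
    decoy_ids: tuple

    def to_dict(self) -> dict:
        return {
            "subgroup_ids": list(self.subgroup_ids),
            "definition": [list(p) for p in self.definition.predicates],
            "items": [str(i) for i in self.items],
            "drug_id": self.drug_id,
            "decoy_ids": list(self.decoy_ids),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlantedTruth":
        return cls(
            subgroup_ids=tuple(d["subgroup_ids"]),
            definition=SubgroupDefinition(tuple(tuple(p) for p in d["definition"])),
            items=tuple(GeneItem.parse(t) for t in d["items"]),
            drug_id=d["drug_id"],
            decoy_ids=tuple(d["decoy_ids"]),
        )


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def simulate_cohort(cfg: SimulationConfig):
    """Generate (clinical, expression, deg_stats, truth) for one seed.

    Expression is genes x patients (raw non-negative units); clinical is
    patients x variables; deg_stats carries per-gene log2FC and p-values in
    which every planted gene passes the DEG thresholds and a
    ``deg_background_rate`` share of the remaining genes does too.
    """
    rng = np.random.default_rng(cfg.seed)
    patients = [f"P{i:03d}" for i in range(cfg.n_patients)]
    genes = [f"G{i:03d}" for i in range(cfg.n_genes)]

    # clinical table: uniform categories, planted block forced to match
    clinical = pd.DataFrame(index=pd.Index(patients, name="patient_id"))
    for name, k in cfg.clinical_vars:
        clinical[name] = [f"cat{j}" for j in rng.integers(0, k, size=cfg.n_patients)]
    designated = rng.choice(cfg.n_patients, size=cfg.planted_size, replace=False)
    for var, val in cfg.planted_definition:
        clinical.iloc[designated, clinical.columns.get_loc(var)] = val
    member_mask = cfg.definition.mask(clinical)
    subgroup_ids = tuple(clinical.index[member_mask])

    # expression: per-gene Gaussian baseline on the log2 scale. Dysregulated
    # cells carry a clean +/- effect_size shift (no independent noise) so the
    # penetrance is the probability the discretised item actually appears.
    mu = rng.uniform(3.0, 8.0, size=cfg.n_genes)
    noise = rng.normal(0.0, 1.0, size=(cfg.n_genes, cfg.n_patients))
    shift = np.zeros_like(noise)
    planted_rows = {g: genes.index(g) for g, _ in cfg.planted_items}
    member_idx = np.flatnonzero(member_mask)
    planted_cells = np.zeros(noise.shape, dtype=bool)
    for gene, direction in cfg.planted_items:
        row = planted_rows[gene]
        hit = member_idx[rng.random(len(member_idx)) < cfg.penetrance]
        sign = 1.0 if direction == UP else -1.0
        shift[row, hit] = sign * cfg.effect_size
        planted_cells[row, member_idx] = True
    background = (rng.random(noise.shape) < cfg.background_item_rate) & ~planted_cells
    signs = rng.choice([-1.0, 1.0], size=noise.shape)
    shift[background] = signs[background] * cfg.effect_size
    noise[shift != 0.0] = 0.0
    log_expr = mu[:, None] + noise + shift
    raw = np.maximum(np.exp2(log_expr) - 1.0, 0.0)
    expr = pd.DataFrame(raw, index=pd.Index(genes, name="gene_id"), columns=patients)

    # differential statistics: planted genes always pass the DEG thresholds
    lfc = rng.uniform(-1.5, 1.5, size=cfg.n_genes)
    pvals = rng.uniform(0.05, 1.0, size=cfg.n_genes)
    extra = rng.random(cfg.n_genes) < cfg.deg_background_rate
    lfc[extra] = rng.choice([-1.0, 1.0], size=int(extra.sum())) * rng.uniform(
        2.2, 4.0, size=int(extra.sum())
    )
    pvals[extra] = rng.uniform(1e-4, 0.04, size=int(extra.sum()))
    for gene, direction in cfg.planted_items:
        row = planted_rows[gene]
        lfc[row] = 3.0 if direction == UP else -3.0
        pvals[row] = 1e-5
    deg_stats = pd.DataFrame(
        {"log2fc": lfc, "pvalue": pvals}, index=pd.Index(genes, name="gene_id")
    )

    drugs = [f"D{i:03d}" for i in range(cfg.kb.n_drugs)]
    truth = PlantedTruth(
        subgroup_ids=subgroup_ids,
        definition=cfg.definition,
        items=cfg.items,
        drug_id=drugs[0],
        decoy_ids=tuple(drugs[1:]),
    )
    logger.info(
        "simulated cohort seed=%d: %d/%d subgroup members",
        cfg.seed, len(subgroup_ids), cfg.n_patients,
    )
    return clinical, expr, deg_stats, truth


# ---------------------------------------------------------------------------
# Knowledge graph
# ---------------------------------------------------------------------------

def simulate_kb(cfg: SimulationConfig, truth: PlantedTruth) -> KnowledgeGraph:
    """Generate the knowledge graph matching a simulated cohort."""
    rng = np.random.default_rng([cfg.seed, 7919])
    kb = KnowledgeGraph()
    genes = [f"G{i:03d}" for i in range(cfg.n_genes)]
    for g in genes:
        kb.add_node(g, GENE)

    counts = {
        "Pathway": cfg.kb.n_pathways,
        "BiologicalProcess": cfg.kb.n_bp,
        "CellularComponent": cfg.kb.n_cc,
        "MolecularFunction": cfg.kb.n_mf,
    }
    for t in ANNOTATION_TYPES:
        prefix = _ANNOTATION_PREFIX[t]
        for i in range(counts[t]):
            kb.add_node(f"{prefix}{i:03d}", t)
        hits = rng.random((cfg.n_genes, counts[t])) < cfg.kb.membership_rate
        for gi, ai in zip(*np.nonzero(hits)):
            kb.add_edge(genes[gi], GENE, RELATION_MEMBER_OF, f"{prefix}{ai:03d}", t)

    for i in range(cfg.kb.n_diseases):
        kb.add_node(f"DIS{i:03d}", DISEASE)
    hits = rng.random((cfg.n_genes, cfg.kb.n_diseases)) < cfg.kb.membership_rate
    for gi, di in zip(*np.nonzero(hits)):
        kb.add_edge(genes[gi], GENE, RELATION_ASSOCIATED, f"DIS{di:03d}", DISEASE)

    pairs = np.triu_indices(cfg.n_genes, k=1)
    link = rng.random(len(pairs[0])) < cfg.kb.gene_gene_rate
    for a, b in zip(pairs[0][link], pairs[1][link]):
        kb.add_edge(genes[a], GENE, RELATION_INTERACTS, genes[b], GENE)

    planted_genes = {i.gene for i in truth.items}
    opposite = {UP: DOWN, DOWN: UP}
    for d in (truth.drug_id,) + truth.decoy_ids:
        kb.add_node(d, DRUG)

    # planted drug: reversal edges for a fidelity share of the planted items
    n_rev = max(1, int(round(cfg.planted_drug_fidelity * len(truth.items))))
    for item in truth.items[:n_rev]:
        kb.add_edge(truth.drug_id, DRUG, RELATION_REGULATES, item.gene, GENE,
                    direction=opposite[item.direction])

    background_genes = [g for g in genes if g not in planted_genes]
    for j, d in enumerate(truth.decoy_ids):
        if j % 2 == 0:
            # same-direction decoy: regulates planted genes the wrong way round
            for item in truth.items:
                kb.add_edge(d, DRUG, RELATION_REGULATES, item.gene, GENE,
                            direction=item.direction)
        else:
            # promiscuous partial decoy: reverses one planted item, perturbs
            # a broad slice of background genes
            item = truth.items[j % len(truth.items)]
            kb.add_edge(d, DRUG, RELATION_REGULATES, item.gene, GENE,
                        direction=opposite[item.direction])
            n_bg = max(1, int(round(cfg.kb.decoy_background_rate * len(background_genes))))
            chosen = rng.choice(len(background_genes), size=n_bg, replace=False)
            for gi in sorted(chosen):
                kb.add_edge(d, DRUG, RELATION_REGULATES, background_genes[gi], GENE,
                            direction=str(rng.choice([UP, DOWN])))
    return kb


def planted_network(kb: KnowledgeGraph, truth: PlantedTruth, growth_cap: float = 100.0):
    """Induce the ground-truth subgroup network from the planted signature.

    The planted items form the network's gene items and the planted
    co-regulation is its single pattern (with the idealised statistics of
    the generative truth: exclusive to the subgroup, growth at the cap).
    Useful for evaluating the drug-ranking cascade independently of the
    mining stage.
    """
    from .kb import induce_subgroup_network
    from .mining import Pattern

    pattern = Pattern(
        items=frozenset(truth.items), s1=1.0, s2=0.0,
        growth=growth_cap, confidence=1.0,
    )
    return induce_subgroup_network(kb, truth.items, [pattern])


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def write_dataset(cfg: SimulationConfig, out_dir) -> dict:
    """Emit the full fixture set (cohort TSVs, KB TSVs, truth.json).

    Returns a name -> path mapping of the files written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    clinical, expr, deg_stats, truth = simulate_cohort(cfg)
    kb = simulate_kb(cfg, truth)
    paths = {
        "clinical": out / "clinical.tsv",
        "expression": out / "expression.tsv",
        "deg_stats": out / "deg_stats.tsv",
        "kb_nodes": out / "kb_nodes.tsv",
        "kb_edges": out / "kb_edges.tsv",
        "truth": out / "truth.json",
    }
    clinical.to_csv(paths["clinical"], sep="\t")
    expr.to_csv(paths["expression"], sep="\t", float_format="%.6f")
    deg_stats.to_csv(paths["deg_stats"], sep="\t", float_format="%.6g")
    kb.write(paths["kb_nodes"], paths["kb_edges"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
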
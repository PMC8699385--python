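"""DScore drug ranking over a subgroup network.

Every drug that entered a subgroup network (it reverses at least one of the
subgroup's dysregulated genes) is scored by a cascade of factors:

* MGF (mean gene frequency): a gene's weight, the mean over five entity
  types (Gene, Pathway, BiologicalProcess, CellularComponent,
  MolecularFunction) of the fraction of that type's network entities
  directly connected to the gene. Hub genes weigh more.
* AGF (accumulative gene frequency): sum of MGF over the genes the drug
  reverses in the subgroup.
* PA: fraction of the subgroup's patterns the drug targets.
* OSM = PA + AGF (overlap score measure).
* GP: fraction of the subgroup's dysregulated genes the drug reverses.
* IDF = log10(Ns / nS_j): inverse drug frequency, Ns the number of genes
  in the knowledge base, nS_j the number of genes the drug perturbs.
  TF-IDF-style: drugs that perturb broad swathes of the genome are
  penalised relative to subgroup-specific ones.
* DScore = OSM * IDF * GP; drugs are ranked by DScore descending.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass

from .kb import GENE, MGF_TYPES, KnowledgeGraph, SubgroupNetwork

logger = logging.getLogger(__name__)


class DrugNotScorable(ValueError):
    """The drug perturbs no gene in the chosen IDF scope."""


@dataclass(frozen=True)
class DrugScoreRecord:
    drug_id: str
    agf: float
    pa: float
    osm: float
    gp: float
    idf: float
    dscore: float
    rank: int
    reversed_genes: tuple


# ---------------------------------------------------------------------------
# Factors
# ---------------------------------------------------------------------------

def mgf(sgnw: SubgroupNetwork, kb: KnowledgeGraph, gene: str) -> float:
    """Mean gene frequency of ``gene`` within the subgroup network.

    For each of the five structural entity types, the fraction of that
    type's entities in the network directly connected to the gene; the
    gene-gene term excludes the gene from its own numerator while the
    denominator is the full network gene set. Types absent from the network
    contribute 0. Returns the mean over the five types.
    """
    if gene not in sgnw.entity_sets.get(GENE, set()):
        raise ValueError(f"gene {gene!r} is not in the subgroup network")
    terms = []
    for t in MGF_TYPES:
        members = sgnw.entity_sets.get(t, set())
        if not members:
            terms.append(0.0)
            continue
        connected = kb.neighbors_of_type(gene, GENE, t) & members
        connected.discard(gene)
        terms.append(len(connected) / len(members))
    return sum(terms) / len(MGF_TYPES)


def agf(sgnw: SubgroupNetwork, kb: KnowledgeGraph, drug: str) -> float:
    """Accumulative gene frequency: sum of MGF over the drug's reversed genes."""
    if drug not in sgnw.drug_targets:
        raise ValueError(f"drug {drug!r} is not in the subgroup network")
    return sum(mgf(sgnw, kb, g) for g in sorted(sgnw.reversed_genes(drug)))


def pa(sgnw: SubgroupNetwork, drug: str, mode: str = "any") -> float:
    """Fraction of subgroup patterns targeted by the drug.

    Under ``mode="any"`` (default) a pattern counts when the drug reverses
    at least one of its items; under ``"all"`` every item must be reversed.
    """
    if mode not in ("any", "all"):
        raise ValueError(f"unknown pattern-targeting mode {mode!r}")
    if not sgnw.patterns:
        raise ValueError("subgroup has no patterns")
    targets = sgnw.drug_targets.get(drug, frozenset())
    quant = any if mode == "any" else all
    hit = sum(1 for p in sgnw.patterns if quant(item in targets for item in p.items))
    return hit / len(sgnw.patterns)


def osm(pa_value: float, agf_value: float) -> float:
    """Overlap score measure: PA + AGF."""
    return pa_value + agf_value


def gp(sgnw: SubgroupNetwork, drug: str) -> float:
    """Fraction of the subgroup's dysregulated genes reversed by the drug."""
    genes = sgnw.genes()
    if not genes:
        raise ValueError("subgroup network has no dysregulated genes")
    return len(sgnw.reversed_genes(drug)) / len(genes)


def idf(
    kb: KnowledgeGraph,
    drug: str,
    scope: str = "kb_wide",
    sgnw: SubgroupNetwork | None = None,
) -> float:
    """Inverse drug frequency log10(Ns / nS_j).

    Ns is the number of genes in the knowledge base. Under the default
    ``kb_wide`` scope, nS_j counts every gene the drug has a regulation
    edge to anywhere in the knowledge base (promiscuity penalty); under
    ``subgroup``, only the genes it reverses inside the given network.
    """
    if scope not in ("kb_wide", "subgroup"):
        raise ValueError(f"unknown IDF scope {scope!r}")
    ns = kb.n_genes()
    if scope == "kb_wide":
        nsj = len(kb.drug_gene_directions(drug))
    else:
        if sgnw is None:
            raise ValueError("subgroup scope requires a subgroup network")
        nsj = len(sgnw.reversed_genes(drug))
    if nsj == 0:
        raise DrugNotScorable(f"drug {drug!r} perturbs no gene in scope {scope!r}")
    return math.log10(ns / nsj)


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

def rank_drugs(
    sgnw: SubgroupNetwork,
    kb: KnowledgeGraph,
    idf_scope: str = "kb_wide",
    pa_mode: str = "any",
    agf_mode: str = "sum",
) -> list:
    """Score every drug in the network and rank by DScore descending.

    Ties are broken by drug id; ranks run 1..K without gaps. Drugs that
    cannot be scored (no perturbed gene in the IDF scope) are skipped with
    a warning. ``agf_mode="mean"`` divides AGF by the number of reversed
    genes (variant reading of the accumulative weight).
    """
    if agf_mode not in ("sum", "mean"):
        raise ValueError(f"unknown agf_mode {agf_mode!r}")
    records = []
    for drug in sorted(sgnw.drug_targets):
        try:
            idf_value = idf(kb, drug, idf_scope, sgnw)
        except DrugNotScorable as exc:
            logger.warning("skipping drug: %s", exc)
            continue
        agf_value = agf(sgnw, kb, drug)
        if agf_mode == "mean":
            agf_value /= len(sgnw.reversed_genes(drug))
        pa_value = pa(sgnw, drug, pa_mode)
        osm_value = osm(pa_value, agf_value)
        gp_value = gp(sgnw, drug)
        records.append(
            DrugScoreRecord(
                drug_id=drug,
                agf=agf_value,
                pa=pa_value,
                osm=osm_value,
                gp=gp_value,
                idf=idf_value,
                dscore=osm_value * idf_value * gp_value,
                rank=0,
                reversed_genes=tuple(sorted(sgnw.reversed_genes(drug))),
            )
        )
    if not records:
        logger.warning("subgroup network contains no scorable drug")
        return []
    records.sort(key=lambda r: (-r.dscore, r.drug_id))
    return [
        DrugScoreRecord(**{**r.__dict__, "rank": i + 1}) for i, r in enumerate(records)
    ]


RANKING_COLUMNS = (
    "rank", "drug_id", "pa", "agf", "osm", "gp", "idf", "dscore", "reversed_genes",
)


def write_ranking(records, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(RANKING_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.rank,
                    r.drug_id,
                    f"{r.pa:.6g}",
                    f"{r.agf:.6g}",
                    f"{r.osm:.6g}",
                    f"{r.gp:.6g}",
                    f"{r.idf:.6g}",
                    f"{r.dscore:.6g}",
                    ";".join(r.reversed_genes),
                ]
            )
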
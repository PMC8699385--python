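"""Gene-centric heterogeneous knowledge graph and subgroup-network induction.

The graph holds seven node types -- Gene, Pathway, BiologicalProcess,
CellularComponent, MolecularFunction, Disease, Drug -- with a gene-centric
schema: every edge is incident to at least one Gene node. Drug->gene edges
carry a regulation direction (the drug's effect on the gene's expression),
which drives CMAP-style signature-reversal matching: a drug enters a
subgroup network only if it regulates at least one of the subgroup's
dysregulated genes in the *opposite* direction.

Backed by :mod:`networkx`; nodes are keyed as (type, id) tuples so ids only
need to be unique within a type.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import networkx as nx

from .cohort import DOWN, UP

logger = logging.getLogger(__name__)

GENE = "Gene"
PATHWAY = "Pathway"
BIOLOGICAL_PROCESS = "BiologicalProcess"
CELLULAR_COMPONENT = "CellularComponent"
MOLECULAR_FUNCTION = "MolecularFunction"
DISEASE = "Disease"
DRUG = "Drug"

NODE_TYPES = (
    GENE,
    PATHWAY,
    BIOLOGICAL_PROCESS,
    CELLULAR_COMPONENT,
    MOLECULAR_FUNCTION,
    DISEASE,
    DRUG,
)

#: Annotation types a gene "belongs to" (the membership side of the schema).
ANNOTATION_TYPES = (PATHWAY, BIOLOGICAL_PROCESS, CELLULAR_COMPONENT, MOLECULAR_FUNCTION)

#: Entity types entering the gene-weight (MGF) computation.
MGF_TYPES = (GENE,) + ANNOTATION_TYPES

RELATION_INTERACTS = "interacts"
RELATION_MEMBER_OF = "member_of"
RELATION_ASSOCIATED = "associated_with"
RELATION_REGULATES = "regulates"

_OPPOSITE = {UP: DOWN, DOWN: UP}


class KnowledgeGraph:
    """Typed, gene-centric biomedical graph."""

    def __init__(self) -> None:
        self._g = nx.Graph()

    # -- construction -------------------------------------------------------

    def add_node(self, node_id: str, node_type: str) -> None:
        if node_type not in NODE_TYPES:
            raise ValueError(f"unknown node type {node_type!r}")
        self._g.add_node((node_type, node_id))

    def add_edge(
        self,
        source_id: str,
        source_type: str,
        relation: str,
        target_id: str,
        target_type: str,
        direction: str | None = None,
    ) -> None:
        for t in (source_type, target_type):
            if t not in NODE_TYPES:
                raise ValueError(f"unknown node type {t!r}")
        src, dst = (source_type, source_id), (target_type, target_id)
        for node in (src, dst):
            if node not in self._g:
                raise ValueError(f"edge references undeclared node {node}")
        if source_type != GENE and target_type != GENE:
            raise ValueError(
                f"gene-centric violation: edge {source_type}->{target_type} "
                "has no Gene endpoint"
            )
        if source_type == GENE and target_type == GENE and src == dst:
            raise ValueError(f"self-loop gene-gene edge on {source_id!r}")
        if direction is not None and direction not in (UP, DOWN):
            raise ValueError(f"bad drug-gene direction {direction!r}")
        self._g.add_edge(src, dst, relation=relation, direction=direction)

    # -- queries -------------------------------------------------------------

    def has_node(self, node_id: str, node_type: str) -> bool:
        return (node_type, node_id) in self._g

    def nodes_of_type(self, node_type: str) -> set:
        return {nid for (t, nid) in self._g.nodes if t == node_type}

    def neighbors_of_type(self, node_id: str, node_type: str, neighbor_type: str) -> set:
        key = (node_type, node_id)
        if key not in self._g:
            return set()
        return {nid for (t, nid) in self._g.neighbors(key) if t == neighbor_type}

    def drug_gene_directions(self, drug_id: str) -> dict:
        """Map gene id -> regulation direction (or None if unlabelled)."""
        key = (DRUG, drug_id)
        out = {}
        for nbr in self._g.neighbors(key) if key in self._g else ():
            if nbr[0] == GENE:
                out[nbr[1]] = self._g.edges[key, nbr].get("direction")
        return out

    def n_genes(self) -> int:
        return len(self.nodes_of_type(GENE))

    def counts(self) -> dict:
        out = {t: 0 for t in NODE_TYPES}
        for t, _ in self._g.nodes:
            out[t] += 1
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        return (
            set(self._g.nodes) == set(other._g.nodes)
            and {frozenset(e): (d["relation"], d["direction"])
                 for *e, d in self._g.edges(data=True)}
            == {frozenset(e): (d["relation"], d["direction"])
                for *e, d in other._g.edges(data=True)}
        )

    # -- persistence ---------------------------------------------------------

    def write(self, nodes_path, edges_path) -> None:
        with open(nodes_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["node_id", "node_type"])
            for t, nid in sorted(self._g.nodes, key=lambda n: (n[0], n[1])):
                w.writerow([nid, t])
        with open(edges_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(
                ["source_id", "source_type", "relation", "target_id", "target_type", "direction"]
            )
            rows = []
            for (st, sid), (tt, tid), data in self._g.edges(data=True):
                # orient gene-first for readability; gene-gene sorted by id
                if st != GENE or (tt == GENE and sid > tid):
                    (st, sid), (tt, tid) = (tt, tid), (st, sid)
                d = data.get("direction")
                rows.append([sid, st, data["relation"], tid, tt, d.lower() if d else "."])
            rows.sort()
            w.writerows(rows)


def load_kb(nodes_path, edges_path) -> KnowledgeGraph:
    """Load a knowledge graph from node/edge TSVs, validating the schema.

    Violations (unknown node type, dangling reference, edge without a Gene
    endpoint) are rejected with the offending line number.
    """
    kb = KnowledgeGraph()
    with open(nodes_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            try:
                kb.add_node(row["node_id"], row["node_type"])
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{nodes_path} line {lineno}: {exc}") from exc
    with open(edges_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            direction = row.get("direction", ".")
            direction = None if direction in (".", "", None) else direction.upper()
            try:
                kb.add_edge(
                    row["source_id"],
                    row["source_type"],
                    row["relation"],
                    row["target_id"],
                    row["target_type"],
                    direction,
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{edges_path} line {lineno}: {exc}") from exc
    logger.info("loaded knowledge graph: %s", kb.counts())
    return kb


# ---------------------------------------------------------------------------
# Subgroup networks
# ---------------------------------------------------------------------------

@dataclass
class SubgroupNetwork:
    """The heterogeneous network induced by a subgroup's dysregulated genes.

    ``entity_sets`` holds, per node type, the entity ids in the network;
    ``drug_targets`` maps each included drug to the subgroup gene items it
    reverses (opposite regulation direction).
    """

    gene_items: frozenset = frozenset()
    entity_sets: dict = field(default_factory=dict)
    patterns: list = field(default_factory=list)
    drug_targets: dict = field(default_factory=dict)

    @classmethod
    def empty(cls) -> "SubgroupNetwork":
        return cls(entity_sets={t: set() for t in NODE_TYPES})

    def reversed_genes(self, drug_id: str) -> set:
        return {item.gene for item in self.drug_targets.get(drug_id, ())}

    def genes(self) -> set:
        return {item.gene for item in self.gene_items}


def induce_subgroup_network(
    kb: KnowledgeGraph,
    items,
    patterns=None,
    reversal: str = "opposite",
) -> SubgroupNetwork:
    """Map a subgroup's gene items onto the knowledge graph.

    The induced network contains: the item genes plus their direct
    gene-gene interaction neighbours; every Pathway / BiologicalProcess /
    CellularComponent / MolecularFunction / Disease node adjacent to an item
    gene; and every Drug with at least one drug-gene edge to an item gene
    whose direction opposes the item's direction (``reversal="opposite"``,
    the default signature-reversal rule; ``"either"`` ignores direction for
    sensitivity analyses). Item genes absent from the graph are dropped with
    a logged count.
    """
    if reversal not in ("opposite", "either"):
        raise ValueError(f"unknown reversal mode {reversal!r}")
    items = set(items)
    if not items:
        raise ValueError("cannot induce a network from an empty item set")
    kb_genes = kb.nodes_of_type(GENE)
    present = {i for i in items if i.gene in kb_genes}
    dropped = len(items) - len(present)
    if dropped:
        logger.warning("%d gene items absent from the knowledge graph", dropped)
    if not present:
        raise ValueError("no subgroup gene is present in the knowledge graph")

    item_genes = {i.gene for i in present}
    entity_sets = {t: set() for t in NODE_TYPES}
    entity_sets[GENE] = set(item_genes)
    for g in item_genes:
        entity_sets[GENE] |= kb.neighbors_of_type(g, GENE, GENE)
        for t in ANNOTATION_TYPES + (DISEASE,):
            entity_sets[t] |= kb.neighbors_of_type(g, GENE, t)

    drug_targets = {}
    for g in item_genes:
        for drug in kb.neighbors_of_type(g, GENE, DRUG):
            directions = kb.drug_gene_directions(drug)
            for item in present:
                d = directions.get(item.gene)
                if d is None:
                    continue  # unlabelled drug-gene edges never match
                if reversal == "either" or d == _OPPOSITE[item.direction]:
                    drug_targets.setdefault(drug, set()).add(item)
    drug_targets = {d: frozenset(t) for d, t in sorted(drug_targets.items())}
    entity_sets[DRUG] = set(drug_targets)

    return SubgroupNetwork(
        gene_items=frozenset(present),
        entity_sets=entity_sets,
        patterns=list(patterns or []),
        drug_targets=drug_targets,
    )


def export_property_graph(kb: KnowledgeGraph, nodes_csv, edges_csv) -> None:
    """Export to a property-graph CSV dialect (id/label nodes, typed edges)."""
    with open(nodes_csv, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id:ID", ":LABEL"])
        for t, nid in sorted(kb._g.nodes):
            w.writerow([f"{t}:{nid}", t])
    with open(edges_csv, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([":START_ID", ":END_ID", ":TYPE", "direction"])
        for (st, sid), (tt, tid), data in sorted(
            kb._g.edges(data=True), key=lambda e: (e[0], e[1])
        ):
            d = data.get("direction")
            w.writerow(
                [f"{st}:{sid}", f"{tt}:{tid}", data["relation"], d.lower() if d else ""]
            )
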
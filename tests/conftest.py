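import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from stratdr.cohort import DOWN, UP, GeneItem, prepare_item_matrix
from stratdr.kb import (
    BIOLOGICAL_PROCESS,
    DISEASE,
    DRUG,
    GENE,
    PATHWAY,
    RELATION_INTERACTS,
    RELATION_MEMBER_OF,
    RELATION_REGULATES,
    KnowledgeGraph,
    induce_subgroup_network,
)
from stratdr.mining import Pattern
from stratdr.simulate import SimulationConfig, simulate_cohort, simulate_kb

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def random_item_matrix(rng, n_patients=20, n_items=8):
    """Boolean item matrix over distinct genes (one direction per gene)."""
    directions = [UP, DOWN]
    items = [GeneItem(f"g{j}", directions[j % 2]) for j in range(n_items)]
    probs = rng.uniform(0.3, 0.9, size=n_items)
    data = rng.random((n_patients, n_items)) < probs
    return pd.DataFrame(
        data, index=[f"P{i:02d}" for i in range(n_patients)], columns=items
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def build_toy_cascade():
    """Hand-built 6-gene / 3-pathway / 2-BP / 2-drug subgroup network.

    Item genes g1:UP, g2:UP, g3:DOWN; g4-g6 enter as interaction neighbours.
    Drug dA reverses g1 and g3; drug dB reverses g2 and perturbs g5, g6
    elsewhere in the graph. Four patterns: {g1,g2}, {g3}, {g1,g3}, {g2}.
    """
    kb = KnowledgeGraph()
    for g in ("g1", "g2", "g3", "g4", "g5", "g6"):
        kb.add_node(g, GENE)
    for p in ("pw1", "pw2", "pw3"):
        kb.add_node(p, PATHWAY)
    for b in ("bp1", "bp2"):
        kb.add_node(b, BIOLOGICAL_PROCESS)
    for d in ("dA", "dB"):
        kb.add_node(d, DRUG)
    for a, b in (("g1", "g4"), ("g1", "g2"), ("g2", "g5"), ("g3", "g6")):
        kb.add_edge(a, GENE, RELATION_INTERACTS, b, GENE)
    for g, p in (("g1", "pw1"), ("g1", "pw2"), ("g2", "pw2"), ("g3", "pw3"),
                 ("g4", "pw1"), ("g5", "pw3"), ("g6", "pw2")):
        kb.add_edge(g, GENE, RELATION_MEMBER_OF, p, PATHWAY)
    for g, b in (("g1", "bp1"), ("g3", "bp2")):
        kb.add_edge(g, GENE, RELATION_MEMBER_OF, b, BIOLOGICAL_PROCESS)
    kb.add_edge("dA", DRUG, RELATION_REGULATES, "g1", GENE, direction=DOWN)
    kb.add_edge("dA", DRUG, RELATION_REGULATES, "g3", GENE, direction=UP)
    kb.add_edge("dB", DRUG, RELATION_REGULATES, "g2", GENE, direction=DOWN)
    kb.add_edge("dB", DRUG, RELATION_REGULATES, "g5", GENE, direction=DOWN)
    kb.add_edge("dB", DRUG, RELATION_REGULATES, "g6", GENE, direction=UP)

    i1, i2, i3 = GeneItem("g1", UP), GeneItem("g2", UP), GeneItem("g3", DOWN)
    patterns = [
        Pattern(frozenset({i1, i2}), 0.9, 0.0, 100.0, 1.0),
        Pattern(frozenset({i3}), 0.8, 0.0, 100.0, 1.0),
        Pattern(frozenset({i1, i3}), 0.8, 0.0, 100.0, 1.0),
        Pattern(frozenset({i2}), 0.9, 0.0, 100.0, 1.0),
    ]
    sgnw = induce_subgroup_network(kb, {i1, i2, i3}, patterns)
    return sgnw, kb


@pytest.fixture
def toy_cascade():
    return build_toy_cascade()


@pytest.fixture
def sim_pipeline():
    """Factory: seed -> (clinical, item matrix, kb, truth) via the full chain."""

    def make(seed, **overrides):
        cfg = SimulationConfig(seed=seed, **overrides)
        clinical, expr, deg_stats, truth = simulate_cohort(cfg)
        kb = simulate_kb(cfg, truth)
        items = prepare_item_matrix(expr, deg_stats)
        return clinical, items, kb, truth

    return make
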
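import dataclasses
import math

import pytest

from stratdr.cohort import DOWN, UP, GeneItem
from stratdr.kb import (
    DRUG,
    GENE,
    RELATION_REGULATES,
    KnowledgeGraph,
    SubgroupNetwork,
)
from stratdr.ranking import (
    DrugNotScorable,
    agf,
    gp,
    idf,
    mgf,
    osm,
    pa,
    rank_drugs,
    write_ranking,
)
from stratdr.simulate import SimulationConfig, planted_network, simulate_cohort, simulate_kb

# hand-computed cascade values for the toy_cascade fixture
MGF_G1 = (2 / 6 + 2 / 3 + 1 / 2) / 5          # 0.3
MGF_G2 = (2 / 6 + 1 / 3 + 0) / 5              # 2/15
MGF_G3 = (1 / 6 + 1 / 3 + 1 / 2) / 5          # 0.2


class TestMgf:
    def test_hand_values(self, toy_cascade):
        sgnw, kb = toy_cascade
        assert mgf(sgnw, kb, "g1") == pytest.approx(MGF_G1, abs=1e-12)
        assert mgf(sgnw, kb, "g2") == pytest.approx(MGF_G2, abs=1e-12)
        assert mgf(sgnw, kb, "g3") == pytest.approx(MGF_G3, abs=1e-12)

    def test_partial_connectivity_fraction(self):
        # gene linked to 2 of 10 pathways and 1 of 5 processes -> 0.08
        kb = KnowledgeGraph()
        kb.add_node("g", GENE)
        for i in range(10):
            kb.add_node(f"pw{i}", "Pathway")
        for i in range(5):
            kb.add_node(f"bp{i}", "BiologicalProcess")
        kb.add_edge("g", GENE, "member_of", "pw0", "Pathway")
        kb.add_edge("g", GENE, "member_of", "pw1", "Pathway")
        kb.add_edge("g", GENE, "member_of", "bp0", "BiologicalProcess")
        sgnw = SubgroupNetwork.empty()
        sgnw.entity_sets["Gene"] = {"g"}
        sgnw.entity_sets["Pathway"] = {f"pw{i}" for i in range(10)}
        sgnw.entity_sets["BiologicalProcess"] = {f"bp{i}" for i in range(5)}
        assert mgf(sgnw, kb, "g") == pytest.approx(0.08, abs=1e-12)

    def test_isolated_gene_zero(self):
        kb = KnowledgeGraph()
        kb.add_node("g", GENE)
        sgnw = SubgroupNetwork.empty()
        sgnw.entity_sets["Gene"] = {"g"}
        assert mgf(sgnw, kb, "g") == 0.0

    def test_absent_gene_rejected(self, toy_cascade):
        sgnw, kb = toy_cascade
        with pytest.raises(ValueError):
            mgf(sgnw, kb, "nope")

    def test_bounded_unit_interval(self, toy_cascade):
        sgnw, kb = toy_cascade
        for g in sgnw.entity_sets[GENE]:
            assert 0.0 <= mgf(sgnw, kb, g) <= 1.0


class TestCascadeFactors:
    def test_agf_hand_sum(self, toy_cascade):
        sgnw, kb = toy_cascade
        assert agf(sgnw, kb, "dA") == pytest.approx(MGF_G1 + MGF_G3, abs=1e-12)
        assert agf(sgnw, kb, "dB") == pytest.approx(MGF_G2, abs=1e-12)

    def test_pa_any_and_all(self, toy_cascade):
        sgnw, kb = toy_cascade
        # dA reverses g1,g3: hits patterns {g1,g2}, {g3}, {g1,g3} of 4
        assert pa(sgnw, "dA", "any") == pytest.approx(0.75)
        assert pa(sgnw, "dB", "any") == pytest.approx(0.5)
        assert pa(sgnw, "dA", "all") == pytest.approx(0.5)
        assert pa(sgnw, "dB", "all") == pytest.approx(0.25)

    def test_osm_sum(self):
        assert osm(0.5, 0.2) == pytest.approx(0.7)
        assert osm(0.0, 0.0) == 0.0

    def test_gp_fraction(self, toy_cascade):
        sgnw, kb = toy_cascade
        assert gp(sgnw, "dA") == pytest.approx(2 / 3)
        assert gp(sgnw, "dB") == pytest.approx(1 / 3)

    def test_idf_known_values(self):
        kb = KnowledgeGraph()
        for i in range(1000):
            kb.add_node(f"g{i}", GENE)
        kb.add_node("dTen", DRUG)
        kb.add_node("dOne", DRUG)
        kb.add_node("dAll", DRUG)
        for i in range(10):
            kb.add_edge("dTen", DRUG, RELATION_REGULATES, f"g{i}", GENE, direction=UP)
        kb.add_edge("dOne", DRUG, RELATION_REGULATES, "g0", GENE, direction=UP)
        for i in range(1000):
            kb.add_edge("dAll", DRUG, RELATION_REGULATES, f"g{i}", GENE, direction=UP)
        assert idf(kb, "dTen") == pytest.approx(2.0, abs=1e-12)
        assert idf(kb, "dOne") == pytest.approx(3.0, abs=1e-12)
        assert idf(kb, "dAll") == pytest.approx(0.0, abs=1e-12)

    def test_idf_strictly_decreasing_in_target_count(self, toy_cascade):
        _, kb = toy_cascade
        ns = kb.n_genes()
        values = [math.log10(ns / k) for k in range(1, ns + 1)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_idf_unscored_drug_signalled(self, toy_cascade):
        sgnw, kb = toy_cascade
        kb.add_node("dNone", DRUG)
        with pytest.raises(DrugNotScorable):
            idf(kb, "dNone")


class TestRankDrugs:
    def test_full_cascade_hand_ranking(self, toy_cascade):
        sgnw, kb = toy_cascade
        records = rank_drugs(sgnw, kb)
        assert [r.drug_id for r in records] == ["dA", "dB"]
        da, db = records
        # dA: OSM = 0.75 + 0.5; IDF = log10(6/2); GP = 2/3
        assert da.dscore == pytest.approx((0.75 + 0.5) * math.log10(3.0) * (2 / 3), abs=1e-9)
        assert db.dscore == pytest.approx((0.5 + MGF_G2) * math.log10(2.0) * (1 / 3), abs=1e-9)
        for r in records:
            assert r.osm == pytest.approx(r.pa + r.agf, abs=1e-9)
            assert r.dscore == pytest.approx(r.osm * r.idf * r.gp, abs=1e-9)
        assert [r.rank for r in records] == [1, 2]

    def test_subgroup_idf_scope(self, toy_cascade):
        sgnw, kb = toy_cascade
        records = rank_drugs(sgnw, kb, idf_scope="subgroup")
        by_id = {r.drug_id: r for r in records}
        assert by_id["dA"].idf == pytest.approx(math.log10(3.0), abs=1e-12)
        assert by_id["dB"].idf == pytest.approx(math.log10(6.0), abs=1e-12)

    def test_ranking_input_order_invariant(self, toy_cascade):
        sgnw, kb = toy_cascade
        reordered = dataclasses.replace(
            sgnw,
            drug_targets=dict(sorted(sgnw.drug_targets.items(), reverse=True)),
        )
        assert rank_drugs(sgnw, kb) == rank_drugs(reordered, kb)

    def test_dscore_monotone_in_reversed_genes(self, toy_cascade):
        """At fixed IDF, granting a drug one more reversed gene never
        lowers PA, AGF or GP, hence never lowers DScore."""
        sgnw, kb = toy_cascade
        extra = GeneItem("g3", DOWN)
        grown = dataclasses.replace(
            sgnw,
            drug_targets={
                **sgnw.drug_targets,
                "dB": frozenset(sgnw.drug_targets["dB"] | {extra}),
            },
        )
        fixed_idf = 1.0
        before = (pa(sgnw, "dB"), agf(sgnw, kb, "dB"), gp(sgnw, "dB"))
        after = (pa(grown, "dB"), agf(grown, kb, "dB"), gp(grown, "dB"))
        assert all(b2 >= b1 for b1, b2 in zip(before, after))
        d_before = osm(before[0], before[1]) * fixed_idf * before[2]
        d_after = osm(after[0], after[1]) * fixed_idf * after[2]
        assert d_after >= d_before

    def test_planted_drug_outranks_decoys(self):
        cfg = SimulationConfig(seed=11)
        _, _, _, truth = simulate_cohort(cfg)
        kb = simulate_kb(cfg, truth)
        records = rank_drugs(planted_network(kb, truth), kb)
        assert records[0].drug_id == truth.drug_id
        assert len(records) >= 2

    def test_empty_network_empty_ranking(self, toy_cascade):
        sgnw, kb = toy_cascade
        bare = dataclasses.replace(sgnw, drug_targets={})
        assert rank_drugs(bare, kb) == []

    def test_ranking_tsv(self, toy_cascade, tmp_path):
        sgnw, kb = toy_cascade
        path = tmp_path / "ranking.tsv"
        write_ranking(rank_drugs(sgnw, kb), path)
        lines = path.read_text().splitlines()
        assert lines[0].split("\t")[0] == "rank"
        assert len(lines) == 3
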
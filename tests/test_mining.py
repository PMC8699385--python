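import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stratdr.cohort import DOWN, UP, GeneItem
from stratdr.mining import (
    JValueConfig,
    MiningConfig,
    NoPatternsError,
    Pattern,
    confidence,
    growth,
    j_value,
    jorg,
    mine_contrast_patterns,
    random_subgroup_baseline,
    support,
)

from .conftest import random_item_matrix
from .oracles import enumerate_contrast_patterns

A_UP = GeneItem("A", UP)
B_DOWN = GeneItem("B", DOWN)


def toy_six_patients():
    """A:UP in P1-P3 only; B:DOWN in P1-P4. Subgroup {P1,P2,P3}."""
    return pd.DataFrame(
        {
            A_UP: [True, True, True, False, False, False],
            B_DOWN: [True, True, True, True, False, False],
        },
        index=[f"P{i}" for i in range(1, 7)],
    )


class TestSupport:
    def test_direct_ratio(self):
        df = pd.DataFrame({A_UP: [True] * 8 + [False] * 2})
        assert support({A_UP}, df) == pytest.approx(0.8)

    def test_all_patients(self):
        df = pd.DataFrame({A_UP: [True] * 5})
        assert support({A_UP}, df) == 1.0

    def test_empty_patient_set_rejected(self):
        with pytest.raises(ValueError):
            support({A_UP}, pd.DataFrame({A_UP: []}))

    def test_matches_row_scan_oracle(self, rng):
        df = random_item_matrix(rng, n_patients=12, n_items=6)
        cols = list(df.columns)
        for _ in range(20):
            k = rng.integers(1, 4)
            items = [cols[j] for j in rng.choice(len(cols), size=k, replace=False)]
            manual = sum(
                all(df.loc[p, i] for i in items) for p in df.index
            ) / len(df)
            assert support(items, df) == pytest.approx(manual)

    def test_anti_monotone_in_items(self, rng):
        df = random_item_matrix(rng, n_patients=15, n_items=6)
        cols = list(df.columns)
        for _ in range(30):
            k = rng.integers(2, 5)
            sup_set = [cols[j] for j in rng.choice(len(cols), size=k, replace=False)]
            sub_set = sup_set[: rng.integers(1, k)]
            assert support(sup_set, df) <= support(sub_set, df) + 1e-12


class TestGrowth:
    @pytest.mark.parametrize(
        "s1,s2,expected",
        [(0.9, 0.45, 2.0), (0.5, 0.5, 1.0), (0.8, 0.0, 100.0), (0.0, 0.8, 100.0)],
    )
    def test_known_values(self, s1, s2, expected):
        assert growth(s1, s2, cap=100.0) == pytest.approx(expected)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            growth(0.0, 0.0)

    @given(
        s1=st.floats(0.0, 1.0), s2=st.floats(0.0, 1.0), cap=st.floats(10.0, 1e6)
    )
    def test_symmetry(self, s1, s2, cap):
        if s1 == 0 and s2 == 0:
            return
        assert growth(s1, s2, cap) == growth(s2, s1, cap)

    @given(s1=st.floats(0.01, 1.0), s2=st.floats(0.01, 1.0))
    def test_at_least_one(self, s1, s2):
        assert growth(s1, s2) >= 1.0


class TestConfidence:
    def test_exclusive_pattern(self):
        df = toy_six_patients()
        sg = df.loc[["P1", "P2", "P3"]]
        assert confidence({A_UP}, sg, df) == 1.0

    def test_partial(self):
        df = toy_six_patients()
        sg = df.loc[["P1", "P2", "P3"]]
        assert confidence({B_DOWN}, sg, df) == pytest.approx(0.75)

    def test_absent_pattern_rejected(self):
        df = toy_six_patients()
        empty = df.copy()
        empty[:] = False
        with pytest.raises(ValueError):
            confidence({A_UP}, empty, empty)

    def test_matches_exhaustive_count(self, rng):
        df = random_item_matrix(rng, n_patients=8, n_items=4)
        sg_ids = list(df.index[:3])
        for col in df.columns:
            if not df[col].any():
                continue
            total = int(df[col].sum())
            inside = int(df.loc[sg_ids, col].sum())
            assert confidence({col}, df.loc[sg_ids], df) == pytest.approx(inside / total)


class TestMineContrastPatterns:
    def test_six_patient_toy_closed(self):
        """The pair pattern is exclusive to the subgroup; {B} fails confidence.

        {A} has the same supporting patients as {A,B}, so the closed output
        keeps only the maximal pattern.
        """
        df = toy_six_patients()
        out = mine_contrast_patterns(df, ["P1", "P2", "P3"], MiningConfig())
        assert [p.items for p in out] == [frozenset({A_UP, B_DOWN})]
        pat = out[0]
        assert pat.s1 == 1.0 and pat.s2 == 0.0
        assert pat.growth == 100.0 and pat.confidence == 1.0

    def test_six_patient_toy_all_itemsets(self):
        df = toy_six_patients()
        cfg = MiningConfig(pattern_set="all")
        out = mine_contrast_patterns(df, ["P1", "P2", "P3"], cfg)
        assert {p.items for p in out} == {
            frozenset({A_UP}),
            frozenset({A_UP, B_DOWN}),
        }

    def test_exclusive_items_all_retained(self):
        items = [GeneItem(g, UP) for g in "xyz"]
        df = pd.DataFrame(
            {i: [True] * 4 + [False] * 4 for i in items},
            index=[f"P{i}" for i in range(8)],
        )
        out = mine_contrast_patterns(df, [f"P{i}" for i in range(4)])
        # single closed pattern: the full triple (all subsets share its mask)
        assert [p.items for p in out] == [frozenset(items)]
        assert out[0].s1 == 1.0

    def test_no_items_in_subgroup_yields_empty(self):
        df = toy_six_patients()
        out = mine_contrast_patterns(df, ["P5", "P6"])
        assert out == []

    def test_whole_cohort_rejected(self):
        df = toy_six_patients()
        with pytest.raises(ValueError):
            mine_contrast_patterns(df, list(df.index))

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_exhaustive_oracle(self, trial):
        rng = np.random.default_rng(5000 + trial)
        df = random_item_matrix(rng, n_patients=20, n_items=8)
        sg = list(rng.choice(df.index, size=6, replace=False))
        cfg = MiningConfig(max_pattern_len=8)
        mined = {
            p.items: (p.s1, p.s2, p.growth, p.confidence)
            for p in mine_contrast_patterns(df, sg, cfg)
        }
        oracle = enumerate_contrast_patterns(df, sg, max_len=8)
        assert set(mined) == set(oracle)
        for key, stats in oracle.items():
            assert mined[key] == pytest.approx(stats)

    def test_deterministic_order(self, rng):
        df = random_item_matrix(rng, n_patients=20, n_items=8)
        sg = list(df.index[:6])
        first = mine_contrast_patterns(df, sg)
        second = mine_contrast_patterns(df[list(df.columns)[::-1]], sg)
        assert [p.items for p in first] == [p.items for p in second]


def make_patterns(growths):
    return [
        Pattern(frozenset({GeneItem(f"g{i}", UP)}), 0.9, 0.0, g, 1.0)
        for i, g in enumerate(growths)
    ]


class TestJValue:
    def test_blend_symmetry(self):
        pats = make_patterns([4.0])
        assert j_value(pats, T=10, random_jorgs=[4.0], M=10) == pytest.approx(4.0)

    def test_prior_only_limit(self):
        pats = make_patterns([7.0])
        assert j_value(pats, T=0, random_jorgs=[2.0, 4.0], M=5) == pytest.approx(3.0)

    def test_known_blend(self):
        pats = make_patterns([4.0])
        assert j_value(pats, T=30, random_jorgs=[2.0], M=30) == pytest.approx(3.0)

    def test_empty_patterns_signalled(self):
        with pytest.raises(NoPatternsError):
            jorg([])

    @given(
        g=st.lists(st.floats(1.0, 100.0), min_size=1, max_size=5),
        prior=st.lists(st.floats(1.0, 100.0), min_size=1, max_size=5),
        T=st.floats(0.0, 100.0),
        M=st.floats(0.1, 100.0),
    )
    def test_bounded_by_blend_components(self, g, prior, T, M):
        pats = make_patterns(g)
        j = j_value(pats, T=T, random_jorgs=prior, M=M)
        lo = min(jorg(pats), float(np.mean(prior)))
        hi = max(jorg(pats), float(np.mean(prior)))
        assert lo - 1e-9 <= j <= hi + 1e-9


class TestRandomSubgroupBaseline:
    def test_reproducible_and_neutral_floor(self, rng):
        clinical = pd.DataFrame(
            {"var": ["a", "a", "b", "b", "c", "c"]},
            index=[f"P{i}" for i in range(1, 7)],
        )
        df = toy_six_patients()
        jcfg = JValueConfig(n_random_subgroups=10, seed=3)
        out1 = random_subgroup_baseline(clinical, df, MiningConfig(), jcfg)
        out2 = random_subgroup_baseline(clinical, df, MiningConfig(), jcfg)
        assert out1 == out2
        jorgs, M = out1
        assert all(j >= 1.0 for j in jorgs)
        assert 0 < M <= len(clinical)
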
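"""Contrast (emerging) pattern mining over dysregulation items.

A *pattern* is a set of (gene, direction) items that co-occur in patients.
For a focus subgroup SG1 inside a cohort, a contrast pattern must be

* frequent in SG1: support s1 = |patients in SG1 with the pattern| / |SG1|
  strictly above ``support_min``;
* contrasted against the outer population SG2: growth rate
  max(s1, s2) / min(s1, s2) strictly above ``growth_min`` (capped when the
  pattern never occurs outside);
* confident: of all patients carrying the pattern, the fraction inside SG1
  must reach ``confidence_min`` (rule confidence pattern -> subgroup).

Enumeration is level-wise (apriori-style) with support-based pruning; by
default only *closed* patterns are reported (no enumerated strict superset
with an identical supporting-patient set), so each distinct supporting set
is represented once, by its maximal item sets.

The aggregate quality of a subgroup's pattern set is the J-value, a
Bayesian-average blend of the subgroup's mean pattern growth with the mean
growth observed in randomly drawn clinical subgroups.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import MISSING, GeneItem

logger = logging.getLogger(__name__)


class NoPatternsError(ValueError):
    """Raised when an aggregate statistic is requested for an empty pattern set."""


@dataclass(frozen=True)
class Pattern:
    """A contrast pattern with its support/contrast statistics."""

    items: frozenset
    s1: float
    s2: float
    growth: float
    confidence: float

    @property
    def sorted_items(self) -> tuple:
        return tuple(sorted(self.items))

    def sort_key(self) -> tuple:
        return (len(self.items), tuple(str(i) for i in self.sorted_items))

    def __str__(self) -> str:
        return ";".join(str(i) for i in self.sorted_items)


@dataclass(frozen=True)
class MiningConfig:
    """Thresholds for contrast-pattern mining.

    Defaults follow the published filter settings: pattern support in the
    focus subgroup strictly greater than 70%, growth strictly greater than
    1.5, and confidence of 1 (exclusive patterns). ``growth_cap`` bounds the
    growth of patterns absent outside the subgroup so that J-value means
    remain finite.
    """

    support_min: float = 0.70
    growth_min: float = 1.5
    confidence_min: float = 1.0
    max_pattern_len: int = 3
    growth_cap: float = 100.0
    pattern_set: str = "closed"  # closed | maximal | all

    def __post_init__(self) -> None:
        if not 0 < self.support_min <= 1:
            raise ValueError("support_min must be in (0, 1]")
        if self.growth_min < 1:
            raise ValueError("growth_min must be >= 1")
        if self.max_pattern_len < 1:
            raise ValueError("max_pattern_len must be >= 1")
        if self.pattern_set not in ("closed", "maximal", "all"):
            raise ValueError(f"unknown pattern_set {self.pattern_set!r}")


@dataclass(frozen=True)
class JValueConfig:
    """Configuration of the J-value Bayesian average.

    ``T`` weights the focus subgroup's own mean pattern growth; ``None``
    uses the focus subgroup's patient count (population-size preference).
    ``n_random_subgroups`` controls the random-subgroup baseline that
    supplies the prior mean growth and the average subgroup size M.
    """

    T: float | None = None
    n_random_subgroups: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T is not None and self.T < 0:
            raise ValueError("T must be >= 0")
        if self.n_random_subgroups < 1:
            raise ValueError("n_random_subgroups must be >= 1")


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def support(pattern_items, patients: pd.DataFrame) -> float:
    """Fraction of ``patients`` (boolean item rows) carrying all items."""
    if len(patients) == 0:
        raise ValueError("support undefined over an empty patient set")
    items = list(pattern_items)
    mask = patients[items].to_numpy(dtype=bool).all(axis=1)
    return float(mask.sum()) / len(patients)


def growth(s1: float, s2: float, cap: float = 100.0) -> float:
    """Growth rate max(s1, s2) / min(s1, s2); returns ``cap`` when min is 0."""
    for s in (s1, s2):
        if not 0 <= s <= 1:
            raise ValueError("supports must lie in [0, 1]")
    if s1 == 0 and s2 == 0:
        raise ValueError("growth undefined: pattern occurs nowhere")
    lo, hi = min(s1, s2), max(s1, s2)
    if lo == 0:
        return float(cap)
    return hi / lo


def confidence(pattern_items, sg_patients: pd.DataFrame, all_patients: pd.DataFrame) -> float:
    """Rule confidence of pattern -> subgroup membership.

    |subgroup patients with the pattern| / |all patients with the pattern|.
    """
    items = list(pattern_items)
    total = all_patients[items].to_numpy(dtype=bool).all(axis=1).sum()
    if total == 0:
        raise ValueError("confidence undefined: pattern absent from the cohort")
    inside = sg_patients[items].to_numpy(dtype=bool).all(axis=1).sum()
    return float(inside) / float(total)


# ---------------------------------------------------------------------------
# Pattern enumeration
# ---------------------------------------------------------------------------

def _frequent_itemsets(X: np.ndarray, sg_mask: np.ndarray, cfg: MiningConfig):
    """Level-wise enumeration of itemsets frequent in the subgroup.

    Returns a dict mapping sorted item-index tuples to their global boolean
    support mask over all patients. Support in SG1 is anti-monotone, so each
    level only joins frequent (k-1)-sets sharing a (k-2)-prefix.
    """
    n_sg = int(sg_mask.sum())
    masks: dict[tuple, np.ndarray] = {}
    level = []
    for j in range(X.shape[1]):
        col = X[:, j]
        if col[sg_mask].sum() / n_sg > cfg.support_min:
            masks[(j,)] = col
            level.append((j,))
    for _ in range(2, cfg.max_pattern_len + 1):
        if not level:
            break
        nxt = []
        for a, b in itertools.combinations(level, 2):
            if a[:-1] != b[:-1]:
                continue
            cand = a + (b[-1],)
            # all (k-1)-subsets must themselves be frequent
            if any(cand[:i] + cand[i + 1:] not in masks for i in range(len(cand))):
                continue
            mask = masks[a] & X[:, b[-1]]
            if mask[sg_mask].sum() / n_sg > cfg.support_min:
                masks[cand] = mask
                nxt.append(cand)
        level = sorted(nxt)
    return masks


def _closed_subset(masks: dict) -> set:
    """Itemsets with no enumerated strict superset sharing the same mask."""
    groups: dict[bytes, list] = {}
    for itemset, mask in masks.items():
        groups.setdefault(mask.tobytes(), []).append(itemset)
    closed = set()
    for members in groups.values():
        sets = [frozenset(m) for m in members]
        for itemset, fs in zip(members, sets):
            if not any(fs < other for other in sets):
                closed.add(itemset)
    return closed


def mine_contrast_patterns(
    item_df: pd.DataFrame, sg_ids, cfg: MiningConfig | None = None
) -> list:
    """Mine contrast patterns of a focus subgroup against the rest.

    ``item_df`` is the boolean item matrix (patients x GeneItem columns);
    ``sg_ids`` the focus subgroup's patient ids (nonempty strict subset).
    Returns retained :class:`Pattern` objects in deterministic order
    (pattern length, then lexicographic item ids).
    """
    cfg = cfg or MiningConfig()
    sg_ids = set(sg_ids)
    if not sg_ids:
        raise ValueError("focus subgroup is empty")
    sg_mask = item_df.index.isin(sg_ids)
    if sg_mask.sum() != len(sg_ids):
        raise ValueError("subgroup contains unknown patient ids")
    if sg_mask.all():
        raise ValueError("focus subgroup must be a strict subset of the cohort")

    columns = sorted(item_df.columns)
    X = item_df[columns].to_numpy(dtype=bool)
    n_sg = int(sg_mask.sum())
    n_out = int((~sg_mask).sum())

    masks = _frequent_itemsets(X, sg_mask, cfg)
    if cfg.pattern_set == "closed":
        keep = _closed_subset(masks)
    else:
        keep = set(masks)

    patterns = []
    for itemset in keep:
        mask = masks[itemset]
        c_sg = int(mask[sg_mask].sum())
        c_out = int(mask[~sg_mask].sum())
        s1 = c_sg / n_sg
        s2 = c_out / n_out
        g = growth(s1, s2, cfg.growth_cap)
        conf = c_sg / (c_sg + c_out)
        if g > cfg.growth_min and conf >= cfg.confidence_min:
            patterns.append(
                Pattern(
                    items=frozenset(columns[j] for j in itemset),
                    s1=s1,
                    s2=s2,
                    growth=g,
                    confidence=conf,
                )
            )

    if cfg.pattern_set == "maximal":
        item_sets = [p.items for p in patterns]
        patterns = [
            p for p in patterns if not any(p.items < other for other in item_sets)
        ]
    patterns.sort(key=Pattern.sort_key)
    return patterns


# ---------------------------------------------------------------------------
# J-value
# ---------------------------------------------------------------------------

def jorg(patterns) -> float:
    """Mean (cap-bounded) growth over a subgroup's retained patterns."""
    patterns = list(patterns)
    if not patterns:
        raise NoPatternsError("J undefined for an empty pattern set")
    return float(np.mean([p.growth for p in patterns]))


def j_value(patterns, T: float, random_jorgs, M: float) -> float:
    """Bayesian-average blend of subgroup and random-baseline mean growth.

    J = (T * Jorg + M * Javg) / (T + M), where Jorg is the subgroup's mean
    pattern growth, Javg the mean of random-subgroup Jorg values, T the
    population-size preference weight and M the average random-subgroup size.
    """
    if T + M <= 0:
        raise ValueError("T + M must be positive")
    j_org = jorg(patterns)
    j_avg = float(np.mean(list(random_jorgs)))
    return (T * j_org + M * j_avg) / (T + M)


def random_subgroup_baseline(
    clinical: pd.DataFrame,
    item_df: pd.DataFrame,
    mining_cfg: MiningConfig,
    jcfg: JValueConfig,
    rng: np.random.Generator | None = None,
):
    """Draw random single-predicate subgroups and summarise their contrast.

    Picks ``jcfg.n_random_subgroups`` clinical (variable = value) predicates
    uniformly at random (missing-value sentinel excluded), mines each
    induced subgroup with the same thresholds, and returns
    ``(jorg_values, M)`` where M is the mean subgroup size. Subgroups with
    no retained patterns (or that are empty / the whole cohort) contribute
    a neutral Jorg of 1 (no contrast).
    """
    rng = rng or np.random.default_rng(jcfg.seed)
    predicates = [
        (var, val)
        for var in clinical.columns
        for val in sorted(clinical[var].dropna().unique())
        if val != MISSING
    ]
    if not predicates:
        raise ValueError("no usable clinical predicates")
    n = len(clinical)
    jorgs, sizes = [], []
    for _ in range(jcfg.n_random_subgroups):
        var, val = predicates[rng.integers(len(predicates))]
        ids = clinical.index[clinical[var] == val]
        sizes.append(len(ids))
        if 0 < len(ids) < n:
            pats = mine_contrast_patterns(item_df, ids, mining_cfg)
            jorgs.append(jorg(pats) if pats else 1.0)
        else:
            jorgs.append(1.0)
    return jorgs, float(np.mean(sizes))


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def patterns_to_frame(patterns) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "items": str(p),
                "s1": p.s1,
                "s2": p.s2,
                "growth": p.growth,
                "confidence": p.confidence,
            }
            for p in patterns
        ],
        columns=["items", "s1", "s2", "growth", "confidence"],
    )


def write_patterns(patterns, path) -> None:
    patterns_to_frame(patterns).to_csv(path, sep="\t", index=False)


def pattern_from_dict(d: dict) -> Pattern:
    return Pattern(
        items=frozenset(GeneItem.parse(t) for t in d["items"].split(";")),
        s1=d["s1"],
        s2=d["s2"],
        growth=d["growth"],
        confidence=d["confidence"],
    )
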
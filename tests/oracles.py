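"""Independent brute-force oracles used to cross-check the fast paths.

These deliberately avoid the package's mining/search internals: pattern
enumeration walks every subset of the item columns; subgroup search scores
every nonempty predicate conjunction. Small inputs only.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_contrast_patterns(
    item_df,
    sg_ids,
    support_min: float = 0.70,
    growth_min: float = 1.5,
    confidence_min: float = 1.0,
    growth_cap: float = 100.0,
    max_len: int | None = None,
    closed: bool = True,
):
    """All itemsets passing the contrast thresholds, by exhaustive scan.

    Returns a dict mapping frozenset(items) -> (s1, s2, growth, confidence).
    Closedness: an itemset is dropped if a strict superset within the
    enumerated frequent family has the identical supporting-patient set.
    """
    cols = list(item_df.columns)
    max_len = max_len or len(cols)
    sg_mask = np.asarray(item_df.index.isin(set(sg_ids)))
    X = item_df.to_numpy(dtype=bool)
    n_sg, n_out = int(sg_mask.sum()), int((~sg_mask).sum())

    frequent = {}  # frozenset(col indices) -> support mask
    for k in range(1, max_len + 1):
        for combo in itertools.combinations(range(len(cols)), k):
            mask = X[:, combo].all(axis=1)
            if mask[sg_mask].sum() / n_sg > support_min:
                frequent[frozenset(combo)] = mask

    out = {}
    for combo, mask in frequent.items():
        if closed and any(
            combo < other and np.array_equal(mask, frequent[other])
            for other in frequent
        ):
            continue
        c_sg = int(mask[sg_mask].sum())
        c_out = int(mask[~sg_mask].sum())
        s1, s2 = c_sg / n_sg, c_out / n_out
        g = growth_cap if min(s1, s2) == 0 else max(s1, s2) / min(s1, s2)
        conf = c_sg / (c_sg + c_out)
        if g > growth_min and conf >= confidence_min:
            out[frozenset(cols[j] for j in combo)] = (s1, s2, g, conf)
    return out


def all_conjunctions(clinical, sentinel="NA"):
    """Every nonempty predicate conjunction over the clinical variables."""
    per_var = []
    for var in clinical.columns:
        values = [v for v in sorted(clinical[var].unique()) if v != sentinel]
        per_var.append([None] + [(var, v) for v in values])
    for combo in itertools.product(*per_var):
        preds = tuple(p for p in combo if p is not None)
        if preds:
            yield preds


def exhaustive_best_spc(clinical, item_df, kb, cfg, baseline):
    """Best SPCScore over every nonempty conjunction (0.0 if none viable)."""
    from stratdr.search import SubgroupDefinition, evaluate_subgroup

    best = 0.0
    for preds in all_conjunctions(clinical):
        res = evaluate_subgroup(
            SubgroupDefinition(preds), clinical, item_df, kb, cfg, baseline
        )
        if res is not None and res.spc_score > best:
            best = res.spc_score
    return best
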
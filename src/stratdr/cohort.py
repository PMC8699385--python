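"""Cohort loading, normalisation, discretisation and item encoding.

The pipeline turns a raw expression matrix (genes x patients, non-negative
counts or normalised units) into a boolean *item matrix* suitable for
contrast-pattern mining:

1. ``normalize_log2`` -- log2(v + pseudocount) transform.
2. ``zscore_categorize`` -- per-gene z-scoring across the cohort, then
   trichotomisation into UP / DOWN / NORMAL regulation states.
3. ``select_degs`` -- differential-expression gene filter on externally
   computed per-gene statistics (log2 fold-change and p-value).
4. ``build_item_matrix`` -- one boolean column per (gene, direction) item;
   NORMAL never forms an item.

Clinical tables are plain pandas DataFrames indexed by patient id with
categorical (string) columns; missing values use the single sentinel
category ``MISSING``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Sentinel category for missing clinical values. Never used as a predicate.
MISSING = "NA"

UP = "UP"
DOWN = "DOWN"
NORMAL = "NORMAL"


@dataclass(frozen=True, order=True)
class GeneItem:
    """A dysregulation item: a gene together with its direction (UP/DOWN)."""

    gene: str
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in (UP, DOWN):
            raise ValueError(f"item direction must be UP or DOWN, got {self.direction!r}")

    def __str__(self) -> str:  # used in TSV/JSON serialisations
        return f"{self.gene}:{self.direction}"

    @classmethod
    def parse(cls, text: str) -> "GeneItem":
        gene, _, direction = text.rpartition(":")
        return cls(gene, direction)


# ---------------------------------------------------------------------------
# I/O helpers (TSV dialects)
# ---------------------------------------------------------------------------

def read_clinical(path) -> pd.DataFrame:
    """Read a clinical TSV (``patient_id`` column + categorical variables)."""
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("patient_id")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate patient_ids in clinical table: {dupes}")
    return df.fillna(MISSING)


def read_expression(path) -> pd.DataFrame:
    """Read an expression TSV (genes as rows, patients as columns)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    return df


def read_deg_stats(path) -> pd.DataFrame:
    """Read per-gene differential statistics: ``gene_id, log2fc, pvalue``."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = {"gene_id", "log2fc", "pvalue"} - set(df.columns)
    if missing:
        raise ValueError(f"deg stats table lacks columns: {sorted(missing)}")
    bad = df[(df["pvalue"] < 0) | (df["pvalue"] > 1)]
    if len(bad):
        raise ValueError(f"p-values outside [0,1] for genes {bad['gene_id'].tolist()}")
    return df.set_index("gene_id")


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def normalize_log2(expr: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2-transform a non-negative expression matrix.

    Each value ``v`` becomes ``log2(v + pseudocount)``. Negative input is a
    contract violation and is rejected with the offending gene/patient named.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    values = expr.to_numpy(dtype=float)
    if (values < 0).any():
        g, p = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative expression value for gene {expr.index[g]!r}, "
            f"patient {expr.columns[p]!r}"
        )
    return pd.DataFrame(
        np.log2(values + pseudocount), index=expr.index, columns=expr.columns
    )


def zscore_categorize(
    expr: pd.DataFrame,
    up_thresh: float = 1.0,
    down_thresh: float = -1.0,
    ddof: int = 1,
) -> pd.DataFrame:
    """Trichotomise expression into regulation states via per-gene z-scores.

    For every gene, z = (value - gene mean) / gene sd across all patients.
    State is UP when z > ``up_thresh``, DOWN when z < ``down_thresh``, NORMAL
    otherwise (boundary values are NORMAL: strict inequalities). Genes with
    zero variance are NORMAL everywhere.

    Returns a patients x genes DataFrame of {UP, DOWN, NORMAL} strings.
    """
    if up_thresh <= down_thresh:
        raise ValueError("up_thresh must exceed down_thresh")
    values = expr.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=ddof, keepdims=True)
    nonzero = sd > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(nonzero, (values - mean) / np.where(nonzero, sd, 1.0), 0.0)
    states = np.full(values.shape, NORMAL, dtype=object)
    states[z > up_thresh] = UP
    states[z < down_thresh] = DOWN
    return pd.DataFrame(states.T, index=expr.columns, columns=expr.index).rename_axis(
        index="patient_id", columns="gene_id"
    )


def select_degs(stats: pd.DataFrame, p_max: float = 0.05, lfc_min: float = 2.0) -> set:
    """Select differentially expressed genes.

    Retains genes with ``pvalue < p_max`` and ``|log2fc| > lfc_min`` (both
    strict, matching the convention log2FC > +2 for up- and < -2 for
    down-regulated genes).
    """
    keep = (stats["pvalue"] < p_max) & (stats["log2fc"].abs() > lfc_min)
    return set(stats.index[keep])


def build_item_matrix(reg: pd.DataFrame, degs: set) -> pd.DataFrame:
    """Encode a regulation matrix as boolean (gene, direction) item columns.

    ``reg`` is patients x genes with {UP, DOWN, NORMAL} entries. Only the
    selected DEGs contribute items; each retained gene yields two columns,
    ``GeneItem(g, UP)`` and ``GeneItem(g, DOWN)``, mutually exclusive per
    patient. Columns are sorted by (gene, direction) for determinism.
    """
    if not degs:
        raise ValueError("empty DEG set: no items to encode")
    missing = set(degs) - set(reg.columns)
    if missing:
        raise ValueError(f"DEGs absent from regulation matrix: {sorted(missing)}")
    genes = sorted(degs)
    sub = reg[genes]
    columns: dict[GeneItem, np.ndarray] = {}
    for gene in genes:
        states = sub[gene].to_numpy()
        columns[GeneItem(gene, UP)] = states == UP
        columns[GeneItem(gene, DOWN)] = states == DOWN
    items = sorted(columns)
    out = pd.DataFrame({it: columns[it] for it in items}, index=reg.index)
    return out


def prepare_item_matrix(
    expr: pd.DataFrame,
    stats: pd.DataFrame,
    pseudocount: float = 1.0,
    up_thresh: float = 1.0,
    down_thresh: float = -1.0,
    p_max: float = 0.05,
    lfc_min: float = 2.0,
) -> pd.DataFrame:
    """Full preprocessing chain: normalise, discretise, select DEGs, encode."""
    degs = select_degs(stats, p_max=p_max, lfc_min=lfc_min)
    if not degs:
        raise ValueError("no gene passes the DEG thresholds")
    reg = zscore_categorize(normalize_log2(expr, pseudocount), up_thresh, down_thresh)
    return build_item_matrix(reg, degs)


def write_item_matrix(items: pd.DataFrame, path) -> None:
    out = items.copy()
    out.columns = [str(c) for c in out.columns]
    out.astype(int).to_csv(path, sep="\t", index_label="patient_id")


def read_item_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="patient_id")
    df.columns = [GeneItem.parse(c) for c in df.columns]
    return df.astype(bool)
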
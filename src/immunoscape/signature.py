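"""T cell-inflamed signature scoring and phenotype classification.

Each signature gene is discretized per sample against its cross-sample
mean: +1 above, -1 below, 0 exactly equal.  The per-sample sum over a
G-gene signature ranges from -G to +G; samples scoring strictly below
-G/2 are called non-inflamed, strictly above +G/2 inflamed, and the rest
intermediate (with G = 160 these thresholds are -80 / +80).  The
continuous "signature expression" used in correlation analyses is the
per-sample median (configurable to mean) of signature-gene log2 values.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionMatrix

__all__ = [
    "GROUPS",
    "gene_direction_scores",
    "tcell_score",
    "classify_phenotype",
    "signature_expression",
    "correlate",
    "score_cohort",
]

GROUPS = ("non_inflamed", "intermediate", "inflamed")


def _present_genes(expr: ExpressionMatrix, genes: Iterable[str]) -> list[str]:
    genes = list(dict.fromkeys(genes))
    if len(genes) == 0:
        raise ValueError("empty signature gene list")
    present = [g for g in genes if g in expr.gene_ids]
    missing = sorted(set(genes) - set(present))
    if missing:
        warnings.warn(
            f"{len(missing)} signature genes absent from matrix and dropped: "
            f"{missing[:10]}{'...' if len(missing) > 10 else ''}",
            stacklevel=3,
        )
    if not present:
        raise ValueError("no signature gene present in the expression matrix")
    return present


def gene_direction_scores(expr: ExpressionMatrix, genes: Sequence[str]) -> pd.DataFrame:
    """Discretize each signature gene per sample: +1 / -1 / 0 versus its
    cross-sample mean (strict inequalities; exact equality scores 0)."""
    present = _present_genes(expr, genes)
    sub = expr.values.loc[present]
    centered = sub.sub(sub.mean(axis=1), axis=0)
    return np.sign(centered).astype(int)


def tcell_score(direction_matrix: pd.DataFrame) -> pd.Series:
    """Per-sample signature score: column sum of the direction matrix."""
    return direction_matrix.sum(axis=0).astype(int)


def classify_phenotype(scores, n_genes: int):
    """Map scores to phenotype groups with strict thresholds at +/- G/2.

    Accepts a scalar or a Series; scores outside [-G, +G] are an error.
    """
    arr = pd.Series(scores, dtype=float) if not np.isscalar(scores) else None
    vals = arr.to_numpy() if arr is not None else np.array([scores], dtype=float)
    if (np.abs(vals) > n_genes).any():
        raise ValueError(f"score outside [-{n_genes}, +{n_genes}]")
    half = n_genes / 2.0
    labels = np.where(vals < -half, "non_inflamed",
                      np.where(vals > half, "inflamed", "intermediate"))
    if arr is None:
        return labels[0]
    return pd.Series(pd.Categorical(labels, categories=GROUPS), index=arr.index)


def signature_expression(expr: ExpressionMatrix, genes: Sequence[str],
                         aggregator: str = "median") -> pd.Series:
    """Continuous per-sample aggregate of signature-gene log2 expression."""
    if aggregator not in ("median", "mean"):
        raise ValueError(f"unknown aggregator {aggregator!r}")
    present = _present_genes(expr, genes)
    return getattr(expr.values.loc[present], aggregator)(axis=0)


def correlate(x, y) -> tuple[float, float]:
    """Two-sided Pearson correlation between two aligned vectors.

    Returns (r, p); zero variance in either input is an error that names
    the offending input.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if xa.size < 3:
        raise ValueError("Pearson correlation requires n >= 3")
    if not (np.isfinite(xa).all() and np.isfinite(ya).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(xa) == 0:
        raise ValueError("first input has zero variance")
    if np.ptp(ya) == 0:
        raise ValueError("second input has zero variance")
    res = stats.pearsonr(xa, ya)
    return float(res.statistic), float(res.pvalue)


def score_cohort(expr: ExpressionMatrix, genes: Sequence[str],
                 aggregator: str = "median") -> pd.DataFrame:
    """Score and classify every sample in one pass.

    Returns a DataFrame indexed by sample with columns ``score`` (integer),
    ``group`` (non_inflamed / intermediate / inflamed) and
    ``signature_expression``.  Thresholds track the effective signature
    size: genes missing from the matrix shrink G.
    """
    if expr.state != "log2":
        raise ValueError(f"expected log2 expression, got state {expr.state!r}")
    directions = gene_direction_scores(expr, genes)
    scores = tcell_score(directions)
    groups = classify_phenotype(scores, n_genes=directions.shape[0])
    sig = signature_expression(expr, list(directions.index), aggregator=aggregator)
    return pd.DataFrame(
        {"score": scores, "group": groups, "signature_expression": sig}
    )
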
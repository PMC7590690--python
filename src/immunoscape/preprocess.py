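"""Count normalization: upper-quartile scaling, TMM/CPM, log2, CPM filter.

Upper-quartile scaling equalizes the 75th percentile of each sample's
nonzero counts.  TMM (trimmed mean of M-values) estimates one scale factor
per sample from the doubly trimmed, precision-weighted mean of gene-wise
log ratios against a reference sample, then converts to counts per million
using the factor-adjusted library size.  Both are composition-based: they
are invariant to pure sequencing-depth differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ExpressionMatrix

__all__ = [
    "NormalizationFactors",
    "upper_quartile_normalize",
    "tmm_factors",
    "tmm_cpm",
    "log2_transform",
    "filter_low_expression",
]


@dataclass
class NormalizationFactors:
    """Per-sample scale factors with the method that produced them."""

    factors: pd.Series  # sample_id -> factor, dimensionless, > 0
    method: str  # "upper_quartile" | "TMM"

    def __post_init__(self) -> None:
        arr = self.factors.to_numpy(dtype=float)
        if not np.isfinite(arr).all() or (arr <= 0).any():
            raise ValueError("normalization factors must be finite and positive")


def _require_counts(counts: ExpressionMatrix) -> np.ndarray:
    if counts.state != "raw_counts":
        raise ValueError(f"expected raw_counts matrix, got state {counts.state!r}")
    return counts.values.to_numpy(dtype=float)


def upper_quartile_normalize(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample so its upper quartile of nonzero counts matches
    the cross-sample mean upper quartile.

    Raises an error naming any sample whose counts are all zero.
    """
    x = _require_counts(counts)
    q75 = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        nz = x[:, j][x[:, j] > 0]
        if nz.size == 0:
            raise ValueError(
                f"sample {counts.sample_ids[j]!r} has all-zero counts"
            )
        q75[j] = np.percentile(nz, 75)
    target = q75.mean()
    scaled = x * (target / q75)[np.newaxis, :]
    return ExpressionMatrix(
        pd.DataFrame(scaled, index=counts.gene_ids, columns=counts.sample_ids),
        "normalized",
    )


def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray, lib_obs: float,
                     lib_ref: float, trim_m: float, trim_a: float) -> float:
    """log2 TMM factor of one sample against the reference.

    Genes must be nonzero in both samples to contribute.  M is the log2
    ratio of relative abundances, A the average log2 abundance; the central
    (1 - 2*trim) of each is kept (double trim) and the retained M values
    are averaged with inverse asymptotic-binomial-variance weights.
    """
    both = (obs > 0) & (ref > 0)
    if not both.any():
        raise ValueError("sample shares no nonzero genes with the reference")
    o, r = obs[both], ref[both]
    m = np.log2((o / lib_obs) / (r / lib_ref))
    a = 0.5 * (np.log2(o / lib_obs) + np.log2(r / lib_ref))
    # precision weight: delta-method variance of M for binomial counts
    v = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    if np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank(method="average").to_numpy()
    rank_a = pd.Series(a).rank(method="average").to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    return float(np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep]))


def tmm_factors(counts: ExpressionMatrix, trim_m: float = 0.30,
                trim_a: float = 0.05) -> NormalizationFactors:
    """TMM scale factors, centered to geometric mean 1.

    The reference sample is the one whose upper-quartile fraction of its
    library is closest to the cross-sample mean.
    """
    x = _require_counts(counts)
    if x.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    lib = x.sum(axis=0)
    if (lib == 0).any():
        j = int(np.argmax(lib == 0))
        raise ValueError(f"sample {counts.sample_ids[j]!r} has all-zero counts")
    f75 = np.array([np.quantile(x[:, j], 0.75) for j in range(x.shape[1])]) / lib
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    log_f = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        if j == ref_idx:
            continue
        log_f[j] = _tmm_pair_factor(
            x[:, j], x[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a
        )
    factors = 2.0 ** log_f
    factors = factors / np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return NormalizationFactors(
        pd.Series(factors, index=counts.sample_ids), "TMM"
    )


def tmm_cpm(counts: ExpressionMatrix, trim_m: float = 0.30,
            trim_a: float = 0.05) -> ExpressionMatrix:
    """TMM-normalized counts per million: counts / (library size x factor) x 1e6."""
    nf = tmm_factors(counts, trim_m=trim_m, trim_a=trim_a)
    x = counts.values.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    eff = lib * nf.factors.to_numpy()
    cpm = x / eff[np.newaxis, :] * 1e6
    return ExpressionMatrix(
        pd.DataFrame(cpm, index=counts.gene_ids, columns=counts.sample_ids),
        "normalized",
    )


def log2_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(value + pseudocount); input values must be nonnegative."""
    x = matrix.values.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("log2_transform requires nonnegative input values")
    return ExpressionMatrix(
        pd.DataFrame(np.log2(x + pseudocount), index=matrix.gene_ids,
                     columns=matrix.sample_ids),
        "log2",
    )


def filter_low_expression(matrix: ExpressionMatrix, threshold: float = 3.0,
                          aggregator: str = "median") -> ExpressionMatrix:
    """Drop lowly expressed genes: aggregate CPM <= threshold (inclusive).

    ``aggregator`` is the per-gene cross-sample summary ("median" or
    "mean").  An empty result is allowed but warned about.
    """
    if aggregator not in ("median", "mean"):
        raise ValueError(f"unknown aggregator {aggregator!r}")
    agg = getattr(matrix.values, aggregator)(axis=1)
    keep = agg > threshold
    if not keep.any():
        warnings.warn("low-expression filter removed every gene", stacklevel=2)
    return ExpressionMatrix(matrix.values.loc[keep], matrix.state)
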
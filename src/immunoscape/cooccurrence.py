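"""Per-sample burden of immune-exclusion lesions and its heterogeneity.

Each non-inflamed sample gets an NSSM score (number of flagged genes it
carries mutations in) and a pathway score (number of pathways called
active in it).  Scores are collapsed into categories 0..cap (default 10),
and per-tumor-type category distributions (percent) are compared through
their Euclidean distance from the cross-type mean distribution; the two
resulting distance samples (mutation vs pathway) are compared with a
two-sided two-sample Kolmogorov-Smirnov test.  The relationship between
burden and signature expression is modeled by OLS on the per-category
median expression, with quadratic and cubic alternatives screened by a
likelihood-ratio test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import ClinicalTable, ExpressionMatrix
from .mutation import MutationSet
from .validation import pathway_expression

__all__ = [
    "RegressionFit",
    "burden_scores",
    "collapse_category",
    "category_distribution",
    "heterogeneity_distances",
    "ks_compare",
    "score_expression_regression",
    "per_sample_pathway_calls",
    "fisher_2x2",
]


def burden_scores(mutset: MutationSet, flagged_genes: Sequence[str],
                  pathway_calls: pd.DataFrame) -> pd.DataFrame:
    """Count flagged mutated genes and active pathways per sample.

    ``pathway_calls`` is a boolean pathways x samples frame.  Returns a
    frame indexed by sample with integer ``nssm_score`` and
    ``pathway_score`` columns (samples = union of both inputs; missing
    entries count 0).
    """
    flagged = [g for g in flagged_genes if g in mutset.genes]
    missing = set(flagged_genes) - set(flagged)
    if missing:
        warnings.warn(
            f"{len(missing)} flagged genes absent from mutation matrix",
            stacklevel=2,
        )
    nssm = mutset.matrix.loc[flagged].sum(axis=0) if flagged else pd.Series(
        0, index=mutset.samples
    )
    pw = pathway_calls.astype(bool).sum(axis=0) if len(pathway_calls) else pd.Series(
        0, index=pathway_calls.columns
    )
    samples = nssm.index.union(pw.index)
    return pd.DataFrame(
        {
            "nssm_score": nssm.reindex(samples, fill_value=0).astype(int),
            "pathway_score": pw.reindex(samples, fill_value=0).astype(int),
        }
    )


def collapse_category(score, cap: int = 10):
    """min(score, cap); scores above the cap collapse into category ``cap``."""
    if cap < 0:
        raise ValueError("cap must be >= 0")
    arr = np.asarray(score)
    if (arr < 0).any():
        raise ValueError("scores must be nonnegative")
    out = np.minimum(arr, cap)
    if np.isscalar(score):
        return int(out)
    if isinstance(score, pd.Series):
        return pd.Series(out, index=score.index)
    return out


def category_distribution(categories: pd.Series, clinical: ClinicalTable,
                          cap: int = 10) -> pd.DataFrame:
    """Percent of samples in each category 0..cap, per tumor type.

    ``categories`` holds already collapsed integer categories for the
    samples under study (callers restrict to non-inflamed samples).
    Tumor types without any such sample are skipped with a warning.
    Rows sum to 100.
    """
    rows = {}
    for ttype, sub in clinical.tumor_type.groupby(clinical.tumor_type):
        vals = categories.loc[[s for s in sub.index if s in categories.index]]
        if len(vals) == 0:
            warnings.warn(f"tumor type {ttype!r} has no samples; skipped", stacklevel=2)
            continue
        counts = np.bincount(vals.to_numpy(dtype=int), minlength=cap + 1)
        rows[str(ttype)] = counts / counts.sum() * 100.0
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(range(cap + 1)))


def heterogeneity_distances(distributions: pd.DataFrame) -> pd.Series:
    """Euclidean distance of each tumor type's category-percentage vector
    from the arithmetic-mean distribution across types."""
    if len(distributions) < 2:
        raise ValueError("need >= 2 tumor types")
    mean = distributions.mean(axis=0)
    diff = distributions.sub(mean, axis=1)
    return np.sqrt((diff ** 2).sum(axis=1))


def ks_compare(distances_a, distances_b) -> tuple[float, float]:
    """Two-sided two-sample KS test (exact for small samples)."""
    a = np.asarray(distances_a, dtype=float)
    b = np.asarray(distances_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 values")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


@dataclass
class RegressionFit:
    """Burden-vs-expression model fit summary."""

    betas: np.ndarray          # coefficients of the chosen model, degree order
    chosen_degree: int
    adjusted_r2: float         # of the linear fit
    slope_p: float             # p of the linear slope
    lrt_p_quadratic: float     # degree 2 vs 1
    lrt_p_cubic: float         # degree 3 vs 1
    points: pd.DataFrame       # (score, median_expression, n) used in the fit


def _ols_poly(x: np.ndarray, y: np.ndarray, degree: int):
    X = np.vander(x, degree + 1, increasing=True)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float((resid ** 2).sum())


def _gaussian_lrt(rss0: float, rss1: float, n: int, df_diff: int) -> float:
    if rss1 <= 0:
        return 0.0
    lr = n * np.log(rss0 / rss1)
    return float(stats.chi2.sf(max(lr, 0.0), df_diff))


def score_expression_regression(scores: pd.Series, signature_expr: pd.Series,
                                min_samples_per_category: int = 10,
                                max_degree: int = 3) -> RegressionFit:
    """OLS of per-category median signature expression on the (uncollapsed)
    burden score, with polynomial alternatives screened by LRT.

    Categories with fewer than ``min_samples_per_category`` samples are
    dropped; at least 3 surviving categories are required.  The chosen
    model is the lowest degree not beaten at P < 0.05 by a higher-degree
    nested alternative.
    """
    common = [s for s in scores.index if s in signature_expr.index]
    sc = scores.loc[common].astype(int)
    counts = sc.value_counts()
    keep = counts.index[counts >= min_samples_per_category]
    pts = []
    for cat in sorted(keep):
        members = sc.index[sc == cat]
        pts.append(
            {"score": int(cat),
             "median_expression": float(signature_expr.loc[members].median()),
             "n": int(len(members))}
        )
    points = pd.DataFrame(pts)
    if len(points) < 3:
        raise ValueError(
            f"only {len(points)} score categories with >= "
            f"{min_samples_per_category} samples; need >= 3"
        )
    x = points["score"].to_numpy(dtype=float)
    y = points["median_expression"].to_numpy(dtype=float)
    npts = len(x)

    beta1, rss1 = _ols_poly(x, y, 1)
    # linear-fit inference
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss1 / tss if tss > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * (npts - 1) / (npts - 2)
    se_num = rss1 / (npts - 2) if npts > 2 else 0.0
    sxx = float(((x - x.mean()) ** 2).sum())
    if se_num > 0 and sxx > 0:
        t = beta1[1] / np.sqrt(se_num / sxx)
        slope_p = float(2.0 * stats.t.sf(abs(t), npts - 2))
    else:
        slope_p = 0.0 if beta1[1] != 0 else 1.0

    lrt_p = {2: 1.0, 3: 1.0}
    fits = {1: (beta1, rss1)}
    for degree in (2, 3):
        if degree > max_degree or npts <= degree + 1:
            continue
        beta_d, rss_d = _ols_poly(x, y, degree)
        fits[degree] = (beta_d, rss_d)
        lrt_p[degree] = _gaussian_lrt(rss1, rss_d, npts, degree - 1)
    if lrt_p[2] < 0.05 and 2 in fits:
        chosen = 2
    elif lrt_p[3] < 0.05 and 3 in fits:
        chosen = 3
    else:
        chosen = 1
    return RegressionFit(
        betas=fits[chosen][0],
        chosen_degree=chosen,
        adjusted_r2=float(adj_r2),
        slope_p=slope_p,
        lrt_p_quadratic=float(lrt_p[2]),
        lrt_p_cubic=float(lrt_p[3]),
        points=points,
    )


def per_sample_pathway_calls(expr: ExpressionMatrix,
                             pathway_genes: Mapping[str, Sequence[str]],
                             strata: Optional[pd.Series] = None) -> pd.DataFrame:
    """Binarize pathway activity per sample: active when the sample's
    pathway expression exceeds the within-stratum median.

    ``pathway_genes`` maps each activated pathway to its gene list;
    ``strata`` maps sample -> tumor type (one pooled stratum when None).
    Returns a boolean pathways x samples frame.
    """
    samples = list(expr.sample_ids)
    if strata is None:
        strata = pd.Series("all", index=samples)
    strata = strata.loc[[s for s in strata.index if s in samples]]
    calls = pd.DataFrame(False, index=list(pathway_genes), columns=samples)
    for name, genes in pathway_genes.items():
        values = pathway_expression(expr, list(genes))
        for _, sub in strata.groupby(strata):
            members = list(sub.index)
            vals = values.loc[members]
            calls.loc[name, members] = (vals > vals.median()).to_numpy()
    return calls


def fisher_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a user-supplied 2x2 table."""
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("expected a nonnegative 2x2 table")
    odds, p = stats.fisher_exact(arr, alternative="two-sided")
    return float(odds), float(p)
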
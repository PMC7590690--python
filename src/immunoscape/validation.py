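"""Cross-cohort validation of pathway activation.

Pathway expression (per-sample median log2 over a pathway's genes) is
correlated with the continuous T cell-inflamed signature expression by
Pearson's test; each pathway gets a binary sign category (negative when
inversely correlated — the hypothesis direction).  Consistency between
two cohorts is the Jaccard coefficient over the sets of negatively
correlated features.  Protein-level validation applies the same
correlation to median-centered RPPA-style abundances within tumor-type
strata with BH-FDR per stratum, and the responder analysis is a
two-sided Welch t-test comparing pathway expression between RECIST
non-responders (PD/SD) and responders (PR/CR).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mutation import bh_fdr
from .signature import correlate
from .types import ExpressionMatrix

__all__ = [
    "pathway_expression",
    "correlate_with_signature",
    "jaccard_consistency",
    "rppa_correlate",
    "responder_compare",
]

_NR = {"PD", "SD"}
_R = {"PR", "CR"}


def pathway_expression(expr: ExpressionMatrix, pathway_genes: Sequence[str]) -> pd.Series:
    """Per-sample median log2 expression over a pathway's genes."""
    present = [g for g in dict.fromkeys(pathway_genes) if g in expr.gene_ids]
    if not present:
        raise ValueError("no pathway gene present in the expression matrix")
    return expr.values.loc[present].median(axis=0)


def correlate_with_signature(values: pd.Series, signature_expr: pd.Series,
                             feature: str = "", stratum: str = "") -> dict:
    """Pearson r / p / sign of one feature against signature expression.

    Sample sets must match exactly (order-insensitive).
    """
    if set(values.index) != set(signature_expr.index):
        raise ValueError("feature values and signature expression sample sets differ")
    sig = signature_expr.loc[values.index]
    r, p = correlate(values.to_numpy(), sig.to_numpy())
    return {
        "feature": feature,
        "stratum": stratum,
        "r": r,
        "p": p,
        "sign": "negative" if r < 0 else "positive",
    }


def jaccard_consistency(signs_a: pd.Series, signs_b: pd.Series) -> float:
    """Jaccard coefficient over the negatively correlated feature sets.

    Both inputs map the same features to 'negative' / 'positive'.  Returns
    |A ∩ B| / |A ∪ B| where A, B collect the features labeled negative in
    each cohort; NaN (with a warning) when neither cohort has a negative
    feature.
    """
    if set(signs_a.index) != set(signs_b.index):
        raise ValueError("sign vectors must cover the same feature set")
    for s in (signs_a, signs_b):
        bad = set(s.unique()) - {"negative", "positive"}
        if bad:
            raise ValueError(f"invalid sign labels: {sorted(bad)}")
    a = set(signs_a.index[signs_a == "negative"])
    b = set(signs_b.index[signs_b == "negative"])
    union = a | b
    if not union:
        warnings.warn("no negatively correlated feature in either cohort", stacklevel=2)
        return float("nan")
    return len(a & b) / len(union)


def rppa_correlate(protein_matrix: pd.DataFrame, signature_expr: pd.Series,
                   strata: pd.Series) -> pd.DataFrame:
    """Protein abundance vs signature expression, per protein per stratum.

    ``protein_matrix`` is proteins x samples of median-centered
    abundances; ``strata`` maps sample -> tumor type.  BH-FDR is applied
    within each stratum.  Strata with fewer than 3 samples are skipped
    with a warning.
    """
    rows = []
    for ttype, sub in strata.groupby(strata):
        samples = [s for s in sub.index
                   if s in protein_matrix.columns and s in signature_expr.index]
        if len(samples) < 3:
            warnings.warn(f"stratum {ttype!r} skipped: n < 3", stacklevel=2)
            continue
        sig = signature_expr.loc[samples].to_numpy()
        for protein in protein_matrix.index:
            vals = protein_matrix.loc[protein, samples].to_numpy(dtype=float)
            if np.ptp(vals) == 0 or np.ptp(sig) == 0:
                continue
            r, p = correlate(vals, sig)
            rows.append(
                {"feature": protein, "stratum": str(ttype), "r": r, "p": p,
                 "sign": "negative" if r < 0 else "positive"}
            )
    out = pd.DataFrame(rows, columns=["feature", "stratum", "r", "p", "sign"])
    out["fdr"] = np.nan
    for _, idx in out.groupby("stratum").groups.items():
        out.loc[idx, "fdr"] = bh_fdr(out.loc[idx, "p"])
    return out


def summarize_rppa(table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Share of correlations that are negative / FDR-significant."""
    n = len(table)
    if n == 0:
        return {"n": 0, "share_negative": float("nan"), "share_significant": float("nan")}
    return {
        "n": n,
        "share_negative": float((table["sign"] == "negative").mean()),
        "share_significant": float((table["fdr"] < alpha).mean()),
    }


def responder_compare(values: pd.Series, response: pd.Series) -> dict:
    """Welch two-sample t-test of pathway expression, NR (PD/SD) vs R (PR/CR).

    Returns t, two-sided p (Satterthwaite df), group means and sizes.
    The t statistic is oriented NR minus R.
    """
    resp = response.dropna()
    labels = resp.map(lambda v: "NR" if v in _NR else ("R" if v in _R else None)).dropna()
    common = [s for s in labels.index if s in values.index]
    nr = values.loc[[s for s in common if labels[s] == "NR"]].to_numpy(dtype=float)
    r = values.loc[[s for s in common if labels[s] == "R"]].to_numpy(dtype=float)
    if len(nr) < 2 or len(r) < 2:
        raise ValueError(f"need >= 2 samples per group (NR={len(nr)}, R={len(r)})")
    res = stats.ttest_ind(nr, r, equal_var=False)
    return {
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "mean_nr": float(nr.mean()),
        "mean_r": float(r.mean()),
        "n_nr": len(nr),
        "n_r": len(r),
    }
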
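"""Differential expression and upstream-regulator activation prediction.

Differential expression between non-inflamed and inflamed samples uses a
per-gene two-group linear model on log2 expression with optional
observation-level precision weights derived from a lowess mean-variance
trend (square-root residual SD versus average abundance), and
empirical-Bayes moderation of the gene-wise variances.  Significant genes
satisfy FDR < 0.05 and |linear fold change| >= 1.5, with fold change
signed the conventional way (down = -2^|delta|).

Upstream regulators are scored against a signed regulator -> target
network: a hypergeometric overlap p measures enrichment of a regulator's
targets among the DEGs, and the unit-weight activation z-score

    z = sum(edge_sign * deg_direction) / sqrt(n_overlap)

measures sign consistency; positive z predicts activation in the
non-inflamed group.  Regulators with overlap p < 0.05 and z > 1.95
(strict) are called activated, and pathways sharing activated regulators
are linked into an undirected weighted network.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

import networkx as nx

from .mutation import bh_fdr
from .types import CausalNetwork, ExpressionMatrix

__all__ = [
    "differential_expression",
    "regulator_overlap_p",
    "activation_zscore",
    "select_activated",
    "run_activation",
    "build_pathway_network",
]


def _fit_f_dist(variances: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F prior to gene-wise variances (empirical
    Bayes).  Returns (prior df d0, prior variance s0^2); d0 = inf when the
    observed spread of log-variances is no larger than expected by chance.
    """
    s2 = np.maximum(variances, 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if not np.isfinite(evar) or evar <= 0:
        return np.inf, float(np.exp(emean))
    # invert trigamma(d0/2) = evar by Newton iteration
    x = 0.5 + 1.0 / evar
    for _ in range(50):
        tri = special.polygamma(1, x)
        delta = tri * (1.0 - tri / evar) / special.polygamma(2, x)
        x = x + delta
        if abs(delta) < 1e-10 * x:
            break
    d0 = 2.0 * x
    s0sq = float(np.exp(emean + special.digamma(x) - np.log(x)))
    return float(d0), s0sq


def differential_expression(expr: ExpressionMatrix, groups: pd.Series,
                            use_weights: bool = True, moderate: bool = True,
                            fdr_threshold: float = 0.05,
                            fc_threshold: float = 1.5,
                            lowess_frac: float = 0.5) -> pd.DataFrame:
    """Two-group DE: non-inflamed minus inflamed on log2 expression.

    ``groups`` maps sample -> 'non_inflamed' | 'inflamed' (>= 3 samples
    each).  Returns per-gene log2_fold_change, linear_fold_change (signed),
    p_value, fdr, significant.  Zero-variance genes get p = NA and are
    excluded from the FDR family.  With ``use_weights=False`` and
    ``moderate=False`` the statistic reduces to the ordinary pooled
    two-sample t-test.
    """
    if expr.state != "log2":
        raise ValueError(f"expected log2 expression, got state {expr.state!r}")
    groups = groups.dropna()
    groups = groups[groups.isin(["non_inflamed", "inflamed"])]
    samples = [s for s in groups.index if s in expr.sample_ids]
    g = groups.loc[samples]
    n_ni = int((g == "non_inflamed").sum())
    n_i = int((g == "inflamed").sum())
    if n_ni < 3 or n_i < 3:
        raise ValueError(
            f"need >= 3 samples per group (non_inflamed={n_ni}, inflamed={n_i})"
        )
    Y = expr.values[samples].to_numpy(dtype=float)  # genes x n
    x = (g == "non_inflamed").to_numpy(dtype=float)  # 1 = non-inflamed
    n = x.size
    X = np.column_stack([np.ones(n), x])

    def fit(weights: Optional[np.ndarray]):
        """Per-gene WLS of Y on [1, x]; returns beta1, residual var, var factor."""
        if weights is None:
            XtX = X.T @ X
            XtXinv = np.linalg.inv(XtX)
            beta = Y @ X @ XtXinv.T  # genes x 2
            resid = Y - beta @ X.T
            s2 = (resid ** 2).sum(axis=1) / (n - 2)
            v11 = np.full(Y.shape[0], XtXinv[1, 1])
            fitted = beta @ X.T
            return beta[:, 1], s2, v11, fitted
        b1 = np.empty(Y.shape[0])
        s2 = np.empty(Y.shape[0])
        v11 = np.empty(Y.shape[0])
        fitted = np.empty_like(Y)
        for i in range(Y.shape[0]):
            w = weights[i]
            Xw = X * w[:, None]
            XtX = X.T @ Xw
            XtXinv = np.linalg.inv(XtX)
            beta = XtXinv @ (Xw.T @ Y[i])
            fit_i = X @ beta
            r = Y[i] - fit_i
            s2[i] = (w * r ** 2).sum() / (n - 2)
            b1[i] = beta[1]
            v11[i] = XtXinv[1, 1]
            fitted[i] = fit_i
        return b1, s2, v11, fitted

    beta1, s2, v11, fitted = fit(None)
    if use_weights:
        # mean-variance trend: sqrt residual SD vs average abundance,
        # evaluated at each fitted value to give observation weights
        amean = Y.mean(axis=1)
        sqrt_sd = np.sqrt(np.sqrt(np.maximum(s2, 1e-12)))
        order = np.argsort(amean)
        trend = lowess(sqrt_sd[order], amean[order], frac=lowess_frac,
                       return_sorted=True)
        tx, ty = trend[:, 0], np.maximum(trend[:, 1], 1e-6)
        pred = np.interp(fitted, tx, ty)
        weights = 1.0 / pred ** 4
        beta1, s2, v11, fitted = fit(weights)

    df_resid = float(n - 2)
    constant = np.ptp(Y, axis=1) == 0
    nonzero = ~constant & (s2 > 1e-300)
    if moderate and nonzero.sum() >= 10:
        d0, s0sq = _fit_f_dist(s2[nonzero], df_resid)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0sq)
            df_total = np.inf
        else:
            s2_post = (d0 * s0sq + df_resid * s2) / (d0 + df_resid)
            df_total = df_resid + d0
    else:
        s2_post = s2
        df_total = df_resid

    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta1 / np.sqrt(s2_post * v11)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(nonzero, p, np.nan)

    lfc = beta1
    linear_fc = np.sign(lfc) * 2.0 ** np.abs(lfc)
    linear_fc = np.where(lfc == 0, 1.0, linear_fc)
    out = pd.DataFrame(
        {
            "gene": expr.gene_ids,
            "log2_fold_change": lfc,
            "linear_fold_change": linear_fc,
            "p_value": p,
        }
    ).set_index("gene")
    out["fdr"] = np.nan
    mask = out["p_value"].notna()
    if mask.any():
        out.loc[mask, "fdr"] = bh_fdr(out.loc[mask, "p_value"])
    out["significant"] = (out["fdr"] < fdr_threshold) & (
        np.abs(out["linear_fold_change"]) >= fc_threshold
    )
    return out


def regulator_overlap_p(network: CausalNetwork, deg_genes: Iterable[str],
                        universe: Iterable[str]) -> pd.Series:
    """Hypergeometric upper-tail P(X >= overlap) per regulator.

    Targets are intersected with the universe first; a regulator with no
    in-universe target gets NA.
    """
    universe = set(universe)
    degs = set(deg_genes)
    if not degs <= universe:
        raise ValueError("deg_genes must be a subset of the universe")
    M, K = len(universe), len(degs)
    out = {}
    for reg in network.regulators():
        targets = set(network.targets_of(reg)["target"]) & universe
        if not targets:
            out[reg] = np.nan
            continue
        k = len(targets & degs)
        out[reg] = float(stats.hypergeom.sf(k - 1, M, K, len(targets)))
    return pd.Series(out, name="overlap_p")


def activation_zscore(network: CausalNetwork,
                      deg_directions: Mapping[str, int]) -> pd.DataFrame:
    """Unit-weight sign-consistency z per regulator.

    ``deg_directions`` maps significant DEGs to +1 (up in non-inflamed) or
    -1.  z = sum(edge_sign * direction) / sqrt(n_overlap); regulators with
    no DEG-overlapping target get NA.
    """
    dirs = pd.Series(deg_directions, dtype=float)
    if not dirs.isin([-1.0, 1.0]).all():
        raise ValueError("DEG directions must be +1 or -1")
    rows = []
    for reg in network.regulators():
        edges = network.targets_of(reg)
        hit = edges[edges["target"].isin(dirs.index)]
        n = len(hit)
        if n == 0:
            rows.append({"regulator": reg, "activation_z": np.nan, "n_overlap": 0})
            continue
        z = float(
            (hit["sign"].to_numpy() * dirs.loc[hit["target"]].to_numpy()).sum()
            / np.sqrt(n)
        )
        rows.append({"regulator": reg, "activation_z": z, "n_overlap": n})
    return pd.DataFrame(rows).set_index("regulator")


def select_activated(table: pd.DataFrame, p_cut: float = 0.05,
                     z_cut: float = 1.95) -> pd.DataFrame:
    """Strict thresholds: overlap_p < p_cut and activation_z > z_cut."""
    ok = (table["overlap_p"] < p_cut) & (table["activation_z"] > z_cut)
    out = table.copy()
    out["activated"] = ok.fillna(False)
    return out


def run_activation(expr: ExpressionMatrix, groups: pd.Series,
                   network: CausalNetwork, stratum: str = "pan-cancer",
                   fdr_threshold: float = 0.05, fc_threshold: float = 1.5,
                   p_cut: float = 0.05, z_cut: float = 1.95,
                   use_weights: bool = True) -> pd.DataFrame:
    """DE -> overlap p -> activation z -> activated flag, in one stratum.

    The hypergeometric universe is the set of genes tested for DE.
    """
    deg = differential_expression(
        expr, groups, use_weights=use_weights,
        fdr_threshold=fdr_threshold, fc_threshold=fc_threshold,
    )
    sig = deg[deg["significant"]]
    universe = deg.index[deg["p_value"].notna()]
    overlap = regulator_overlap_p(network, sig.index, universe)
    dirs = np.sign(sig["log2_fold_change"]).astype(int)
    dirs = dirs[dirs != 0]
    z = activation_zscore(network, dirs.to_dict())
    table = z.join(overlap)
    table = select_activated(table, p_cut=p_cut, z_cut=z_cut)
    table["stratum"] = stratum
    return table.reset_index()[
        ["regulator", "stratum", "overlap_p", "activation_z", "n_overlap", "activated"]
    ]


def build_pathway_network(activated_regulators: Iterable[str],
                          annotation: Mapping[str, set[str]]) -> nx.Graph:
    """Undirected pathway network weighted by shared activated regulators.

    Nodes are pathways annotated to >= 1 activated regulator; an edge's
    ``weight`` counts the activated regulators shared by the two pathways;
    zero-weight pairs are omitted.
    """
    members: dict[str, set[str]] = {}
    for reg in activated_regulators:
        for pw in annotation.get(reg, set()):
            members.setdefault(pw, set()).add(reg)
    graph = nx.Graph()
    graph.add_nodes_from(members)
    pathways = sorted(members)
    for i, a in enumerate(pathways):
        for b in pathways[i + 1:]:
            shared = len(members[a] & members[b])
            if shared > 0:
                graph.add_edge(a, b, weight=shared)
    return graph
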
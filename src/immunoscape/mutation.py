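"""Mutation enrichment against the inflamed / non-inflamed phenotype.

Variants are reduced to NSSM (non-synonymous somatic mutation) calls:
protein-altering SNVs, small indels and splice-site variants.  Tumor
mutational burden (TMB) is the NSSM count per sample, and a binary
gene x sample matrix records whether a sample carries >= 1 NSSM in a
gene.  The per-gene association with phenotype is a logistic regression

    logit P(non_inflamed) = b0 + b1 * mutated + b2 * log10(TMB + 1)

so TMB-driven mutation prevalence does not masquerade as a phenotype
association.  b1 is reported in logits; positive values mean enrichment
in the non-T cell-inflamed group.  Genes mutated in < 5% of a tumor type
(or < 0.5% pan-cancer) are excluded before testing, and Wald p-values of
the mutation-status term are Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml
from statsmodels.stats.multitest import multipletests

from .types import ClinicalTable, VariantRecord

__all__ = [
    "MutationSet",
    "load_nssm_vocabulary",
    "is_nssm",
    "build_mutation_set",
    "frequency_filter",
    "logistic_enrichment",
    "bh_fdr",
    "run_enrichment",
    "mutation_frequency_table",
]

_DEFAULT_VOCAB: Optional[dict[str, bool]] = None
_warned_tokens: set[str] = set()


def load_nssm_vocabulary(path=None) -> dict[str, bool]:
    """Load the variant-classification -> NSSM map (packaged default YAML,
    or a user-supplied file of the same shape)."""
    global _DEFAULT_VOCAB
    if path is None:
        if _DEFAULT_VOCAB is None:
            ref = importlib.resources.files("immunoscape.data") / "nssm_classes.yaml"
            _DEFAULT_VOCAB = yaml.safe_load(ref.read_text())
        return dict(_DEFAULT_VOCAB)
    with open(path) as fh:
        return yaml.safe_load(fh)


def is_nssm(record: VariantRecord, vocabulary: Optional[Mapping[str, bool]] = None) -> bool:
    """True iff the record's classification is protein-altering.

    Unknown classification tokens are treated as non-NSSM with a one-time
    warning per token.
    """
    vocab = vocabulary if vocabulary is not None else load_nssm_vocabulary()
    token = record.variant_classification
    if token not in vocab:
        if token not in _warned_tokens:
            _warned_tokens.add(token)
            warnings.warn(
                f"unknown variant classification {token!r}; treated as non-NSSM",
                stacklevel=2,
            )
        return False
    return bool(vocab[token])


@dataclass
class MutationSet:
    """Binary NSSM gene x sample matrix plus per-sample TMB.

    ``matrix`` entries are 0/1; ``tmb`` counts NSSM variants (not genes),
    so tmb >= number of mutated genes for every sample.
    """

    matrix: pd.DataFrame
    tmb: pd.Series

    def __post_init__(self) -> None:
        vals = self.matrix.to_numpy()
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("mutation matrix entries must be 0/1")
        if (self.tmb < 0).any():
            raise ValueError("TMB must be nonnegative")
        if not self.matrix.columns.equals(self.tmb.index):
            raise ValueError("matrix samples and TMB index misaligned")
        genes_per_sample = self.matrix.sum(axis=0)
        if (self.tmb < genes_per_sample).any():
            raise ValueError("TMB cannot be below the number of mutated genes")

    @property
    def samples(self) -> pd.Index:
        return self.matrix.columns

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index


def build_mutation_set(records: Iterable[VariantRecord], samples: Sequence[str],
                       vocabulary: Optional[Mapping[str, bool]] = None) -> MutationSet:
    """Tally NSSM records into the binary matrix and TMB counts.

    ``samples`` is the sample universe: samples with no variants get
    all-zero rows and TMB 0; a record for a sample outside the universe is
    an error listing the orphans.
    """
    samples = list(samples)
    sample_set = set(samples)
    vocab = vocabulary if vocabulary is not None else load_nssm_vocabulary()
    tmb = {s: 0 for s in samples}
    mutated: dict[str, set[str]] = {}
    orphans = set()
    for rec in records:
        if rec.sample_id not in sample_set:
            orphans.add(rec.sample_id)
            continue
        if not is_nssm(rec, vocab):
            continue
        tmb[rec.sample_id] += 1
        mutated.setdefault(rec.gene_symbol, set()).add(rec.sample_id)
    if orphans:
        raise ValueError(
            f"variant records reference samples outside the universe: "
            f"{sorted(orphans)[:10]}"
        )
    genes = sorted(mutated)
    matrix = pd.DataFrame(0, index=genes, columns=samples, dtype=np.int8)
    for gene, samps in mutated.items():
        matrix.loc[gene, list(samps)] = 1
    return MutationSet(matrix, pd.Series(tmb, index=samples, dtype=int))


def frequency_filter(mutset: MutationSet, clinical: Optional[ClinicalTable],
                     mode: str = "per_type", per_type_threshold: float = 5.0,
                     pan_threshold: float = 0.5):
    """Genes frequent enough to test, per the strict '<' exclusion rule.

    ``per_type`` mode returns {tumor_type: [genes with mutated fraction
    >= per_type_threshold % within that stratum]}; ``pan_cancer`` mode
    returns the list of genes mutated in >= pan_threshold % of all samples.
    Boundary frequencies are retained.
    """
    if mode == "pan_cancer":
        if not 0 < pan_threshold < 100:
            raise ValueError("pan_threshold must be in (0, 100)")
        frac = mutset.matrix.mean(axis=1) * 100
        return list(mutset.genes[frac >= pan_threshold])
    if mode != "per_type":
        raise ValueError(f"unknown mode {mode!r}")
    if not 0 < per_type_threshold < 100:
        raise ValueError("per_type_threshold must be in (0, 100)")
    if clinical is None:
        raise ValueError("per_type mode requires a clinical table")
    out: dict[str, list[str]] = {}
    for ttype, sub in clinical.tumor_type.groupby(clinical.tumor_type):
        stratum = [s for s in sub.index if s in mutset.samples]
        if len(stratum) == 0:
            raise ValueError(f"tumor type {ttype!r} has no samples in the mutation set")
        frac = mutset.matrix[stratum].mean(axis=1) * 100
        out[str(ttype)] = list(mutset.genes[frac >= per_type_threshold])
    return out


def logistic_enrichment(gene_status, group, tmb) -> tuple[float, float, bool]:
    """Fit logit P(non_inflamed) = b0 + b1*mutated + b2*log10(TMB+1).

    ``group`` is binary with 1 = non-inflamed.  Returns (b1, two-sided
    Wald p of b1, ok); when the fit does not converge or the data are
    separated, ok is False and the estimates are NaN — such genes are
    reported but excluded from FDR.
    """
    status = np.asarray(gene_status, dtype=float)
    y = np.asarray(group, dtype=float)
    logtmb = np.log10(np.asarray(tmb, dtype=float) + 1.0)
    if np.ptp(logtmb) == 0:
        # constant TMB is collinear with the intercept; the model reduces
        # to the covariate-free fit
        X = np.column_stack([np.ones_like(status), status])
    else:
        X = np.column_stack([np.ones_like(status), status, logtmb])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:
            return float("nan"), float("nan"), False
    converged = bool(fit.mle_retvals.get("converged", False))
    coef = float(fit.params[1])
    se = float(fit.bse[1])
    if not converged or not np.isfinite(se) or se > 50 or abs(coef) > 15:
        return float("nan"), float("nan"), False
    return coef, float(fit.pvalues[1]), True


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("NA p-values must be excluded before adjustment")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _enrich_stratum(mutset: MutationSet, samples: list[str], genes: list[str],
                    group01: pd.Series, stratum: str) -> pd.DataFrame:
    rows = []
    y = group01.loc[samples].to_numpy()
    tmb = mutset.tmb.loc[samples].to_numpy()
    for gene in genes:
        status = mutset.matrix.loc[gene, samples].to_numpy()
        coef, p, ok = logistic_enrichment(status, y, tmb)
        rows.append(
            {
                "gene": gene,
                "stratum": stratum,
                "coefficient": coef,
                "p_value": p,
                "ok": ok,
                "n_mutated": int(status.sum()),
                "n_total": len(samples),
            }
        )
    return pd.DataFrame(
        rows, columns=["gene", "stratum", "coefficient", "p_value", "ok",
                       "n_mutated", "n_total"],
    )


def run_enrichment(mutset: MutationSet, calls: pd.DataFrame,
                   clinical: Optional[ClinicalTable] = None,
                   mode: str = "pan_cancer", per_type_threshold: float = 5.0,
                   pan_threshold: float = 0.5,
                   fdr_cutoff: float = 0.10) -> pd.DataFrame:
    """Frequency-filter, fit the TMB-adjusted model per gene, BH-adjust.

    ``calls`` is the score_cohort output; intermediate samples are dropped
    here.  In ``per_type`` mode the FDR family is within each tumor type;
    in ``pan_cancer`` mode it spans all tested genes.  Strata where either
    phenotype group has < 2 samples are skipped with a warning.  Output
    columns: gene, stratum, coefficient (logits; positive = enriched in
    non-inflamed under the non_inflamed=1 coding), p_value, fdr, direction,
    significant, n_mutated, n_total, ok.
    """
    two_group = calls[calls["group"].isin(["non_inflamed", "inflamed"])]
    usable = [s for s in two_group.index if s in set(mutset.samples)]
    group01 = (two_group.loc[usable, "group"] == "non_inflamed").astype(int)

    def group_ok(samples: list[str]) -> bool:
        g = group01.loc[samples]
        return (g == 1).sum() >= 2 and (g == 0).sum() >= 2

    frames = []
    if mode == "pan_cancer":
        if not group_ok(usable):
            raise ValueError("need >= 2 samples in each phenotype group")
        sub = MutationSet(mutset.matrix[usable], mutset.tmb.loc[usable])
        genes = frequency_filter(sub, None, "pan_cancer", pan_threshold=pan_threshold)
        frames.append(_enrich_stratum(sub, usable, genes, group01, "pan-cancer"))
    elif mode == "per_type":
        if clinical is None:
            raise ValueError("per_type mode requires a clinical table")
        for ttype, csub in clinical.tumor_type.groupby(clinical.tumor_type):
            stratum = [s for s in csub.index if s in set(usable)]
            if len(stratum) == 0 or not group_ok(stratum):
                warnings.warn(
                    f"stratum {ttype!r} skipped: a phenotype group has < 2 samples",
                    stacklevel=2,
                )
                continue
            sub = MutationSet(mutset.matrix[stratum], mutset.tmb.loc[stratum])
            genes = frequency_filter(
                sub, None, "pan_cancer", pan_threshold=per_type_threshold
            )
            frames.append(_enrich_stratum(sub, stratum, genes, group01, str(ttype)))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if not frames:
        return pd.DataFrame(
            columns=["gene", "stratum", "coefficient", "p_value", "fdr",
                     "direction", "significant", "n_mutated", "n_total", "ok"]
        )
    result = pd.concat(frames, ignore_index=True)
    result["fdr"] = np.nan
    fam = "stratum" if mode == "per_type" else None
    if fam is None:
        mask = result["ok"].to_numpy()
        if mask.any():
            result.loc[mask, "fdr"] = bh_fdr(result.loc[mask, "p_value"])
    else:
        for _, idx in result.groupby(fam).groups.items():
            sub = result.loc[idx]
            mask = sub["ok"]
            if mask.any():
                result.loc[sub.index[mask], "fdr"] = bh_fdr(sub.loc[mask, "p_value"])
    result["direction"] = np.where(
        result["coefficient"] >= 0, "non_inflamed", "inflamed"
    )
    result.loc[~result["ok"], "direction"] = pd.NA
    result["significant"] = result["fdr"] < fdr_cutoff
    cols = ["gene", "stratum", "coefficient", "p_value", "fdr", "direction",
            "significant", "n_mutated", "n_total", "ok"]
    return result[cols].sort_values(["stratum", "fdr", "gene"]).reset_index(drop=True)


def mutation_frequency_table(mutset: MutationSet, clinical: ClinicalTable) -> pd.DataFrame:
    """Per-gene per-tumor-type mutated fraction with stratum sizes."""
    rows = []
    for ttype, sub in clinical.tumor_type.groupby(clinical.tumor_type):
        stratum = [s for s in sub.index if s in mutset.samples]
        n = len(stratum)
        frac = mutset.matrix[stratum].mean(axis=1) if n else pd.Series(dtype=float)
        for gene in mutset.genes:
            rows.append(
                {"gene": gene, "tumor_type": str(ttype),
                 "fraction": float(frac.get(gene, 0.0)) if n else 0.0, "n": n}
            )
    return pd.DataFrame(rows)
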
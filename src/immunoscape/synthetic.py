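"""Synthetic multi-tumor-type cohorts with a known inflammation axis.

The generator emulates the statistical structure the analysis modules
assume, with every effect recorded in a ground-truth object:

* a latent inflammation axis lambda ~ Normal(0, 1) per sample drives the
  signature genes (baseline + effect * lambda + noise);
* each oncogenic pathway has a regulator whose target genes move
  opposite to lambda (anti-correlated transcriptional programs), scaled
  per tumor type by a fixed pattern so pathway activation is
  heterogeneous across types;
* a panel of recurrently mutated background genes realizes the per-type
  tumor mutational burden (a log-normal propensity, optionally coupled to
  lambda); flagged mutation genes carry a genuine phenotype odds ratio on
  top of a log10-TMB term, while confounder genes depend on TMB only —
  exactly null once the enrichment model adjusts for burden;
* protein rows track pathway activity plus noise (median-centered);
* treatment response is logistic in lambda.

The "true" phenotype couples mutations to lambda thresholded at +/-0.67
SD; the observed phenotype always comes from scoring, so the classifier
is honestly exercised.  The RNG is counter-based (Philox) so a seed
reproduces the cohort bit-for-bit across platforms.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_formats
from .types import (
    CausalNetwork,
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    VariantRecord,
)

__all__ = ["GeneratorConfig", "GroundTruth", "SyntheticCohort",
           "generate_cohort", "write_fixture_bundle"]

_NSSM_TOKENS = ["Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del",
                "Frame_Shift_Ins", "In_Frame_Del", "Splice_Site"]
_NSSM_PROBS = [0.62, 0.12, 0.10, 0.06, 0.04, 0.06]
LAMBDA_THRESHOLD = 0.67  # SD units; couples mutations to the latent axis


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-generating parameters (all effects in log2 / logit units)."""

    seed: int = 0
    n_types: int = 10
    samples_per_type: int = 60
    n_signature_genes: int = 160
    n_background_genes: int = 240
    n_pathways: int = 5
    targets_per_pathway: int = 20
    pathway_effect: float = 1.0          # log2 shift per SD of lambda
    signature_effect: float = 1.0        # log2 shift per SD of lambda
    pathway_pattern: str = "heterogeneous"  # or "homogeneous"
    n_flagged_mutation_genes: int = 3
    flagged_odds_ratio: float = 4.0
    flagged_prevalence: float = 0.10
    flagged_tmb_coupling: float = 0.5    # logits per log10(TMB + 1)
    n_confounder_genes: int = 3
    confounder_prevalence: float = 0.15
    confounder_tmb_coupling: float = 3.0
    n_background_mutation_genes: int = 60
    tmb_log10_base: float = 1.2          # per-type means spread around this
    tmb_log10_type_spread: float = 0.4
    tmb_log10_sd: float = 0.25
    tmb_lambda_coupling: float = 0.25    # log10 TMB units per SD of lambda
    baseline_mean: float = 7.0           # log2 baseline abundance
    baseline_sd: float = 1.0
    noise_sd: float = 1.0
    protein_noise_sd: float = 0.5
    n_null_regulators: int = 5
    n_decoy_regulators: int = 5          # DE targets, random edge signs
    responder_intercept: float = 0.0
    responder_slope: float = 1.5

    def validate(self) -> None:
        counts = [self.n_types, self.samples_per_type, self.n_signature_genes,
                  self.n_background_genes, self.n_pathways,
                  self.targets_per_pathway, self.n_background_mutation_genes]
        if any(c <= 0 for c in counts):
            raise ValueError("all cohort counts must be positive")
        if not 0 < self.flagged_prevalence < 1 or not 0 < self.confounder_prevalence < 1:
            raise ValueError("mutation prevalences must be in (0, 1)")
        if self.pathway_pattern not in ("heterogeneous", "homogeneous"):
            raise ValueError(f"unknown pathway_pattern {self.pathway_pattern!r}")
        for name in ("pathway_effect", "signature_effect", "noise_sd",
                     "tmb_lambda_coupling", "flagged_odds_ratio"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class GroundTruth:
    """Generating mechanism for every feature of one cohort."""

    lam: pd.Series                  # latent inflammation per sample
    true_phenotype: pd.Series       # non_inflamed / intermediate / inflamed
    signature_genes: list[str]
    pathway_targets: dict[str, list[str]]   # pathway -> target genes
    pathway_regulators: dict[str, str]      # pathway -> regulator
    pathway_type_scale: pd.DataFrame        # types x pathways effect scale
    flagged_genes: dict[str, float]         # gene -> odds ratio
    confounder_genes: dict[str, float]      # gene -> TMB coupling (logits)
    decoy_regulators: list[str]             # DE targets, random signs (null z)
    protein_pathway: dict[str, str]         # protein -> pathway it tracks
    tmb_target: pd.Series                   # intended NSSM count per sample
    response_probability: pd.Series


@dataclass
class SyntheticCohort:
    config: GeneratorConfig
    expression: ExpressionMatrix            # log2 state
    variants: list[VariantRecord]
    clinical: ClinicalTable
    proteins: pd.DataFrame                  # proteins x samples, median-centered
    gene_sets: GeneSetCollection
    network: CausalNetwork
    truth: GroundTruth

    @property
    def samples(self) -> pd.Index:
        return self.expression.sample_ids


def _type_scale(config: GeneratorConfig) -> np.ndarray:
    """Per-type pathway effect scales.  The heterogeneous pattern activates
    an increasing prefix of pathways (type 0 gets one pathway, the last
    type gets all), producing between-type heterogeneity in how many
    programs are live; the homogeneous pattern activates everything."""
    scale = np.zeros((config.n_types, config.n_pathways))
    if config.pathway_pattern == "homogeneous":
        scale[:] = 1.0
        return scale
    for t in range(config.n_types):
        if config.n_types == 1:
            n_active = config.n_pathways
        else:
            n_active = 1 + round(t * (config.n_pathways - 1) / (config.n_types - 1))
        scale[t, :n_active] = 1.0
    return scale


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Draw one fully labeled cohort from the configured mechanism."""
    config.validate()
    rng = np.random.Generator(np.random.Philox(key=config.seed))

    n = config.n_types * config.samples_per_type
    samples = [f"S{i:04d}" for i in range(n)]
    types = np.repeat([f"T{t}" for t in range(config.n_types)],
                      config.samples_per_type)
    type_idx = np.repeat(np.arange(config.n_types), config.samples_per_type)

    lam = rng.normal(0.0, 1.0, size=n)
    true_pheno = np.where(lam < -LAMBDA_THRESHOLD, "non_inflamed",
                          np.where(lam > LAMBDA_THRESHOLD, "inflamed",
                                   "intermediate"))

    sig_genes = [f"SIG{i:04d}" for i in range(config.n_signature_genes)]
    pathway_names = [f"PW{i}" for i in range(config.n_pathways)]
    pw_targets = {
        pw: [f"{pw}_TGT{j:03d}" for j in range(config.targets_per_pathway)]
        for pw in pathway_names
    }
    bg_genes = [f"BG{i:04d}" for i in range(config.n_background_genes)]
    all_genes = sig_genes + [g for pw in pathway_names for g in pw_targets[pw]] + bg_genes

    scale = _type_scale(config)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd,
                          size=len(all_genes))
    expr = np.empty((len(all_genes), n))
    row = 0
    for _ in sig_genes:
        expr[row] = baseline[row] + config.signature_effect * lam
        row += 1
    for p, pw in enumerate(pathway_names):
        per_sample = -config.pathway_effect * scale[type_idx, p] * lam
        for _ in pw_targets[pw]:
            expr[row] = baseline[row] + per_sample
            row += 1
    for _ in bg_genes:
        expr[row] = baseline[row]
        row += 1
    expr += rng.normal(0.0, config.noise_sd, size=expr.shape)
    expression = ExpressionMatrix(
        pd.DataFrame(expr, index=all_genes, columns=samples), "log2"
    )

    # --- mutations -------------------------------------------------------
    # Per-sample mutational propensity (log10 scale): per-type base, an
    # optional coupling to lambda (the TMB confounding channel), and noise.
    log10_propensity = (
        config.tmb_log10_base
        + config.tmb_log10_type_spread
        * (type_idx - (config.n_types - 1) / 2.0)
        / max(config.n_types - 1, 1)
        + config.tmb_lambda_coupling * lam
        + rng.normal(0.0, config.tmb_log10_sd, size=n)
    )
    is_ni = (true_pheno == "non_inflamed").astype(float)

    def logit(p: float) -> float:
        return float(np.log(p / (1.0 - p)))

    flagged = {f"MUTFLAG{i}": config.flagged_odds_ratio
               for i in range(config.n_flagged_mutation_genes)}
    confounders = {f"MUTCONF{i}": config.confounder_tmb_coupling
                   for i in range(config.n_confounder_genes)}
    bg_mut = [f"MUTBG{i:03d}" for i in range(config.n_background_mutation_genes)]

    records: list[VariantRecord] = []

    def draw_gene(gene: str, eta: np.ndarray) -> np.ndarray:
        p = 1.0 / (1.0 + np.exp(-eta))
        hit = rng.random(n) < p
        for i in np.flatnonzero(hit):
            records.append(VariantRecord(
                samples[i], gene,
                str(rng.choice(_NSSM_TOKENS, p=_NSSM_PROBS)),
                protein_change=None,
            ))
        return hit

    # Background genes realize the bulk of the TMB: each has its own
    # baseline prevalence modulated by the sample propensity, so realized
    # TMB is a sum of independent Bernoullis, lognormal-like across types.
    bg_prev = rng.uniform(0.05, 0.25, size=len(bg_mut))
    base_tmb = np.zeros(n, dtype=int)
    centered_prop = log10_propensity - log10_propensity.mean()
    for gene, prev in zip(bg_mut, bg_prev):
        hit = draw_gene(gene, logit(float(prev)) + np.log(10.0) * centered_prop)
        base_tmb += hit
    # Flagged and confounder genes couple to log10(realized TMB + 1) — the
    # same covariate the enrichment model adjusts for — so confounder genes
    # are exactly null given TMB while flagged genes add a genuine
    # phenotype odds ratio on top.
    log_tmb_term = np.log10(base_tmb + 1.0)
    mean_tmb_term = float(log_tmb_term.mean())
    for gene, odds in flagged.items():
        a = logit(config.flagged_prevalence) - config.flagged_tmb_coupling * mean_tmb_term
        draw_gene(gene, a + np.log(odds) * is_ni
                  + config.flagged_tmb_coupling * log_tmb_term)
    for gene, coupling in confounders.items():
        a = logit(config.confounder_prevalence) - coupling * mean_tmb_term
        draw_gene(gene, a + coupling * log_tmb_term)
    # a sprinkling of synonymous calls exercises the NSSM filter
    n_silent = n // 2
    for i in rng.choice(n, size=n_silent, replace=True):
        records.append(VariantRecord(
            samples[int(i)], str(rng.choice(bg_mut)), "Silent"
        ))
    tmb_target = base_tmb

    # --- proteins --------------------------------------------------------
    prot_names = [f"PROT_{pw}" for pw in pathway_names]
    prot = np.empty((config.n_pathways, n))
    for p in range(config.n_pathways):
        activity = -config.pathway_effect * scale[type_idx, p] * lam
        prot[p] = activity + rng.normal(0.0, config.protein_noise_sd, size=n)
    prot = prot - np.median(prot, axis=1, keepdims=True)
    proteins = pd.DataFrame(prot, index=prot_names, columns=samples)

    # --- response --------------------------------------------------------
    p_resp = 1.0 / (1.0 + np.exp(-(config.responder_intercept
                                   + config.responder_slope * lam)))
    responder = rng.random(n) < p_resp
    fine = np.where(responder,
                    np.where(rng.random(n) < 0.5, "PR", "CR"),
                    np.where(rng.random(n) < 0.5, "PD", "SD"))
    clinical = ClinicalTable(pd.DataFrame(
        {"tumor_type": types, "response": fine}, index=pd.Index(samples, name="sample_id")
    ))

    # --- gene sets and network ------------------------------------------
    sets = {"TCELL_SIGNATURE": sig_genes}
    sets.update({pw: genes for pw, genes in pw_targets.items()})
    gene_sets = GeneSetCollection(
        sets, {name: "synthetic" for name in sets}
    )

    regulators = {pw: f"REG_{pw}" for pw in pathway_names}
    edges = [
        {"regulator": regulators[pw], "target": tgt, "sign": 1}
        for pw in pathway_names for tgt in pw_targets[pw]
    ]
    for i in range(config.n_null_regulators):
        reg = f"REG_NULL{i}"
        targets = rng.choice(bg_genes, size=config.targets_per_pathway,
                             replace=False)
        signs = rng.choice([1, -1], size=config.targets_per_pathway)
        edges.extend(
            {"regulator": reg, "target": str(t), "sign": int(s)}
            for t, s in zip(targets, signs)
        )
    # decoy regulators: genuinely DE targets but random edge signs, so the
    # sign-consistency z is null while the overlap gate passes — the
    # honest operating point for activation type-I calibration
    all_targets = [g for pw in pathway_names for g in pw_targets[pw]]
    decoys = []
    for i in range(config.n_decoy_regulators):
        reg = f"REG_DECOY{i}"
        decoys.append(reg)
        targets = rng.choice(all_targets, size=config.targets_per_pathway,
                             replace=False)
        signs = rng.choice([1, -1], size=config.targets_per_pathway)
        edges.extend(
            {"regulator": reg, "target": str(t), "sign": int(s)}
            for t, s in zip(targets, signs)
        )
    annotation = {regulators[pw]: {f"{pw}_signaling"} for pw in pathway_names}
    network = CausalNetwork(pd.DataFrame(edges), annotation)

    truth = GroundTruth(
        lam=pd.Series(lam, index=samples, name="lambda"),
        true_phenotype=pd.Series(true_pheno, index=samples),
        signature_genes=sig_genes,
        pathway_targets=pw_targets,
        pathway_regulators=regulators,
        pathway_type_scale=pd.DataFrame(
            scale, index=[f"T{t}" for t in range(config.n_types)],
            columns=pathway_names,
        ),
        flagged_genes=flagged,
        confounder_genes=confounders,
        decoy_regulators=decoys,
        protein_pathway=dict(zip(prot_names, pathway_names)),
        tmb_target=pd.Series(tmb_target, index=samples),
        response_probability=pd.Series(p_resp, index=samples),
    )
    return SyntheticCohort(config, expression, records, clinical, proteins,
                           gene_sets, network, truth)


def write_fixture_bundle(cohort: SyntheticCohort, directory) -> dict[str, Path]:
    """Write the cohort in the pipeline's TSV dialects plus ground truth
    and a config echo; returns the path of every file written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "variants": directory / "variants.tsv",
        "clinical": directory / "clinical.tsv",
        "gene_sets": directory / "gene_sets.gmt",
        "network": directory / "network.tsv",
        "proteins": directory / "proteins.tsv",
        "ground_truth": directory / "ground_truth.tsv",
        "config": directory / "config.yaml",
    }
    io_formats.write_expression(cohort.expression, paths["expression"])
    io_formats.write_variants(cohort.variants, paths["variants"])
    io_formats.write_clinical(cohort.clinical, paths["clinical"])
    io_formats.write_gmt(cohort.gene_sets, paths["gene_sets"])
    io_formats.write_network(cohort.network, paths["network"],
                             annotation_path=directory / "annotation.tsv")
    paths["annotation"] = directory / "annotation.tsv"
    io_formats.write_table(
        cohort.proteins, paths["proteins"], index=True, index_label="protein"
    )
    gt = pd.DataFrame({
        "lambda": cohort.truth.lam,
        "true_phenotype": cohort.truth.true_phenotype,
        "tmb_target": cohort.truth.tmb_target,
        "response_probability": cohort.truth.response_probability,
    })
    io_formats.write_table(gt, paths["ground_truth"], index=True,
                           index_label="sample_id")
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cohort.config), fh, sort_keys=True)
    return paths


def load_config(path) -> GeneratorConfig:
    """Parse a YAML config echo back into a GeneratorConfig."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return GeneratorConfig(**raw)
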
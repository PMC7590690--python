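"""End-to-end orchestration: simulate -> score -> enrich -> activate ->
validate -> cooccur, with a manifest of outputs.

The run config is a plain mapping (usually parsed from YAML):

.. code-block:: yaml

    seed: 1
    simulate: {samples_per_type: 100}        # generator overrides, or:
    # inputs: {expression: e.tsv, variants: v.tsv, clinical: c.tsv,
    #          gene_sets: s.gmt, network: n.tsv, annotation: a.tsv}
    signature_set: TCELL_SIGNATURE
    params:
      mutation_fdr: 0.10
      deg_fdr: 0.05
      fold_change: 1.5
      z_cut: 1.95
      overlap_p_cut: 0.05
      cap: 10
      min_category_n: 10
      enrichment_mode: pan_cancer

Intermediate samples are excluded from all two-group analyses at this
level, and strata where one phenotype group is (nearly) empty are
dropped with a logged reason.  A pathway's gene list is its regulator's
target set, so per-sample pathway calls and pathway expression follow
directly from the causal network.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__, io_formats
from .cooccurrence import (
    burden_scores,
    category_distribution,
    collapse_category,
    heterogeneity_distances,
    ks_compare,
    per_sample_pathway_calls,
    score_expression_regression,
)
from .mutation import build_mutation_set, run_enrichment
from .pathways import run_activation
from .signature import score_cohort
from .synthetic import GeneratorConfig, generate_cohort, write_fixture_bundle
from .types import ClinicalTable, ExpressionMatrix, FormatError

logger = logging.getLogger("immunoscape")

DEFAULT_PARAMS = {
    "mutation_fdr": 0.10,
    "deg_fdr": 0.05,
    "fold_change": 1.5,
    "z_cut": 1.95,
    "overlap_p_cut": 0.05,
    "cap": 10,
    "min_category_n": 10,
    "enrichment_mode": "pan_cancer",
    "min_group_n": 3,
}

__all__ = ["run_pipeline", "DEFAULT_PARAMS"]


def _config_hash(config: Mapping) -> str:
    canonical = yaml.safe_dump(json.loads(json.dumps(config, sort_keys=True)),
                               sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _load_inputs(inputs: Mapping, outdir: Path):
    required = ["expression", "variants", "clinical", "gene_sets", "network"]
    missing = [k for k in required if k not in inputs]
    if missing:
        raise FormatError(f"run config inputs missing keys: {missing}")
    absent = [str(inputs[k]) for k in inputs if not Path(inputs[k]).exists()]
    if absent:
        raise FormatError(f"input files not found: {absent}")
    expression = io_formats.read_expression(inputs["expression"], state="log2")
    variants = io_formats.read_variants(inputs["variants"])
    clinical = io_formats.read_clinical(inputs["clinical"])
    gene_sets = io_formats.read_gmt(inputs["gene_sets"])
    network = io_formats.read_network(inputs["network"],
                                      annotation_path=inputs.get("annotation"))
    return expression, variants, clinical, gene_sets, network


def _check_universe(expression: ExpressionMatrix, variants,
                    clinical: ClinicalTable) -> None:
    universe = set(clinical.sample_ids)
    extra_expr = sorted(set(expression.sample_ids) - universe)
    extra_var = sorted({v.sample_id for v in variants} - universe)
    problems = []
    if extra_expr:
        problems.append(f"expression samples outside clinical table: {extra_expr[:5]}")
    if extra_var:
        problems.append(f"variant samples outside clinical table: {extra_var[:5]}")
    if problems:
        raise FormatError("sample-universe mismatch: " + "; ".join(problems))


def run_pipeline(config: Mapping, outdir) -> dict:
    """Execute the pipeline; returns (and writes) the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    seed = int(config.get("seed", 0))
    signature_set = config.get("signature_set", "TCELL_SIGNATURE")
    manifest: dict = {
        "version": __version__,
        "config_hash": _config_hash(dict(config)),
        "seed": seed,
        "params": params,
        "stages": [],
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def stage(name: str, outputs: dict) -> None:
        manifest["stages"].append(
            {"name": name, "outputs": {k: str(v) for k, v in outputs.items()}}
        )
        logger.info("stage %s complete: %s", name, sorted(outputs))

    try:
        # ---- inputs -----------------------------------------------------
        if "inputs" in config:
            expression, variants, clinical, gene_sets, network = _load_inputs(
                config["inputs"], outdir
            )
            stage("load", {k: v for k, v in config["inputs"].items()})
        else:
            overrides = dict(config.get("simulate", {}))
            overrides["seed"] = seed
            gen_config = GeneratorConfig(**overrides)
            cohort = generate_cohort(gen_config)
            paths = write_fixture_bundle(cohort, outdir / "cohort")
            expression, variants, clinical = (
                cohort.expression, cohort.variants, cohort.clinical
            )
            gene_sets, network = cohort.gene_sets, cohort.network
            stage("simulate", paths)
        _check_universe(expression, variants, clinical)
        if signature_set not in gene_sets:
            raise FormatError(f"signature set {signature_set!r} not in gene sets")
        signature_genes = gene_sets[signature_set]

        # ---- score ------------------------------------------------------
        calls = score_cohort(expression, signature_genes)
        calls_path = outdir / "phenotype_calls.tsv"
        io_formats.write_table(
            calls, calls_path, index=True, index_label="sample_id",
            params={"n_genes": len(signature_genes)},
        )
        stage("score", {"calls": calls_path})
        logger.info("phenotype counts: %s",
                    calls["group"].value_counts().to_dict())
        two_group = calls[calls["group"].isin(["non_inflamed", "inflamed"])]

        # ---- mutation enrichment ---------------------------------------
        mutset = build_mutation_set(variants, list(clinical.sample_ids))
        enrichment = run_enrichment(
            mutset, calls, clinical, mode=params["enrichment_mode"],
            fdr_cutoff=params["mutation_fdr"],
        )
        enr_path = outdir / "mutation_enrichment.tsv"
        io_formats.write_table(
            enrichment, enr_path,
            params={"fdr": params["mutation_fdr"],
                    "coding": "coefficient>0 => enriched in non_inflamed"},
        )
        stage("enrich", {"enrichment": enr_path})

        # ---- pathway activation per tumor type -------------------------
        activation_frames = []
        min_n = params["min_group_n"]
        for ttype, sub in clinical.tumor_type.groupby(clinical.tumor_type):
            members = [s for s in sub.index if s in two_group.index]
            grp = two_group.loc[members, "group"]
            if (grp == "non_inflamed").sum() < min_n or (grp == "inflamed").sum() < min_n:
                logger.warning(
                    "stratum %s dropped: phenotype group below %d samples",
                    ttype, min_n,
                )
                continue
            act = run_activation(
                expression.subset_samples(members), grp, network,
                stratum=str(ttype), fdr_threshold=params["deg_fdr"],
                fc_threshold=params["fold_change"],
                p_cut=params["overlap_p_cut"], z_cut=params["z_cut"],
            )
            activation_frames.append(act)
        activation = (
            pd.concat(activation_frames, ignore_index=True)
            if activation_frames else pd.DataFrame(
                columns=["regulator", "stratum", "overlap_p", "activation_z",
                         "n_overlap", "activated"])
        )
        act_path = outdir / "activation.tsv"
        io_formats.write_table(
            activation, act_path,
            params={"z": params["z_cut"], "overlap_p": params["overlap_p_cut"]},
        )
        stage("activate", {"activation": act_path})

        # ---- co-occurrence burden --------------------------------------
        flagged = sorted(
            enrichment.loc[
                (enrichment["significant"] == True)  # noqa: E712
                & (enrichment["direction"] == "non_inflamed"), "gene"
            ].unique()
        )
        ni_samples = calls.index[calls["group"] == "non_inflamed"]
        call_frames = []
        for ttype, sub in clinical.tumor_type.groupby(clinical.tumor_type):
            members = [s for s in sub.index if s in ni_samples]
            if not members:
                logger.warning("stratum %s has no non-inflamed samples", ttype)
                continue
            regs = activation.loc[
                (activation["stratum"] == str(ttype)) & activation["activated"],
                "regulator",
            ]
            pw_genes = {
                reg: list(network.targets_of(reg)["target"]) for reg in regs
            }
            if not pw_genes:
                call_frames.append(pd.DataFrame(columns=members))
                continue
            call_frames.append(per_sample_pathway_calls(
                expression.subset_samples(members), pw_genes
            ))
        pathway_calls = (
            pd.concat(call_frames, axis=1).fillna(False)
            if call_frames else pd.DataFrame()
        )
        pathway_calls = pathway_calls.reindex(columns=list(ni_samples),
                                              fill_value=False)
        ni_mutset = _subset_mutset(mutset, list(ni_samples))
        scores = burden_scores(ni_mutset, flagged, pathway_calls)
        scores_path = outdir / "burden_scores.tsv"
        io_formats.write_table(scores, scores_path, index=True,
                               index_label="sample_id",
                               params={"n_flagged": len(flagged)})
        cap = params["cap"]
        results: dict = {"n_flagged_genes": len(flagged)}
        ni_clin = ClinicalTable(clinical.data.loc[list(ni_samples)])
        dist_tables = {}
        for kind in ("nssm_score", "pathway_score"):
            cats = collapse_category(scores[kind], cap)
            dist = category_distribution(cats, ni_clin, cap=cap)
            dist_tables[kind] = dist
            io_formats.write_table(
                dist, outdir / f"{kind}_distribution.tsv", index=True,
                index_label="tumor_type",
            )
        if all(len(d) >= 2 for d in dist_tables.values()):
            d_nssm = heterogeneity_distances(dist_tables["nssm_score"])
            d_pw = heterogeneity_distances(dist_tables["pathway_score"])
            D, p = ks_compare(d_nssm, d_pw)
            results["heterogeneity_ks"] = {"D": D, "p": p}
        sig_expr = calls.loc[list(ni_samples), "signature_expression"]
        for kind in ("nssm_score", "pathway_score"):
            try:
                fit = score_expression_regression(
                    scores[kind], sig_expr,
                    min_samples_per_category=params["min_category_n"],
                )
            except ValueError as exc:
                logger.warning("regression on %s skipped: %s", kind, exc)
                continue
            results[f"{kind}_regression"] = {
                "slope": float(fit.betas[1]),
                "intercept": float(fit.betas[0]),
                "adjusted_r2": fit.adjusted_r2,
                "slope_p": fit.slope_p,
                "chosen_degree": fit.chosen_degree,
            }
        summary_path = outdir / "cooccurrence_summary.json"
        with open(summary_path, "w") as fh:
            json.dump(results, fh, indent=2)
        stage("cooccur", {"scores": scores_path, "summary": summary_path})

        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        manifest["status"] = "ok"
    except Exception:
        manifest["status"] = "failed"
        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise
    stable = {k: manifest[k] for k in ("version", "config_hash", "seed",
                                       "params", "stages")}
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(stable, sort_keys=True).encode()
    ).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _subset_mutset(mutset, samples):
    from .mutation import MutationSet

    present = [s for s in samples if s in mutset.samples]
    return MutationSet(mutset.matrix[present], mutset.tmb.loc[present])
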
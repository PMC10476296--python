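"""End-to-end orchestration: simulate -> prepare -> score -> associate ->
prs-fit/prs-score -> predict, with a reproducibility manifest.

Every stage is a pure function of (inputs, config, seed); ``run_all``
always recomputes the full chain, so re-running with the same config
reproduces byte-identical artifacts (the manifest records each file's
SHA-256 digest for checking exactly that).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import fit_gene_association, scan_outputs, scan_summary
from .cohort_prep import (
    CohortSplit,
    adjust_table,
    apply_normalization,
    fit_normalization,
    split_cohort,
    write_split,
)
from .gene_scores import WeightParams, compute_gbs
from .io_formats import (
    RunConfig,
    write_annotations,
    write_association_table,
    write_genotypes,
    write_phenotypes,
    write_score_matrix,
)
from .prediction import run_modalities, select_gene_predictors
from .prs import compute_prs, construct_prs_weights, write_prs_weights
from .synthetic_data import SimulationConfig, simulate_cohort

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config: dict
    sim_config: dict
    seed: int
    version: str
    stage_seconds: dict[str, float] = field(default_factory=dict)
    file_digests: dict[str, str] = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(
    sim_config: SimulationConfig,
    run_config: RunConfig,
    outdir,
    trait: str = "cholesterol",
    zoo=None,
) -> RunManifest:
    """Run the whole analysis on a simulated cohort; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=dataclasses.asdict(run_config),
        sim_config={
            k: (dict(v) if isinstance(v, dict) else v)
            for k, v in dataclasses.asdict(sim_config).items()
        },
        seed=run_config.random_seed,
        version=__version__,
    )

    def stage(name):
        t0 = time.perf_counter()

        def done(*files):
            manifest.stage_seconds[name] = round(time.perf_counter() - t0, 3)
            for f in files:
                manifest.file_digests[Path(f).name] = _digest(Path(f))

        return done

    # --- simulate ----------------------------------------------------------
    done = stage("simulate")
    geno_rare, geno_common, annotations, pheno, truth = simulate_cohort(sim_config)
    f_rare = outdir / "genotypes_rare.tsv"
    f_common = outdir / "genotypes_common.tsv"
    f_ann = outdir / "annotations.tsv"
    f_pheno = outdir / "phenotypes.tsv"
    write_genotypes(geno_rare, f_rare)
    write_genotypes(geno_common, f_common)
    write_annotations(annotations, f_ann)
    write_phenotypes(pheno, f_pheno)
    f_truth = outdir / "truth_variance_fractions.tsv"
    truth.variance_fractions.rename_axis("component").to_csv(f_truth, sep="\t")
    done(f_rare, f_common, f_ann, f_pheno, f_truth)

    # --- prepare -----------------------------------------------------------
    done = stage("prepare")
    included = pheno.loc[pheno["biomarker"].notna()]
    if trait in run_config.statin_factors:
        included = adjust_table(included, trait, run_config.statin_factors)
    split = split_cohort(
        included.index, run_config.split_fractions, seed=run_config.random_seed
    )
    f_adj = outdir / "phenotypes_adjusted.tsv"
    f_split = outdir / "split.tsv"
    write_phenotypes(included, f_adj)
    write_split(split, f_split)
    done(f_adj, f_split)
    log.info("prepare: %d samples included, split sizes %s", len(included), split.sizes)

    # --- score -------------------------------------------------------------
    done = stage("score")
    params = WeightParams(run_config.beta_a, run_config.beta_b, run_config.maf_threshold)
    gbs = compute_gbs(geno_rare.subset_samples(included.index), annotations, params)
    f_gbs = outdir / "gbs.tsv"
    write_score_matrix(gbs, f_gbs)
    done(f_gbs)

    # --- associate (whole included cohort, per the analysis design) --------
    done = stage("associate")
    covars = included[["bmi", "age", "sex", "pc1", "pc2", "pc3", "pc4"]]
    table = fit_gene_association(gbs, included["biomarker"], covars, alpha=run_config.alpha)
    summary = scan_summary(table)
    gene_pos = annotations.groupby("gene")["position"].min()
    plots = scan_outputs(table, gene_pos)
    f_assoc = outdir / "association.tsv"
    f_sum = outdir / "scan_summary.tsv"
    write_association_table(table, f_assoc)
    pd.Series(dataclasses.asdict(summary)).rename_axis("field").to_csv(f_sum, sep="\t", header=["value"])
    f_qq = outdir / "qq_points.tsv"
    f_man = outdir / "manhattan_points.tsv"
    plots["qq"].to_csv(f_qq, sep="\t", index=False)
    plots["manhattan"].to_csv(f_man, sep="\t", index=False)
    done(f_assoc, f_sum, f_qq, f_man)
    log.info(
        "associate: lambda=%.3f, %d/%d genes significant (+%d/-%d)",
        summary.lambda_, summary.n_positive + summary.n_negative,
        summary.m_tested, summary.n_positive, summary.n_negative,
    )

    # --- PRS ---------------------------------------------------------------
    done = stage("prs")
    con_ids = list(split.construction_ids)
    geno_con = geno_common.subset_samples(con_ids)
    weights = construct_prs_weights(
        geno_con,
        included.loc[con_ids, "biomarker"],
        included.loc[con_ids, ["bmi", "age", "sex", "pc1", "pc2", "pc3", "pc4"]],
        split=split,
        seed=run_config.random_seed,
        maf_min=run_config.maf_threshold,
    )
    rest_ids = list(split.training_ids) + list(split.test_ids)
    prs = compute_prs(geno_common.subset_samples(rest_ids), weights)
    f_w = outdir / "prs_weights.tsv"
    f_prs = outdir / "prs_scores.tsv"
    write_prs_weights(weights, f_w)
    write_score_matrix(prs.to_frame(), f_prs)
    done(f_w, f_prs)
    log.info("prs: %d active SNPs at alpha=%.3g", len(weights.betas), weights.metadata["alpha"])

    # --- predict -----------------------------------------------------------
    done = stage("predict")
    genes = select_gene_predictors(
        gbs.loc[con_ids],
        included.loc[con_ids, "biomarker"],
        covars.loc[con_ids],
        alpha=run_config.alpha,
        split=split,
    )
    log.info("predict: %d gene predictor(s) selected", len(genes))
    tr_ids, te_ids = list(split.training_ids), list(split.test_ids)
    raw_features = pd.concat(
        [
            included[["sex", "age", "bmi", "pc1", "pc2", "pc3", "pc4"]],
            gbs[genes],
            prs.rename("prs").to_frame().reindex(included.index),
        ],
        axis=1,
    )
    stats = fit_normalization(raw_features.loc[tr_ids], tr_ids)
    genes = [g for g in genes if g not in stats.dropped]
    norm_tr = apply_normalization(raw_features.loc[tr_ids], stats)
    norm_te = apply_normalization(raw_features.loc[te_ids], stats)
    if "prs" in stats.dropped:
        # an all-zero PRS (null lasso) is kept as a constant-zero feature so
        # the PRS/combined modalities keep their declared column set
        norm_tr["prs"] = 0.0
        norm_te["prs"] = 0.0
    cov_cols = ["sex", "age", "bmi", "pc1", "pc2", "pc3", "pc4"]
    report = run_modalities(
        covariates_train=norm_tr[cov_cols],
        covariates_test=norm_te[cov_cols],
        target_train=included.loc[tr_ids, "biomarker"],
        target_test=included.loc[te_ids, "biomarker"],
        gbs_train=norm_tr[genes],
        gbs_test=norm_te[genes],
        prs_train=norm_tr["prs"],
        prs_test=norm_te["prs"],
        zoo=zoo,
        folds=run_config.cv_folds,
        seed=run_config.random_seed,
    )
    f_rep = outdir / "model_report.tsv"
    report.to_csv(f_rep, sep="\t")
    f_top = outdir / "top_features.tsv"
    tops = pd.concat(
        {m: r.top_features for m, r in report.attrs["results"].items()},
        names=["modality", "feature"],
    )
    tops.to_csv(f_top, sep="\t", header=["importance"])
    done(f_rep, f_top)

    manifest.save(outdir / "manifest.json")
    return manifest
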
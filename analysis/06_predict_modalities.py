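"""Feature selection and the four-modality risk-prediction comparison.

Bonferroni-significant genes are selected on the construction split; all
features are z-scored with training-split statistics; each modality's model
family is chosen by 10-fold CV on the training split and evaluated once on
the held-out test split. The headline column is the incremental R^2 over
the covariates-only model.
"""
import pandas as pd

from common import COVARIATES, RESULTS, RUN_CONFIG, SCRATCH, SEED, ensure_dirs

from burdenblend.cohort_prep import apply_normalization, fit_normalization, read_split
from burdenblend.io_formats import read_phenotypes, read_score_matrix
from burdenblend.prediction import run_modalities, select_gene_predictors


def main() -> None:
    ensure_dirs()
    pheno = read_phenotypes(SCRATCH / "phenotypes_adjusted.tsv")
    split = read_split(SCRATCH / "split.tsv")
    gbs = read_score_matrix(SCRATCH / "gbs.tsv")
    prs = read_score_matrix(SCRATCH / "prs_scores.tsv").iloc[:, 0].rename("prs")

    con = list(split.construction_ids)
    genes = select_gene_predictors(
        gbs.loc[con], pheno.loc[con, "biomarker"], pheno.loc[con, COVARIATES],
        alpha=RUN_CONFIG.alpha, split=split,
    )
    print(f"gene predictors selected on the construction split: {genes}")

    tr, te = list(split.training_ids), list(split.test_ids)
    feats = pd.concat(
        [pheno[["sex", "age", "bmi", "pc1", "pc2", "pc3", "pc4"]], gbs[genes],
         prs.to_frame().reindex(pheno.index)],
        axis=1,
    )
    stats = fit_normalization(feats.loc[tr], tr)
    genes = [g for g in genes if g not in stats.dropped]
    norm_tr = apply_normalization(feats.loc[tr], stats)
    norm_te = apply_normalization(feats.loc[te], stats)
    if "prs" in stats.dropped:
        norm_tr["prs"] = 0.0
        norm_te["prs"] = 0.0

    cov_cols = ["sex", "age", "bmi", "pc1", "pc2", "pc3", "pc4"]
    report = run_modalities(
        covariates_train=norm_tr[cov_cols], covariates_test=norm_te[cov_cols],
        target_train=pheno.loc[tr, "biomarker"], target_test=pheno.loc[te, "biomarker"],
        gbs_train=norm_tr[genes], gbs_test=norm_te[genes],
        prs_train=norm_tr["prs"], prs_test=norm_te["prs"],
        folds=RUN_CONFIG.cv_folds, seed=SEED, split=split,
    )
    report.to_csv(RESULTS / "demo_model_report.tsv", sep="\t")
    tops = pd.concat(
        {m: r.top_features for m, r in report.attrs["results"].items()},
        names=["modality", "feature"],
    )
    tops.to_csv(RESULTS / "demo_top_features.tsv", sep="\t", header=["importance"])

    print(report.to_string(float_format="%.3f"))
    combined = report.attrs["results"]["combined"]
    print("top features of the combined model (permutation importance):")
    print(combined.top_features.head(5).to_string(float_format="%.4f"))


if __name__ == "__main__":
    main()
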
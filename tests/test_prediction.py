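import numpy as np
import pandas as pd
import pytest

from burdenblend.cohort_prep import LeakageError, split_cohort
from burdenblend.gene_scores import compute_gbs
from burdenblend.prediction import (
    MODALITY_SPECS,
    assemble_features,
    default_zoo,
    evaluate,
    feature_importance,
    incremental_r2,
    run_modalities,
    select_gene_predictors,
    train_and_select,
)
from burdenblend.synthetic_data import SimulationConfig, pick_causal_genes, simulate_cohort


def _linear_zoo(seed=0):
    zoo = default_zoo(seed)
    return {k: zoo[k] for k in ("ols", "ridge")}


def _features(rng, n=300, p=5, index=None):
    idx = index if index is not None else [f"S{i}" for i in range(n)]
    return pd.DataFrame(
        rng.normal(size=(len(idx), p)), index=idx, columns=[f"f{j}" for j in range(p)]
    )


# -- feature selection -------------------------------------------------------


def test_alpha_zero_selects_nothing(covariates_frame, rng):
    gbs = _features(rng, p=4, index=covariates_frame.index)
    y = pd.Series(rng.normal(size=len(gbs)), index=gbs.index)
    assert select_gene_predictors(gbs, y, covariates_frame, alpha=0.0) == []


def test_strong_gene_selected_null_genes_not():
    cfg = SimulationConfig(
        n_samples=3000, n_genes=50, n_common_snps=2,
        causal_genes=pick_causal_genes(50, [0.8]), seed=13,
    )
    geno_rare, _, ann, pheno, _ = simulate_cohort(cfg)
    gbs = compute_gbs(geno_rare, ann)
    covars = pheno[["bmi", "age", "sex", "pc1", "pc2", "pc3", "pc4"]]
    selected = select_gene_predictors(gbs, pheno["biomarker"], covars, alpha=0.05)
    assert "GENE0000" in selected
    assert len(selected) <= 3  # essentially no Bonferroni false positives


def test_feature_selection_outside_construction_split_raises(covariates_frame, rng):
    gbs = _features(rng, p=3, index=covariates_frame.index)
    y = pd.Series(rng.normal(size=len(gbs)), index=gbs.index)
    split = split_cohort(list(gbs.index[:100]), seed=0)  # gbs has 200 extra ids
    with pytest.raises(LeakageError, match="feature selection"):
        select_gene_predictors(gbs, y, covariates_frame, split=split)


# -- feature assembly --------------------------------------------------------


def _blocks(rng, n=50):
    idx = [f"S{i}" for i in range(n)]
    cov = pd.DataFrame(
        rng.normal(size=(n, 7)), index=idx,
        columns=["sex", "age", "bmi", "pc1", "pc2", "pc3", "pc4"],
    )
    gbs = pd.DataFrame(rng.normal(size=(n, 5)), index=idx,
                       columns=[f"GENE{k}" for k in range(5)])
    prs = pd.Series(rng.normal(size=n), index=idx, name="prs")
    return cov, gbs, prs


def test_covariates_modality_is_exactly_seven_columns(rng):
    cov, gbs, prs = _blocks(rng)
    out = assemble_features("covariates", cov, gbs, prs)
    assert list(out.columns) == ["sex", "age", "bmi", "pc1", "pc2", "pc3", "pc4"]


def test_combined_modality_column_count(rng):
    cov, gbs, prs = _blocks(rng)
    out = assemble_features("combined", cov, gbs, prs)
    assert out.shape[1] == 7 + 5 + 1
    assert out.columns[-1] == "prs"


def test_gbs_modality_has_no_prs_column(rng):
    cov, gbs, prs = _blocks(rng)
    out = assemble_features("gbs", cov, gbs, prs)
    assert "prs" not in out.columns
    assert set(gbs.columns) <= set(out.columns)


def test_missing_required_block_raises(rng):
    cov, gbs, prs = _blocks(rng)
    with pytest.raises(ValueError, match="GBS"):
        assemble_features("gbs", cov, None, prs)
    with pytest.raises(ValueError, match="PRS"):
        assemble_features("prs", cov, gbs, None)


# -- training, selection, evaluation -----------------------------------------


def test_exact_linear_target_fits_perfectly(rng):
    X = _features(rng, n=200, p=4)
    y = 2 * X["f0"] - X["f3"] + 0.25
    model, cv = train_and_select(X, y, zoo=_linear_zoo(), folds=10, seed=0)
    assert evaluate(model, X, y) == pytest.approx(1.0, abs=1e-6)
    assert cv.attrs["selected"] == "ols"  # ties broken linear-first


def test_pure_noise_target_has_no_predictive_power(rng):
    X = _features(rng, n=3000, p=6)
    y = pd.Series(rng.normal(size=3000), index=X.index)
    X_test = _features(rng, n=1000, p=6)
    y_test = pd.Series(rng.normal(size=1000), index=X_test.index)
    model, _ = train_and_select(X, y, zoo=_linear_zoo(), folds=10, seed=0)
    assert evaluate(model, X_test, y_test) <= 0.02


def test_interaction_target_prefers_tree_family(rng):
    """A strong multiplicative sex-by-feature interaction favours gradient
    boosting over OLS in cross-validation."""
    n = 1200
    sex = rng.integers(0, 2, n).astype(float)
    x = rng.normal(size=n)
    y = pd.Series(3.0 * sex * x + rng.normal(scale=0.5, size=n))
    X = pd.DataFrame({"sex": sex, "x": x})
    zoo = {k: v for k, v in default_zoo(0).items() if k in ("ols", "gradient_boosting")}
    _, cv = train_and_select(X, y, zoo=zoo, folds=5, seed=0)
    cv = cv.set_index("family")
    assert cv.loc["gradient_boosting", "cv_r2_mean"] > cv.loc["ols", "cv_r2_mean"]
    assert cv.attrs["selected"] == "gradient_boosting"


def test_fewer_samples_than_folds_rejected(rng):
    X = _features(rng, n=5, p=2)
    with pytest.raises(ValueError, match="folds"):
        train_and_select(X, pd.Series(np.arange(5.0), index=X.index), folds=10)


def test_evaluate_trivial_cases(rng):
    X = _features(rng, n=50, p=2)
    y = pd.Series(rng.normal(size=50), index=X.index)

    class Echo:
        def predict(self, A):
            return y.to_numpy()

    class Mean:
        def predict(self, A):
            return np.full(len(A), y.mean())

    assert evaluate(Echo(), X, y) == 1.0
    assert evaluate(Mean(), X, y) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError, match="zero variance"):
        evaluate(Mean(), X, pd.Series(np.ones(50), index=X.index))


def test_incremental_r2_is_plain_difference():
    assert incremental_r2(0.103, 0.071) == pytest.approx(0.032)
    assert incremental_r2(0.242, 0.248) == pytest.approx(-0.006)  # never clamped


def test_training_and_evaluation_respect_split(rng):
    X = _features(rng, n=100, p=3)
    y = pd.Series(rng.normal(size=100), index=X.index)
    split = split_cohort(X.index, seed=0)
    with pytest.raises(LeakageError, match="model training"):
        train_and_select(X, y, zoo=_linear_zoo(), folds=5, split=split)
    model, _ = train_and_select(
        X.loc[split.training_ids], y.loc[split.training_ids],
        zoo=_linear_zoo(), folds=5, split=split,
    )
    with pytest.raises(LeakageError, match="evaluation"):
        evaluate(model, X, y, split=split)


# -- permutation importance --------------------------------------------------


def test_sex_only_target_ranks_sex_first(rng):
    cov, gbs, prs = _blocks(rng, n=400)
    y = 5.0 * cov["sex"] + rng.normal(scale=0.1, size=400)
    X = assemble_features("combined", cov, gbs, prs)
    model, _ = train_and_select(X, y, zoo=_linear_zoo(), folds=5, seed=0)
    imp = feature_importance(model, X, y, seed=0)
    assert imp.index[0] == "sex"


def test_noise_target_importances_are_null(rng):
    X = _features(rng, n=2000, p=7)
    y = pd.Series(rng.normal(size=2000), index=X.index)
    model, _ = train_and_select(X, y, zoo=_linear_zoo(), folds=5, seed=0)
    imp = feature_importance(model, X, y, seed=0)
    assert imp.max() < 0.02


def test_importances_reproducible_under_seed(rng):
    X = _features(rng, n=300, p=4)
    y = pd.Series(X["f1"] + rng.normal(size=300), index=X.index)
    model, _ = train_and_select(X, y, zoo=_linear_zoo(), folds=5, seed=0)
    a = feature_importance(model, X, y, seed=3)
    b = feature_importance(model, X, y, seed=3)
    pd.testing.assert_series_equal(a, b)


# -- the four-modality report ------------------------------------------------


def test_modality_report_structure(rng):
    cov, gbs, prs = _blocks(rng, n=400)
    cov_te, gbs_te, prs_te = _blocks(rng, n=100)
    y_tr = pd.Series(
        0.5 * cov["age"] + 0.8 * gbs["GENE0"] + 0.6 * prs + rng.normal(size=400),
        index=cov.index,
    )
    y_te = pd.Series(
        0.5 * cov_te["age"] + 0.8 * gbs_te["GENE0"] + 0.6 * prs_te
        + rng.normal(size=100),
        index=cov_te.index,
    )
    report = run_modalities(
        cov, cov_te, y_tr, y_te,
        gbs_train=gbs, gbs_test=gbs_te, prs_train=prs, prs_test=prs_te,
        zoo=_linear_zoo(), folds=5, seed=0,
    )
    assert list(report.index) == ["covariates", "gbs", "prs", "combined"]
    assert report.loc["covariates", "incremental_r2"] == 0.0
    assert report.loc["combined", "test_r2"] > report.loc["covariates", "test_r2"]
    for modality, res in report.attrs["results"].items():
        assert len(res.top_features) <= 10
        if not MODALITY_SPECS[modality].include_gbs:
            assert res.n_gene_predictors == 0
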
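"""Feature selection and the four risk-prediction modalities.

Gene predictors are chosen on the construction split: the association scan
is run there and genes surviving Bonferroni at alpha are kept. Four feature
sets are then assembled —

    covariates : sex + age + BMI + PC1..PC4
    gbs        : covariates + selected gene burden scores
    prs        : covariates + polygenic score
    combined   : covariates + selected gene scores + polygenic score

— all z-scored with training-split statistics. For each modality a small
zoo of regression families (OLS, ridge, lasso, elastic net, random forest,
gradient boosting) is scored by mean 10-fold cross-validated R^2 on the
training split; the best family (ties to the earlier, linear-first zoo
order) is refit on the full training split and evaluated once on the test
split. The headline quantity is the incremental R^2: test R^2 of a genetic
modality minus that of the covariates-only modality, reported as-is (it can
be negative). Feature importances are model-agnostic permutation
importances on the test split.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.linear_model import ElasticNet, Lasso, LinearRegression, Ridge
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold

from .association import fit_gene_association
from .cohort_prep import CohortSplit, assert_within_split

log = logging.getLogger(__name__)

MODALITIES = ("covariates", "gbs", "prs", "combined")
COVARIATE_BLOCK = ["sex", "age", "bmi", "pc1", "pc2", "pc3", "pc4"]


@dataclass(frozen=True)
class ModalitySpec:
    name: str
    include_gbs: bool
    include_prs: bool


MODALITY_SPECS: dict[str, ModalitySpec] = {
    "covariates": ModalitySpec("covariates", False, False),
    "gbs": ModalitySpec("gbs", True, False),
    "prs": ModalitySpec("prs", False, True),
    "combined": ModalitySpec("combined", True, True),
}


def default_zoo(seed: int = 0) -> dict[str, Callable[[], object]]:
    """Ordered model families; linear families first so ties stay linear.

    Hyperparameters are fixed small-grid-free choices kept deliberately
    plain; the selection compares families, not tuned variants.
    """
    return {
        "ols": lambda: LinearRegression(),
        "ridge": lambda: Ridge(alpha=1.0),
        "lasso": lambda: Lasso(alpha=0.01, max_iter=50_000),
        "elastic_net": lambda: ElasticNet(alpha=0.01, l1_ratio=0.5, max_iter=50_000),
        "random_forest": lambda: RandomForestRegressor(
            n_estimators=100, min_samples_leaf=5, random_state=seed, n_jobs=1
        ),
        "gradient_boosting": lambda: GradientBoostingRegressor(random_state=seed),
    }


def select_gene_predictors(
    gbs: pd.DataFrame,
    phenotype: pd.Series,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    split: CohortSplit | None = None,
) -> list[str]:
    """Genes Bonferroni-significant on the construction split."""
    if split is not None:
        assert_within_split(gbs.index, split.construction_ids, "feature selection")
    if alpha <= 0:
        return []
    table = fit_gene_association(gbs, phenotype, covariates, alpha=alpha)
    keep = table.loc[table["tested"] & (table["p_adj"] < alpha)]
    return sorted(keep.index.tolist())


def assemble_features(
    modality: str,
    covariates: pd.DataFrame,
    gbs_selected: pd.DataFrame | None = None,
    prs: pd.Series | None = None,
) -> pd.DataFrame:
    """Feature matrix for one modality; blocks must already be z-scored
    with training-split statistics. Column order is deterministic:
    covariates, then genes (sorted), then PRS."""
    spec = MODALITY_SPECS[modality]
    missing = [c for c in COVARIATE_BLOCK if c not in covariates.columns]
    if missing:
        raise KeyError(f"covariate block missing columns {missing}")
    blocks = [covariates[COVARIATE_BLOCK]]
    if spec.include_gbs:
        if gbs_selected is None:
            raise ValueError(f"modality {modality!r} requires the GBS block")
        blocks.append(gbs_selected.reindex(sorted(gbs_selected.columns), axis=1))
    if spec.include_prs:
        if prs is None:
            raise ValueError(f"modality {modality!r} requires the PRS block")
        blocks.append(prs.rename("prs").to_frame())
    out = pd.concat([b.loc[covariates.index] for b in blocks], axis=1)
    if out.isna().any().any():
        bad = out.columns[out.isna().any()].tolist()
        raise ValueError(f"feature block(s) incomplete for modality {modality!r}: {bad[:5]}")
    return out


def train_and_select(
    features: pd.DataFrame,
    target: pd.Series,
    zoo: Mapping[str, Callable[[], object]] | None = None,
    folds: int = 10,
    seed: int = 0,
    split: CohortSplit | None = None,
):
    """Score each family by mean k-fold CV R^2, refit the winner on the full
    training data. Returns (fitted model, CV table)."""
    if split is not None:
        assert_within_split(features.index, split.training_ids, "model training")
    X = features.to_numpy(dtype=float)
    y = np.asarray(target, dtype=float)
    if len(y) < folds:
        raise ValueError(f"n={len(y)} smaller than {folds} folds")
    zoo = default_zoo(seed) if zoo is None else zoo
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    rows = []
    for name, factory in zoo.items():
        scores = []
        for tr, va in splits:
            m = factory()
            m.fit(X[tr], y[tr])
            scores.append(r2_score(y[va], m.predict(X[va])))
        rows.append((name, float(np.mean(scores)), float(np.std(scores, ddof=1))))
    cv_table = pd.DataFrame(rows, columns=["family", "cv_r2_mean", "cv_r2_sd"])
    best_score = cv_table["cv_r2_mean"].max()
    best_name = cv_table.loc[cv_table["cv_r2_mean"] >= best_score - 1e-12, "family"].iloc[0]
    best = zoo[best_name]()
    best.fit(X, y)
    cv_table.attrs["selected"] = best_name
    return best, cv_table


def evaluate(model, features: pd.DataFrame, target: pd.Series, split: CohortSplit | None = None) -> float:
    """Test-split R^2 = 1 - SS_res / SS_tot."""
    if split is not None:
        assert_within_split(features.index, split.test_ids, "model evaluation")
    y = np.asarray(target, dtype=float)
    if np.var(y) == 0:
        raise ValueError("test target has zero variance")
    return float(r2_score(y, model.predict(features.to_numpy(dtype=float))))


def incremental_r2(model_r2: float, covariates_r2: float) -> float:
    """Added predictive value of the genetic features; may be negative."""
    return model_r2 - covariates_r2


def feature_importance(
    model, features: pd.DataFrame, target: pd.Series, seed: int = 0, n_repeats: int = 10
) -> pd.Series:
    """Permutation importance (drop in R^2), descending."""
    res = permutation_importance(
        model,
        features.to_numpy(dtype=float),
        np.asarray(target, dtype=float),
        n_repeats=n_repeats,
        random_state=seed,
        scoring="r2",
    )
    imp = pd.Series(res.importances_mean, index=features.columns, name="importance")
    return imp.sort_values(ascending=False, kind="mergesort")


@dataclass
class ModalityResult:
    modality: str
    family: str
    cv_r2: float
    test_r2: float
    incremental_r2: float
    n_gene_predictors: int
    top_features: pd.Series = field(repr=False, default=None)


def run_modalities(
    covariates_train: pd.DataFrame,
    covariates_test: pd.DataFrame,
    target_train: pd.Series,
    target_test: pd.Series,
    gbs_train: pd.DataFrame | None = None,
    gbs_test: pd.DataFrame | None = None,
    prs_train: pd.Series | None = None,
    prs_test: pd.Series | None = None,
    zoo: Mapping[str, Callable[[], object]] | None = None,
    folds: int = 10,
    seed: int = 0,
    split: CohortSplit | None = None,
    modalities: Sequence[str] = MODALITIES,
    importance_top: int = 10,
) -> pd.DataFrame:
    """Train, select and evaluate every modality; Table-2-style report.

    Returns one row per modality: selected family, CV R^2, test R^2 and
    incremental R^2 over the covariates-only model (0 by definition for the
    covariates row). ``attrs['results']`` keeps the full per-modality
    objects including top permutation importances.
    """
    n_genes = 0 if gbs_train is None else gbs_train.shape[1]
    results: dict[str, ModalityResult] = {}
    for modality in modalities:
        feats_tr = assemble_features(
            modality, covariates_train,
            gbs_selected=gbs_train if MODALITY_SPECS[modality].include_gbs else None,
            prs=prs_train if MODALITY_SPECS[modality].include_prs else None,
        )
        feats_te = assemble_features(
            modality, covariates_test,
            gbs_selected=gbs_test if MODALITY_SPECS[modality].include_gbs else None,
            prs=prs_test if MODALITY_SPECS[modality].include_prs else None,
        )
        model, cv_table = train_and_select(
            feats_tr, target_train, zoo=zoo, folds=folds, seed=seed, split=split
        )
        r2 = evaluate(model, feats_te, target_test, split=split)
        imp = feature_importance(model, feats_te, target_test, seed=seed).head(importance_top)
        results[modality] = ModalityResult(
            modality=modality,
            family=cv_table.attrs["selected"],
            cv_r2=float(cv_table.loc[cv_table["family"] == cv_table.attrs["selected"], "cv_r2_mean"].iloc[0]),
            test_r2=r2,
            incremental_r2=np.nan,
            n_gene_predictors=n_genes if MODALITY_SPECS[modality].include_gbs else 0,
            top_features=imp,
        )
    base = results["covariates"].test_r2 if "covariates" in results else np.nan
    for res in results.values():
        res.incremental_r2 = 0.0 if res.modality == "covariates" else incremental_r2(res.test_r2, base)
    report = pd.DataFrame(
        [
            {
                "modality": r.modality,
                "family": r.family,
                "cv_r2": r.cv_r2,
                "test_r2": r.test_r2,
                "incremental_r2": r.incremental_r2,
                "n_gene_predictors": r.n_gene_predictors,
            }
            for r in results.values()
        ]
    ).set_index("modality")
    report.attrs["results"] = results
    return report
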
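"""Common-variant polygenic score by screened L1-penalised regression.

The weights are learned on the construction split only. The phenotype is
first residualised on the covariates; SNPs (cohort MAF >= 0.01) are ranked
by absolute marginal correlation with the residual and the top batch
(default 500) enters an L1 path. The penalty is chosen by R^2 on a held-out
validation fold of the construction subset (ties go to the larger penalty,
i.e. the sparser model). At the chosen penalty the model is refit on the
whole construction subset and the Karush-Kuhn-Tucker optimality conditions
are checked over *all* SNPs: any inactive SNP whose gradient exceeds the
penalty is batched in and the fit repeated, so the screened solution equals
the full-lasso solution at that penalty. This mirrors batch-screening
iterative lasso (BASIL) fitting at desk scale.

Scoring is an intercept-free weighted dosage sum. A weights object carries
the construction sample ids; scoring a cohort that overlaps them raises
unless explicitly allowed, which keeps PRS features leak-free downstream.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso

from .cohort_prep import CohortSplit, LeakageError, assert_within_split
from .io_formats import FLOAT_FMT, GenotypeMatrix

log = logging.getLogger(__name__)

_LASSO_KW = dict(fit_intercept=True, tol=1e-10, max_iter=200_000)


@dataclass
class PRSWeights:
    betas: pd.Series  # variant_id -> beta, nonzero entries only
    intercept: float
    construction_ids: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.betas.to_numpy(dtype=float))):
            raise ValueError("PRS weights must be finite")


def _residualise(y: np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
    C = np.column_stack([np.ones(len(y)), covariates.to_numpy(dtype=float)])
    coef, *_ = np.linalg.lstsq(C, y, rcond=None)
    return y - C @ coef


def _fit_lasso(X: np.ndarray, y: np.ndarray, alpha: float) -> Lasso:
    model = Lasso(alpha=alpha, **_LASSO_KW)
    model.fit(X, y)
    return model


def _kkt_violators(
    X: np.ndarray, y: np.ndarray, model: Lasso, members: np.ndarray, alpha: float
) -> np.ndarray:
    """Indices (into X's columns) of inactive SNPs violating |x_c' r| / n <= alpha."""
    n = len(y)
    resid = y - model.predict(X[:, members]) if len(members) else y - y.mean()
    Xc = X - X.mean(axis=0)
    grad = np.abs(Xc.T @ (resid - resid.mean())) / n
    candidates = np.setdiff1d(np.arange(X.shape[1]), members)
    viol = candidates[grad[candidates] > alpha * (1 + 1e-8) + 1e-12]
    return viol


def construct_prs_weights(
    genotypes_common: GenotypeMatrix,
    phenotype,
    covariates: pd.DataFrame,
    split: CohortSplit | None = None,
    batch_size: int = 500,
    n_alphas: int = 50,
    alpha_min_ratio: float = 1e-3,
    val_fraction: float = 0.2,
    maf_min: float = 0.01,
    seed: int = 0,
    max_rounds: int = 20,
) -> PRSWeights:
    """Learn sparse per-SNP weights on the construction subset."""
    sample_ids = genotypes_common.sample_ids
    if split is not None:
        assert_within_split(sample_ids, split.construction_ids, "PRS construction")
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    if n != genotypes_common.n_samples or len(covariates) != n:
        raise ValueError("genotypes, phenotype and covariates must align")
    n_val = int(round(val_fraction * n))
    if n_val < 10 or n - n_val < 30:
        raise ValueError(f"n={n} too small for a {val_fraction:.0%} validation fold")

    maf = genotypes_common.allele_frequencies()
    maf = np.minimum(maf, 1 - maf)
    common = maf >= maf_min
    if not common.any():
        raise ValueError("no SNP passes the common-variant MAF filter")
    X_all = genotypes_common.dosage_float(missing="mean")[:, common]
    snp_ids = genotypes_common.variant_ids[common]

    r = _residualise(y, covariates)

    def _screen(X: np.ndarray, resid: np.ndarray) -> np.ndarray:
        Xc = X - X.mean(axis=0)
        sd = Xc.std(axis=0)
        sd[sd == 0] = np.inf
        marg = np.abs(Xc.T @ (resid - resid.mean())) / (len(resid) * sd)
        return np.sort(np.argsort(marg)[::-1][: min(batch_size, X.shape[1])])

    # penalty grid from the unrestricted gradient at beta = 0
    Xc_all = X_all - X_all.mean(axis=0)
    alpha_max = float(np.max(np.abs(Xc_all.T @ (r - r.mean()))) / len(r))
    if alpha_max <= 0:
        alpha_max = 1e-3
    alphas = alpha_max * np.logspace(0, np.log10(alpha_min_ratio), n_alphas)

    # penalty selection on a held-out validation fold of the construction
    # set; the screen for this path sees only the fitting fold, otherwise
    # screened-in noise SNPs look predictive on the validation fold
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    val_idx, fit_idx = perm[:n_val], perm[n_val:]
    fit_batch = _screen(X_all[fit_idx], r[fit_idx])
    val_r2 = np.full(n_alphas, -np.inf)
    for k, a in enumerate(alphas):
        m = _fit_lasso(X_all[np.ix_(fit_idx, fit_batch)], r[fit_idx], a)
        pred = m.predict(X_all[np.ix_(val_idx, fit_batch)])
        ss_tot = float(np.sum((r[val_idx] - r[val_idx].mean()) ** 2))
        if ss_tot > 0:
            val_r2[k] = 1.0 - float(np.sum((r[val_idx] - pred) ** 2)) / ss_tot
    # ties -> the larger penalty (earlier in the grid), hence the sparser model
    best = int(np.argmax(val_r2 > val_r2.max() - 1e-12))
    alpha_star = float(alphas[best])
    batch = _screen(X_all, r)

    # final fit on the full construction subset with KKT-checked batching
    members = batch.copy()
    rounds = 0
    while True:
        model = _fit_lasso(X_all[:, members], r, alpha_star)
        rounds += 1
        viol = _kkt_violators(X_all, r, model, members, alpha_star)
        if len(viol) == 0 or rounds >= max_rounds:
            if len(viol):
                log.warning("KKT batching stopped after %d rounds with %d violators", rounds, len(viol))
            break
        members = np.sort(np.concatenate([members, viol]))

    nonzero = model.coef_ != 0
    betas = pd.Series(model.coef_[nonzero], index=snp_ids[members][nonzero], name="beta")
    return PRSWeights(
        betas=betas,
        intercept=float(model.intercept_),
        construction_ids=np.asarray(sample_ids, dtype=object),
        metadata={
            "alpha": alpha_star,
            "alpha_max": alpha_max,
            "screening_rounds": rounds,
            "n_construction": n,
            "n_snps_screened": int(len(batch)),
            "n_active": int(nonzero.sum()),
            "validation_r2": float(val_r2[best]),
        },
    )


def compute_prs(
    genotypes: GenotypeMatrix,
    weights: PRSWeights,
    allow_construction_overlap: bool = False,
) -> pd.Series:
    """score_i = sum_j beta_j * dosage_ij (missing dosage -> per-SNP mean)."""
    if not allow_construction_overlap:
        overlap = set(genotypes.sample_ids) & set(weights.construction_ids)
        if overlap:
            raise LeakageError(
                f"{len(overlap)} sample(s) to score were used for PRS construction, "
                f"e.g. {sorted(overlap)[:3]}; pass allow_construction_overlap=True to force"
            )
    idx = pd.Index(genotypes.variant_ids).get_indexer(weights.betas.index)
    if (idx < 0).any():
        absent = weights.betas.index[idx < 0].tolist()
        raise KeyError(f"weighted variant(s) absent from genotypes: {absent[:5]}")
    X = genotypes.dosage_float(missing="mean")[:, idx]
    scores = X @ weights.betas.to_numpy(dtype=float)
    return pd.Series(scores, index=genotypes.sample_ids, name="prs")


def write_prs_weights(weights: PRSWeights, path) -> None:
    df = weights.betas.rename_axis("variant_id").reset_index()
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_prs_weights(path, construction_ids=()) -> PRSWeights:
    df = pd.read_csv(path, sep="\t")
    return PRSWeights(
        betas=df.set_index("variant_id")["beta"],
        intercept=0.0,
        construction_ids=np.asarray(list(construction_ids), dtype=object),
    )
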
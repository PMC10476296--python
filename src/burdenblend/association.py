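"""Per-gene association scan of a quantitative trait on gene burden scores.

For every gene, the trait is regressed by ordinary least squares on the
gene's burden score plus the covariates (intercept, age, sex, BMI,
PC1..PC4). The reported effect size is z = beta / se of the gene-score
coefficient; the two-sided p-value comes from the exact t distribution
with residual degrees of freedom. Multiple testing is handled by
Bonferroni over the genes actually tested (zero-variance genes are marked
untested and excluded from m). Scan-level calibration is summarised by the
genomic inflation factor

    lambda = median( qchisq(1 - p, df=1) ) / median(chisq_1)

which is 1 for a perfectly calibrated null.

The per-gene fits use the Frisch-Waugh-Lovell decomposition: trait and
scores are residualised on the covariate design once (via a QR factor),
after which each gene reduces to a simple regression. This is algebraically
identical to the full OLS fit, gene by gene, but runs the whole scan as a
few matrix products.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: median of the 1-df chi-square distribution, the null reference for lambda
CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))


@dataclass
class ScanSummary:
    lambda_: float
    m_tested: int
    significance_threshold: float
    n_positive: int
    n_negative: int


def zscore(beta: float, se: float) -> float:
    """Effect size z = beta / se; identical to the regression t statistic."""
    if se <= 0:
        raise ValueError(f"standard error must be positive, got {se}")
    return beta / se


def bonferroni(p_values, alpha: float, m: int):
    """Adjusted p-values min(1, p*m) and the significance threshold alpha/m."""
    if m < 1:
        raise ValueError("m must be at least 1")
    p = np.asarray(p_values, dtype=float)
    return np.minimum(1.0, p * m), alpha / m


def genomic_lambda(p_values) -> float:
    """Median-based genomic inflation factor of a p-value vector."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite p-values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chisq = stats.chi2.isf(p, 1)
    return float(np.median(chisq) / CHI2_MEDIAN_1DF)


def _covariate_qr(covariates: pd.DataFrame) -> np.ndarray:
    C = np.column_stack([np.ones(len(covariates)), covariates.to_numpy(dtype=float)])
    names = ["intercept"] + list(covariates.columns)
    # a dependent column shows up as a ~0 diagonal entry of R
    Q, R = np.linalg.qr(C, mode="reduced")
    diag = np.abs(np.diag(R))
    tol = max(C.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = [names[k] for k in np.nonzero(diag <= tol)[0]]
    if bad:
        raise ValueError(f"covariate design is rank deficient; collinear column(s): {bad}")
    return Q


def fit_gene_association(
    scores: pd.DataFrame,
    phenotype,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """OLS scan of ``phenotype`` on each gene score plus covariates.

    Returns a table indexed by gene with columns beta, se, z, p, p_adj and
    tested; ``attrs['m_tested']`` holds the Bonferroni denominator.
    """
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    if covariates.isna().any().any():
        raise ValueError("covariates contain missing values")
    if len(covariates) != n or len(scores) != n:
        raise ValueError("phenotype, covariates and scores must align")
    Q = _covariate_qr(covariates)
    p_cov = Q.shape[1]
    df = n - p_cov - 1
    if df <= 0:
        raise ValueError(f"not enough residual degrees of freedom (n={n})")

    G = scores.to_numpy(dtype=float)
    y_r = y - Q @ (Q.T @ y)
    G_r = G - Q @ (Q.T @ G)

    gg = np.einsum("ij,ij->j", G_r, G_r)
    scale = np.einsum("ij,ij->j", G, G)
    tested = gg > np.maximum(scale, 1.0) * np.finfo(float).eps * n
    if not tested.any():
        raise ValueError("no gene has nonzero score variance after residualisation")

    beta = np.full(G.shape[1], np.nan)
    se = np.full(G.shape[1], np.nan)
    gy = G_r.T @ y_r
    beta[tested] = gy[tested] / gg[tested]
    yy = float(y_r @ y_r)
    ssr = yy - beta[tested] ** 2 * gg[tested]
    ssr = np.maximum(ssr, 0.0)
    sigma2 = ssr / df
    se[tested] = np.sqrt(sigma2 / gg[tested])

    z = np.full_like(beta, np.nan)
    pval = np.full_like(beta, np.nan)
    ok = tested & (se > 0)
    z[ok] = beta[ok] / se[ok]
    pval[ok] = 2.0 * stats.t.sf(np.abs(z[ok]), df)
    # a perfect fit (zero residual) has se = 0: infinite t, underflowing p
    perfect = tested & (se == 0)
    z[perfect] = np.sign(beta[perfect]) * np.inf
    pval[perfect] = np.finfo(float).tiny
    ok = ok | perfect
    # clamp: p must be > 0 for downstream lambda; underflow maps to tiny
    pval[ok] = np.maximum(pval[ok], np.finfo(float).tiny)

    m = int(ok.sum())
    p_adj = np.full_like(pval, np.nan)
    p_adj[ok], threshold = bonferroni(pval[ok], alpha, m)

    table = pd.DataFrame(
        {"beta": beta, "se": se, "z": z, "p": pval, "p_adj": p_adj, "tested": ok},
        index=scores.columns,
    )
    table.index.name = "gene"
    table.attrs["m_tested"] = m
    table.attrs["alpha"] = alpha
    table.attrs["significance_threshold"] = threshold
    table.attrs["residual_df"] = df
    return table


def scan_summary(table: pd.DataFrame, alpha: float | None = None) -> ScanSummary:
    alpha = table.attrs.get("alpha", 0.05) if alpha is None else alpha
    tested = table["tested"]
    m = int(tested.sum())
    threshold = alpha / m
    sig = tested & (table["p"] < threshold)
    return ScanSummary(
        lambda_=genomic_lambda(table.loc[tested, "p"]),
        m_tested=m,
        significance_threshold=threshold,
        n_positive=int((sig & (table["z"] > 0)).sum()),
        n_negative=int((sig & (table["z"] < 0)).sum()),
    )


def qq_expected(m: int) -> np.ndarray:
    """-log10 expected uniform quantiles for ranks 1..m: -log10((k-0.5)/m)."""
    k = np.arange(1, m + 1)
    return -np.log10((k - 0.5) / m)


def scan_outputs(
    table: pd.DataFrame, gene_positions: pd.Series | None = None
) -> dict[str, pd.DataFrame]:
    """QQ points, Manhattan points and the significant effect-size set."""
    tested = table.loc[table["tested"]]
    p = tested["p"].to_numpy()
    order = np.argsort(p)
    qq = pd.DataFrame(
        {
            "expected": qq_expected(len(p)),
            "observed": -np.log10(p[order]),
            "gene": tested.index.to_numpy()[order],
        }
    )

    man = tested.reset_index()[["gene", "p"]].copy()
    man["neglog10_p"] = -np.log10(man["p"])
    if gene_positions is not None:
        man["position"] = man["gene"].map(gene_positions)
        man = man.sort_values(["position", "gene"], kind="mergesort")
    else:
        man = man.sort_values("gene", kind="mergesort")
    man = man.reset_index(drop=True)

    threshold = table.attrs.get("alpha", 0.05) / max(int(table["tested"].sum()), 1)
    sig = tested.loc[tested["p"] < threshold, ["z"]].copy()
    sig = sig.sort_values("z", kind="mergesort")
    sig["label"] = ""
    if len(sig):
        # extremes labelled; exact ties resolved by gene symbol order
        lo = sig.loc[sig["z"] == sig["z"].min()].sort_index().index[0]
        hi = sig.loc[sig["z"] == sig["z"].max()].sort_index().index[0]
        sig.loc[lo, "label"] = "lowest"
        sig.loc[hi, "label"] = "highest" if hi != lo else "lowest"
    return {"qq": qq, "manhattan": man, "effect_sizes": sig}
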
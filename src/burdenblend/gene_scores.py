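"""Individual-level gene-based burden scores (GBS) from rare functional variants.

A gene's score for a sample is the sum, over qualifying rare variants in the
gene, of

    deleteriousness(v) * w(MAF_v) * dosage(sample, v)

where ``w`` is the Beta-distribution density with shapes (1, 25) evaluated at
the variant's minor allele frequency — the standard rare-variant
up-weighting, ~25 near MAF 0 and decaying with frequency. Qualifying means:
functional-consequence flag set, MAF below the rarity threshold (default
0.01), gene assigned and a deleteriousness score present (CADD-raw-like;
negative values are accepted). No per-gene normalisation or dosage cap is
applied.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import beta as beta_dist

from .io_formats import GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WeightParams:
    """Rarity filter and Beta-density weighting shapes."""

    a: float = 1.0
    b: float = 25.0
    maf_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("beta shapes must be positive")
        if not 0 < self.maf_threshold < 1:
            raise ValueError("maf_threshold must lie in (0, 1)")


def variant_weight(maf, params: WeightParams = WeightParams()):
    """Beta(a, b) density at ``maf``; scalar in, scalar out.

    With the default shapes (1, 25) the weight at MAF 0 is exactly 25 and
    decreases monotonically with frequency.
    """
    arr = np.asarray(maf, dtype=float)
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError(f"MAF outside [0, 1]: {arr[(arr < 0) | (arr > 1) | ~np.isfinite(arr)][:5]}")
    # subnormal MAFs overflow the underlying incomplete-beta routine; the
    # density is continuous there, so evaluate them at 0
    arr = np.where(arr < np.finfo(float).tiny, 0.0, arr)
    w = beta_dist.pdf(arr, params.a, params.b)
    return float(w) if np.isscalar(maf) else w


def select_qualifying_variants(
    annotations: pd.DataFrame, params: WeightParams = WeightParams()
) -> pd.DataFrame:
    """Subset of the annotation table entering the burden scores."""
    gene_ok = annotations["gene"].notna() & (
        annotations["gene"].astype(str).str.strip() != ""
    )
    mask = (
        annotations["functional"].astype(bool)
        & annotations["af"].notna()
        & (annotations["af"] < params.maf_threshold)
        & gene_ok
        & annotations["score"].notna()
    )
    kept = annotations.loc[mask].copy()
    if kept.empty:
        log.warning("no variant passed the qualifying filter")
    return kept


def compute_gbs(
    genotypes_rare: GenotypeMatrix,
    annotations: pd.DataFrame,
    params: WeightParams = WeightParams(),
    missing: str = "zero",
) -> pd.DataFrame:
    """Samples x genes burden-score matrix.

    Genotype variants absent from the annotation table are excluded with a
    warning. Every gene named in the annotations gets a column; genes with no
    qualifying variant are all-zero and listed in ``result.attrs['empty_genes']``.
    Missing dosages contribute 0 by default (``missing='mean'`` substitutes
    the per-variant mean dosage instead).
    """
    ann = annotations.set_index("variant_id")
    known = ann.index.get_indexer(genotypes_rare.variant_ids) >= 0
    if not known.all():
        dropped = genotypes_rare.variant_ids[~known]
        log.warning(
            "%d genotype variant(s) absent from annotations, excluded: %s%s",
            len(dropped),
            list(dropped[:5]),
            "..." if len(dropped) > 5 else "",
        )
    qualifying = select_qualifying_variants(annotations, params)
    qual_ids = qualifying.set_index("variant_id")

    genes = sorted(
        g
        for g in annotations["gene"].dropna().astype(str).unique()
        if g.strip() != ""
    )
    gene_index = {g: k for k, g in enumerate(genes)}

    dosage = genotypes_rare.dosage_float(missing=missing)
    pos = qual_ids.index.get_indexer(genotypes_rare.variant_ids)
    rows = np.nonzero(pos >= 0)[0]
    qual_rows = qual_ids.iloc[pos[rows]]
    cols = np.array([gene_index[g] for g in qual_rows["gene"].astype(str)], dtype=int)
    weights = qual_rows["score"].to_numpy(dtype=float) * variant_weight(
        qual_rows["af"].to_numpy(dtype=float), params
    )
    W = sparse.csc_matrix(
        (weights, (rows, cols)), shape=(genotypes_rare.n_variants, len(genes))
    )
    scores = dosage @ W  # n_samples x n_genes, dense result

    out = pd.DataFrame(
        np.asarray(scores), index=genotypes_rare.sample_ids, columns=genes
    )
    out.index.name = "sample_id"
    used = np.zeros(len(genes), dtype=bool)
    used[list(set(cols))] = True
    empty = [g for g, k in gene_index.items() if not used[k]]
    out.attrs["empty_genes"] = sorted(empty)
    if empty:
        log.warning("%d gene(s) have zero qualifying variants", len(empty))
    return out
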
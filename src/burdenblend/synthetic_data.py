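"""Synthetic cohorts with the architecture the analysis assumes.

The generator draws, per sample, rare variants grouped into genes (MAF
log-uniform on [1e-4, 0.009], so every site passes the 0.01 rarity filter),
independent common SNPs (MAF >= 0.01), covariates (age, sex, BMI, four
principal components) and builds a quantitative biomarker as

    y = covariate effects
        + sum_g effect_g * z(true burden_g)        (rare, signed gene effects)
        + sum_j beta_j * dosage_j                  (additive polygenic)
        + Normal(0, noise_sd)

Gene effects apply to the z-standardised true burden so "standardised
effect" means the same thing for every gene. Genotypes are Binomial(2, MAF)
under Hardy-Weinberg and linkage equilibrium. Statin users' *recorded*
biomarker is the latent value multiplied by a treatment factor, which the
preparation stage is expected to undo. Deleteriousness scores are
|Normal(3, 1)| — non-negative, CADD-raw-like in spread. All randomness
comes from ``numpy.random.default_rng`` (PCG64), so a fixed seed gives
byte-identical cohorts on any platform.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gene_scores import WeightParams, compute_gbs
from .io_formats import COVARIATE_COLUMNS, GenotypeMatrix, validate_annotations


@dataclass
class SimulationConfig:
    n_samples: int = 2000
    n_genes: int = 100
    variants_per_gene: tuple[int, int] = (2, 8)
    rare_maf_range: tuple[float, float] = (1e-4, 0.009)
    n_common_snps: int = 300
    common_maf_range: tuple[float, float] = (0.05, 0.5)
    #: gene symbol -> standardised effect (signed); applied to z(true burden)
    causal_genes: Mapping[str, float] = field(default_factory=dict)
    n_causal_snps: int = 0
    snp_effect_sd: float = 0.05
    #: 'normal' draws causal betas ~ N(0, sd); 'fixed' gives every causal SNP
    #: magnitude sd with a random sign (a guaranteed-large-effect design)
    snp_effect_dist: str = "normal"
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {
            "age": 0.01,
            "sex": 0.5,
            "bmi": 0.02,
            "pc1": 0.1,
            "pc2": 0.1,
            "pc3": 0.1,
            "pc4": 0.1,
        }
    )
    noise_sd: float = 1.0
    statin_prevalence: float = 0.0
    statin_effect: float = 0.684
    functional_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.rare_maf_range
        if not (0 < lo <= hi < 0.01):
            raise ValueError("rare MAFs must lie within (0, 0.01)")
        lo, hi = self.common_maf_range
        if not (0.01 <= lo <= hi <= 0.5):
            raise ValueError("common MAFs must lie within [0.01, 0.5]")
        if self.noise_sd < 0 or self.snp_effect_sd < 0:
            raise ValueError("variance components must be non-negative")
        if self.n_causal_snps > self.n_common_snps:
            raise ValueError(
                f"{self.n_causal_snps} causal SNPs requested but only "
                f"{self.n_common_snps} simulated"
            )
        genes = {f"GENE{k:04d}" for k in range(self.n_genes)}
        unknown = set(self.causal_genes) - genes
        if unknown:
            raise ValueError(f"causal genes not among simulated genes: {sorted(unknown)[:5]}")


@dataclass
class SimulationTruth:
    """Ground truth for recovery tests."""

    gene_effects: dict[str, float]
    snp_betas: pd.Series  # indexed by SNP id, zero for non-causal
    common_maf: pd.Series  # generating MAF per common SNP
    covariate_betas: dict[str, float]
    true_burden: pd.DataFrame  # samples x causal genes, standardised
    polygenic_value: pd.Series  # samples
    latent_phenotype: pd.Series  # before statin distortion
    variance_fractions: pd.Series  # covariate / rare_burden / polygenic / noise


def pick_causal_genes(n_genes: int, effects: Sequence[float]) -> dict[str, float]:
    """Assign the given standardised effects to the first genes, in order."""
    if len(effects) > n_genes:
        raise ValueError("more causal effects than genes")
    return {f"GENE{k:04d}": float(e) for k, e in enumerate(effects)}


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, GenotypeMatrix, pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Draw one cohort; returns (rare genotypes, common genotypes,
    annotations, phenotype/covariate table, truth)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = np.array([f"S{i:06d}" for i in range(n)], dtype=object)

    # --- rare panel, grouped into genes -----------------------------------
    lo, hi = config.variants_per_gene
    vpg = rng.integers(lo, hi + 1, size=config.n_genes)
    genes = [f"GENE{k:04d}" for k in range(config.n_genes)]
    gene_of_variant = np.repeat(genes, vpg)
    n_rare = int(vpg.sum())
    rare_ids = np.array(
        [f"{g}_v{i}" for g, i in zip(gene_of_variant, _within_gene_index(vpg))],
        dtype=object,
    )
    log_lo, log_hi = np.log(config.rare_maf_range)
    rare_maf = np.exp(rng.uniform(log_lo, log_hi, size=n_rare))
    rare_dosage = rng.binomial(2, rare_maf, size=(n, n_rare)).astype(np.int16)
    deleteriousness = np.abs(rng.normal(3.0, 1.0, size=n_rare))
    functional = rng.random(n_rare) < config.functional_fraction

    annotations = pd.DataFrame(
        {
            "variant_id": rare_ids,
            "gene": gene_of_variant,
            "af": rare_maf,
            "score": deleteriousness,
            "functional": functional,
            "position": np.arange(1, n_rare + 1) * 1000,
        }
    )
    annotations = validate_annotations(annotations, source="simulator")

    geno_rare = GenotypeMatrix(
        sample_ids, rare_ids, rare_dosage, panel="rare",
        positions=annotations["position"].to_numpy(),
    )

    # --- common panel ------------------------------------------------------
    snp_ids = np.array([f"snp{j:05d}" for j in range(config.n_common_snps)], dtype=object)
    common_maf = rng.uniform(*config.common_maf_range, size=config.n_common_snps)
    common_dosage = rng.binomial(2, common_maf, size=(n, config.n_common_snps)).astype(np.int16)
    geno_common = GenotypeMatrix(sample_ids, snp_ids, common_dosage, panel="common")

    # --- covariates --------------------------------------------------------
    cov = pd.DataFrame(
        {
            "age": rng.normal(55.0, 8.0, size=n),
            "sex": rng.integers(0, 2, size=n).astype(float),
            "bmi": rng.normal(27.0, 4.0, size=n),
            "pc1": rng.normal(0.0, 1.0, size=n),
            "pc2": rng.normal(0.0, 1.0, size=n),
            "pc3": rng.normal(0.0, 1.0, size=n),
            "pc4": rng.normal(0.0, 1.0, size=n),
        },
        index=sample_ids,
    )

    cov_betas = {c: float(config.covariate_effects.get(c, 0.0)) for c in COVARIATE_COLUMNS}
    cov_component = sum(cov[c].to_numpy() * b for c, b in cov_betas.items())
    cov_component = np.asarray(cov_component, dtype=float)

    # --- rare-burden component (true burden uses the generating MAFs) ------
    burden_component = np.zeros(n)
    std_burden = {}
    if config.causal_genes:
        causal_ann = annotations[annotations["gene"].isin(config.causal_genes)]
        causal_vids = set(causal_ann["variant_id"])
        keep = [j for j, v in enumerate(rare_ids) if v in causal_vids]
        geno_causal = GenotypeMatrix(
            sample_ids, rare_ids[keep], rare_dosage[:, keep], panel="rare"
        )
        gbs_true = compute_gbs(geno_causal, causal_ann, WeightParams())
    for gene, effect in config.causal_genes.items():
        raw = gbs_true[gene].to_numpy()
        sd = raw.std(ddof=1)
        if sd == 0:
            z = np.zeros(n)  # monomorphic gene: effect cannot be expressed
        else:
            z = (raw - raw.mean()) / sd
        std_burden[gene] = z
        burden_component = burden_component + effect * z
    true_burden = pd.DataFrame(std_burden, index=sample_ids)

    # --- polygenic component -----------------------------------------------
    snp_betas = np.zeros(config.n_common_snps)
    if config.n_causal_snps:
        causal_idx = rng.choice(config.n_common_snps, size=config.n_causal_snps, replace=False)
        if config.snp_effect_dist == "fixed":
            snp_betas[causal_idx] = config.snp_effect_sd * rng.choice(
                (-1.0, 1.0), size=config.n_causal_snps
            )
        elif config.snp_effect_dist == "normal":
            snp_betas[causal_idx] = rng.normal(
                0.0, config.snp_effect_sd, size=config.n_causal_snps
            )
        else:
            raise ValueError(f"unknown snp_effect_dist {config.snp_effect_dist!r}")
    polygenic = common_dosage.astype(float) @ snp_betas

    noise = rng.normal(0.0, config.noise_sd, size=n)
    latent = cov_component + burden_component + polygenic + noise

    statin = rng.random(n) < config.statin_prevalence
    recorded = np.where(statin, latent * config.statin_effect, latent)

    pheno = cov.copy()
    pheno.insert(0, "biomarker", recorded)
    pheno["statin"] = statin
    pheno.index.name = "sample_id"

    var_y = float(np.var(latent))
    fractions = pd.Series(
        {
            "covariate": float(np.var(cov_component)) / var_y,
            "rare_burden": float(np.var(burden_component)) / var_y,
            "polygenic": float(np.var(polygenic)) / var_y,
            "noise": float(np.var(noise)) / var_y,
        },
        name="variance_fraction",
    )

    truth = SimulationTruth(
        gene_effects=dict(config.causal_genes),
        snp_betas=pd.Series(snp_betas, index=snp_ids),
        common_maf=pd.Series(common_maf, index=snp_ids, name="maf"),
        covariate_betas=cov_betas,
        true_burden=true_burden,
        polygenic_value=pd.Series(polygenic, index=sample_ids, name="polygenic"),
        latent_phenotype=pd.Series(latent, index=sample_ids, name="latent"),
        variance_fractions=fractions,
    )
    return geno_rare, geno_common, annotations, pheno, truth


def _within_gene_index(vpg: np.ndarray) -> np.ndarray:
    return np.concatenate([np.arange(k) for k in vpg]) if len(vpg) else np.array([], int)


def realized_variance_fractions(
    components: Mapping[str, np.ndarray], phenotype: np.ndarray
) -> pd.Series:
    """Variance of each additive component over the variance of the phenotype."""
    phenotype = np.asarray(phenotype, dtype=float)
    var_y = float(np.var(phenotype))
    if var_y == 0:
        raise ValueError("phenotype has zero variance")
    return pd.Series(
        {name: float(np.var(np.asarray(c, dtype=float))) / var_y for name, c in components.items()},
        name="variance_fraction",
    )
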
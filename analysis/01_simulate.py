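"""Draw the demo cohort and record its true variance decomposition.

Writes genotype/annotation/phenotype tables to scratch/analysis and the
realized variance fractions (covariate / rare-burden / polygenic / noise)
to results/demo_variance_fractions.tsv.
"""
from common import RESULTS, SCRATCH, SIM_CONFIG, ensure_dirs

from burdenblend.io_formats import write_annotations, write_genotypes, write_phenotypes
from burdenblend.synthetic_data import simulate_cohort


def main() -> None:
    ensure_dirs()
    geno_rare, geno_common, ann, pheno, truth = simulate_cohort(SIM_CONFIG)
    write_genotypes(geno_rare, SCRATCH / "genotypes_rare.tsv")
    write_genotypes(geno_common, SCRATCH / "genotypes_common.tsv")
    write_annotations(ann, SCRATCH / "annotations.tsv")
    write_phenotypes(pheno, SCRATCH / "phenotypes.tsv")
    frac = truth.variance_fractions
    frac.rename_axis("component").to_csv(
        RESULTS / "demo_variance_fractions.tsv", sep="\t"
    )
    print(f"simulated {SIM_CONFIG.n_samples} samples, "
          f"{geno_rare.n_variants} rare variants in {SIM_CONFIG.n_genes} genes, "
          f"{SIM_CONFIG.n_common_snps} common SNPs")
    print("realized variance fractions of the latent trait:")
    print(frac.to_string(float_format="%.3f"))


if __name__ == "__main__":
    main()
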
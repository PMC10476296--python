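"""Construct the polygenic score on the construction split and score the
training/test cohort.

Screened, KKT-checked lasso on common-SNP dosages (MAF >= 0.01) with the
penalty chosen on a held-out validation fold of the construction subset.
"""
from common import COVARIATES, RESULTS, SCRATCH, SEED, ensure_dirs

from burdenblend.cohort_prep import read_split
from burdenblend.io_formats import read_genotypes, read_phenotypes, write_score_matrix
from burdenblend.prs import compute_prs, construct_prs_weights, write_prs_weights


def main() -> None:
    ensure_dirs()
    geno = read_genotypes(SCRATCH / "genotypes_common.tsv", panel="common")
    pheno = read_phenotypes(SCRATCH / "phenotypes_adjusted.tsv")
    split = read_split(SCRATCH / "split.tsv")

    con = list(split.construction_ids)
    weights = construct_prs_weights(
        geno.subset_samples(con),
        pheno.loc[con, "biomarker"],
        pheno.loc[con, COVARIATES],
        split=split,
        seed=SEED,
    )
    rest = list(split.training_ids) + list(split.test_ids)
    prs = compute_prs(geno.subset_samples(rest), weights)

    write_prs_weights(weights, RESULTS / "demo_prs_weights.tsv")
    write_score_matrix(prs.to_frame(), SCRATCH / "prs_scores.tsv")

    md = weights.metadata
    print(f"construction n = {md['n_construction']}; screened batch of "
          f"{md['n_snps_screened']} SNPs; {md['screening_rounds']} KKT round(s)")
    print(f"selected penalty {md['alpha']:.4g} "
          f"(validation R^2 = {md['validation_r2']:.3f}); "
          f"{md['n_active']} SNPs carry nonzero weight")
    print(f"scored {len(prs)} training/test samples")


if __name__ == "__main__":
    main()
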
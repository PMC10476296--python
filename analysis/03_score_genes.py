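"""Compute per-individual gene burden scores from the rare panel.

Each gene's score sums deleteriousness x Beta(1,25)-density(MAF) x dosage
over its qualifying rare functional variants (MAF < 0.01).
"""
from common import RUN_CONFIG, SCRATCH, ensure_dirs

from burdenblend.gene_scores import WeightParams, compute_gbs, select_qualifying_variants
from burdenblend.io_formats import read_annotations, read_genotypes, write_score_matrix


def main() -> None:
    ensure_dirs()
    geno = read_genotypes(SCRATCH / "genotypes_rare.tsv", panel="rare")
    ann = read_annotations(SCRATCH / "annotations.tsv")
    params = WeightParams(RUN_CONFIG.beta_a, RUN_CONFIG.beta_b, RUN_CONFIG.maf_threshold)
    qualifying = select_qualifying_variants(ann, params)
    gbs = compute_gbs(geno, ann, params)
    write_score_matrix(gbs, SCRATCH / "gbs.tsv")
    print(f"{len(qualifying)}/{len(ann)} variants qualify "
          f"(functional, MAF < {params.maf_threshold})")
    print(f"scored {gbs.shape[0]} samples x {gbs.shape[1]} genes; "
          f"{len(gbs.attrs['empty_genes'])} genes without qualifying variants")
    carriers = (gbs > 0).sum().sort_values(ascending=False)
    print("most-carried genes (samples with nonzero score):")
    print(carriers.head(5).to_string())


if __name__ == "__main__":
    main()
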
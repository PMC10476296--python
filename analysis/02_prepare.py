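"""Statin back-adjustment and the 60/30/10 cohort split.

Reads the simulated phenotypes, divides statin users' cholesterol-like
measurements by the 0.684 on-treatment factor, drops samples without a
biomarker value, and writes the split membership.
"""
from common import RUN_CONFIG, SCRATCH, SEED, ensure_dirs

from burdenblend.cohort_prep import adjust_table, split_cohort, write_split
from burdenblend.io_formats import read_phenotypes, write_phenotypes


def main() -> None:
    ensure_dirs()
    pheno = read_phenotypes(SCRATCH / "phenotypes.tsv")
    included = pheno.loc[pheno["biomarker"].notna()]
    n_statin = int(included["statin"].sum())
    included = adjust_table(included, "cholesterol", RUN_CONFIG.statin_factors)
    split = split_cohort(included.index, RUN_CONFIG.split_fractions, seed=SEED)
    write_phenotypes(included, SCRATCH / "phenotypes_adjusted.tsv")
    write_split(split, SCRATCH / "split.tsv")
    print(f"included {len(included)} samples ({n_statin} statin users adjusted "
          f"by 1/{RUN_CONFIG.statin_factors['cholesterol']})")
    print(f"split sizes (construction, training, test): {split.sizes}")


if __name__ == "__main__":
    main()
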
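import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from burdenblend.gene_scores import (
    WeightParams,
    compute_gbs,
    select_qualifying_variants,
    variant_weight,
)
from burdenblend.io_formats import GenotypeMatrix
from conftest import random_genotypes


def brute_force_gbs(geno, annotations, params=WeightParams()):
    """Per-entry triple loop reference: sum over qualifying variants of
    score * Beta-density(MAF) * dosage (missing dosage -> 0)."""
    qual = {
        r.variant_id: r
        for r in annotations.itertuples()
        if r.functional
        and not pd.isna(r.af)
        and r.af < params.maf_threshold
        and isinstance(r.gene, str)
        and r.gene.strip()
        and not pd.isna(r.score)
    }
    genes = sorted(set(annotations["gene"].dropna()))
    out = pd.DataFrame(0.0, index=geno.sample_ids, columns=genes)
    for i, sid in enumerate(geno.sample_ids):
        for j, vid in enumerate(geno.variant_ids):
            if vid not in qual:
                continue
            r = qual[vid]
            d = geno.dosages[i, j]
            if d < 0:
                continue
            out.loc[sid, r.gene] += r.score * variant_weight(r.af, params) * d
    return out


def random_annotations(rng, variant_ids, n_genes=5):
    genes = [f"G{k}" for k in range(n_genes)]
    return pd.DataFrame(
        {
            "variant_id": variant_ids,
            "gene": rng.choice(genes, size=len(variant_ids)),
            "af": rng.uniform(1e-4, 0.02, size=len(variant_ids)),
            "score": rng.normal(3, 1, size=len(variant_ids)),
            "functional": rng.random(len(variant_ids)) < 0.9,
        }
    )


# -- the weighting function --------------------------------------------------


def test_weight_at_zero_maf_is_exactly_25():
    assert variant_weight(0.0, WeightParams(1, 25)) == 25.0


def test_weight_at_small_maf_matches_closed_form():
    # Beta(1,25) density: 25 * (1-x)^24
    assert variant_weight(0.001) == pytest.approx(25 * 0.999**24, rel=1e-12)
    assert variant_weight(0.001) == pytest.approx(24.4068, abs=5e-5)


@pytest.mark.parametrize("maf", [0.0, 0.1, 0.5, 0.77, 1.0])
def test_uniform_shapes_give_unit_weight(maf):
    assert variant_weight(maf, WeightParams(1, 1)) == pytest.approx(1.0)


@pytest.mark.parametrize("maf", [-0.1, 1.2, np.nan])
def test_weight_rejects_invalid_maf(maf):
    with pytest.raises(ValueError):
        variant_weight(maf)


@given(st.floats(0, 1), st.floats(0, 1))
def test_weight_decreases_with_frequency(a, b):
    """Beta(1,25) density is monotone decreasing: rarer -> larger weight."""
    lo, hi = sorted((a, b))
    assert variant_weight(lo) >= variant_weight(hi)


# -- qualifying-variant filter -----------------------------------------------


def test_filter_matches_row_by_row_manual_filter():
    ann = pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(6)],
            "gene": ["G1", "G1", "G2", "G2", "G3", "G3"],
            "af": [0.001, 0.05, 0.009, 0.0005, 0.002, 0.008],
            "score": [3.0, 2.0, 1.0, 4.0, np.nan, 2.5],
            "functional": [True, True, True, True, True, False],
        }
    )
    kept = select_qualifying_variants(ann)
    # v1 fails AF >= 0.01, v4 has no score, v5 is non-functional
    assert sorted(kept["variant_id"]) == ["v0", "v2", "v3"]


@pytest.mark.parametrize(
    "af,functional,expect",
    [(0.05, True, False), (0.009, True, True), (0.001, False, False)],
)
def test_filter_threshold_and_flag(af, functional, expect):
    ann = pd.DataFrame(
        {"variant_id": ["v"], "gene": ["G"], "af": [af], "score": [1.0],
         "functional": [functional]}
    )
    assert (len(select_qualifying_variants(ann)) == 1) is expect


# -- the burden score itself -------------------------------------------------


def test_single_variant_single_gene_score():
    geno = GenotypeMatrix(
        np.array(["S1"], dtype=object), np.array(["v1"], dtype=object),
        np.array([[2]], dtype=np.int16),
    )
    ann = pd.DataFrame(
        {"variant_id": ["v1"], "gene": ["G1"], "af": [0.001], "score": [3.0],
         "functional": [True]}
    )
    gbs = compute_gbs(geno, ann)
    assert gbs.loc["S1", "G1"] == pytest.approx(2 * 3.0 * variant_weight(0.001))
    assert gbs.loc["S1", "G1"] == pytest.approx(146.441, abs=5e-3)


def test_zero_dosages_give_zero_scores(rng):
    geno = random_genotypes(rng, 4, 10)
    geno.dosages[:] = 0
    ann = random_annotations(rng, geno.variant_ids)
    gbs = compute_gbs(geno, ann)
    assert (gbs.to_numpy() == 0).all()


@pytest.mark.parametrize("seed", range(5))
@pytest.mark.parametrize("missing_rate", [0.0, 0.15])
def test_vectorised_scores_equal_triple_loop(seed, missing_rate):
    rng = np.random.default_rng(seed)
    geno = random_genotypes(rng, 20, 50, missing_rate=missing_rate)
    ann = random_annotations(rng, geno.variant_ids, n_genes=8)
    gbs = compute_gbs(geno, ann)
    ref = brute_force_gbs(geno, ann)
    np.testing.assert_allclose(
        gbs.to_numpy(), ref[gbs.columns].to_numpy(), atol=1e-10
    )


def test_adding_a_carried_variant_strictly_increases_score(rng):
    geno = random_genotypes(rng, 3, 4)
    ann = random_annotations(rng, geno.variant_ids, n_genes=2)
    ann["gene"] = ["G0", "G0", "G1", "G1"]
    ann["functional"] = True
    ann["af"] = 0.001
    ann["score"] = np.abs(ann["score"])
    before = compute_gbs(geno, ann)
    extra = GenotypeMatrix(
        geno.sample_ids,
        np.append(geno.variant_ids, "v_new"),
        np.column_stack([geno.dosages, np.array([1, 0, 0], dtype=np.int16)]),
    )
    ann2 = pd.concat(
        [ann, pd.DataFrame({"variant_id": ["v_new"], "gene": ["G0"], "af": [0.002],
                            "score": [2.0], "functional": [True]})],
        ignore_index=True,
    )
    after = compute_gbs(extra, ann2)
    assert after.loc["S0", "G0"] > before.loc["S0", "G0"]
    assert after.loc["S1", "G0"] == before.loc["S1", "G0"]  # non-carrier unchanged


def test_common_variant_never_contributes(rng):
    """Excluding a variant at/above the MAF threshold changes no score."""
    geno = random_genotypes(rng, 10, 6)
    ann = random_annotations(rng, geno.variant_ids)
    ann.loc[2, "af"] = 0.05  # above threshold
    with_common = compute_gbs(geno, ann)
    dropped = GenotypeMatrix(
        geno.sample_ids,
        np.delete(geno.variant_ids, 2),
        np.delete(geno.dosages, 2, axis=1),
    )
    without = compute_gbs(dropped, ann[ann["variant_id"] != ann.loc[2, "variant_id"]])
    shared = [c for c in with_common.columns if c in without.columns]
    np.testing.assert_allclose(
        with_common[shared].to_numpy(), without[shared].to_numpy(), atol=1e-12
    )


def test_unannotated_variant_warned_and_excluded(rng, caplog):
    geno = random_genotypes(rng, 5, 6)
    ann = random_annotations(rng, geno.variant_ids[:-1])
    with caplog.at_level("WARNING"):
        gbs = compute_gbs(geno, ann)
    assert "absent from annotations" in caplog.text
    ref = brute_force_gbs(
        GenotypeMatrix(geno.sample_ids, geno.variant_ids[:-1], geno.dosages[:, :-1]),
        ann,
    )
    np.testing.assert_allclose(gbs.to_numpy(), ref[gbs.columns].to_numpy(), atol=1e-10)


def test_gene_without_qualifying_variants_is_zero_and_flagged(rng):
    geno = random_genotypes(rng, 5, 3)
    ann = pd.DataFrame(
        {"variant_id": geno.variant_ids, "gene": ["G1", "G1", "G2"],
         "af": [0.001, 0.002, 0.05], "score": [1.0, 1.0, 1.0],
         "functional": [True, True, True]}
    )
    gbs = compute_gbs(geno, ann)
    assert (gbs["G2"] == 0).all()
    assert gbs.attrs["empty_genes"] == ["G2"]


def test_missing_dosage_policies(rng):
    geno = random_genotypes(rng, 50, 1)
    geno.dosages[0, 0] = -1
    ann = pd.DataFrame(
        {"variant_id": geno.variant_ids, "gene": ["G1"], "af": [0.003],
         "score": [1.0], "functional": [True]}
    )
    zero = compute_gbs(geno, ann, missing="zero")
    assert zero.iloc[0, 0] == 0.0
    mean = compute_gbs(geno, ann, missing="mean")
    w = variant_weight(0.003)
    expected = geno.dosages[1:, 0].mean() * w
    assert mean.iloc[0, 0] == pytest.approx(expected)
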
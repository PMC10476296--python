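"""Cohort preparation: statin back-adjustment, the 60/30/10 split, and
z-score feature normalisation.

Statin-treated lipid measurements are rescaled by a published on-treatment
factor (cholesterol 0.684, LDL 0.749, apolipoprotein B 0.719) to
approximate the untreated level; the default convention divides the
measured value by the factor. The cohort split assigns the first
floor(0.6 n) of a seeded random permutation to PRS construction + feature
selection, the next floor(0.3 n) to model training, and the remainder to
testing — the rounding rule that turns n = 145,464 into
(87,278, 43,639, 14,547). Normalisation statistics are always estimated on
a stated reference subset (the training split) and re-used verbatim on
held-out data.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class LeakageError(RuntimeError):
    """Raised when a stage touches samples outside its permitted split."""


class AdjustmentError(RuntimeError):
    """Raised on a second statin adjustment of the same trait."""


# ---------------------------------------------------------------------------
# statin adjustment
# ---------------------------------------------------------------------------


def adjust_for_statins(
    values,
    statin_flags,
    trait: str,
    factors,
    direction: str = "divide",
) -> np.ndarray:
    """Rescale statin users' measurements to the untreated scale.

    ``direction='divide'`` (default) computes measured / factor for users;
    ``'multiply'`` is available because the literature factor could be
    stated either way. Traits without a configured factor pass through
    unchanged with a warning.
    """
    values = np.asarray(values, dtype=float)
    flags = np.asarray(statin_flags, dtype=bool)
    if values.shape != flags.shape:
        raise ValueError("values and statin_flags must align")
    if trait not in factors:
        log.warning("no statin factor configured for trait %r; values unchanged", trait)
        return values.copy()
    factor = float(factors[trait])
    if factor <= 0:
        raise ValueError(f"statin factor for {trait} must be positive, got {factor}")
    out = values.copy()
    if direction == "divide":
        out[flags] = values[flags] / factor
    elif direction == "multiply":
        out[flags] = values[flags] * factor
    else:
        raise ValueError(f"unknown adjustment direction {direction!r}")
    return out


def adjust_table(
    pheno: pd.DataFrame,
    trait: str,
    factors,
    column: str = "biomarker",
    direction: str = "divide",
) -> pd.DataFrame:
    """Statin-adjust one biomarker column of a phenotype table.

    The returned table records the adjustment in ``attrs``; adjusting the
    same trait a second time raises :class:`AdjustmentError` so the
    correction cannot be applied twice.
    """
    done = set(pheno.attrs.get("statin_adjusted", ()))
    if trait in done:
        raise AdjustmentError(f"trait {trait!r} already statin-adjusted")
    out = pheno.copy()
    out[column] = adjust_for_statins(
        pheno[column].to_numpy(), pheno["statin"].to_numpy(), trait, factors, direction
    )
    out.attrs["statin_adjusted"] = sorted(done | {trait})
    return out


# ---------------------------------------------------------------------------
# cohort split
# ---------------------------------------------------------------------------


@dataclass
class CohortSplit:
    construction_ids: np.ndarray
    training_ids: np.ndarray
    test_ids: np.ndarray

    def __post_init__(self) -> None:
        sets = [set(self.construction_ids), set(self.training_ids), set(self.test_ids)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("split subsets overlap")

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.construction_ids), len(self.training_ids), len(self.test_ids))

    def all_ids(self) -> np.ndarray:
        return np.concatenate([self.construction_ids, self.training_ids, self.test_ids])


def split_cohort(
    sample_ids,
    fractions: tuple[float, float, float] = (0.6, 0.3, 0.1),
    seed: int = 0,
) -> CohortSplit:
    """Seeded random partition; floor rounding for the first two subsets,
    remainder to test."""
    ids = np.asarray(list(sample_ids), dtype=object)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(ids)
    n_con = int(np.floor(fractions[0] * n))
    n_tr = int(np.floor(fractions[1] * n))
    n_te = n - n_con - n_tr
    if min(n_con, n_tr, n_te) == 0:
        raise ValueError(f"split of n={n} with fractions {fractions} leaves an empty subset")
    perm = np.random.default_rng(seed).permutation(n)
    shuffled = ids[perm]
    return CohortSplit(
        construction_ids=shuffled[:n_con],
        training_ids=shuffled[n_con : n_con + n_tr],
        test_ids=shuffled[n_con + n_tr :],
    )


def write_split(split: CohortSplit, path) -> None:
    rows = [
        (sid, name)
        for name, ids in (
            ("construction", split.construction_ids),
            ("training", split.training_ids),
            ("test", split.test_ids),
        )
        for sid in ids
    ]
    pd.DataFrame(rows, columns=["sample_id", "subset"]).to_csv(path, sep="\t", index=False)


def read_split(path) -> CohortSplit:
    df = pd.read_csv(path, sep="\t")
    by = {name: g["sample_id"].to_numpy(dtype=object) for name, g in df.groupby("subset")}
    return CohortSplit(by["construction"], by["training"], by["test"])


def assert_within_split(sample_ids, allowed_ids, stage: str) -> None:
    """Guard: every id used by ``stage`` must belong to its permitted subset."""
    outside = set(sample_ids) - set(allowed_ids)
    if outside:
        raise LeakageError(
            f"{stage} used {len(outside)} sample(s) outside its permitted split, "
            f"e.g. {sorted(outside)[:3]}"
        )


# ---------------------------------------------------------------------------
# z-score normalisation
# ---------------------------------------------------------------------------


@dataclass
class NormalizationStats:
    mean: pd.Series
    sd: pd.Series  # sample (n-1) standard deviation
    dropped: list[str] = field(default_factory=list)
    reference_n: int = 0


def fit_normalization(features: pd.DataFrame, reference_ids) -> NormalizationStats:
    """Per-feature mean/sd on the reference subset; zero-variance features
    are dropped (recorded, logged), never divided by."""
    ref = features.loc[list(reference_ids)]
    if ref.empty:
        raise ValueError("reference subset is empty")
    mean = ref.mean()
    sd = ref.std(ddof=1)
    dropped = sorted(sd.index[(sd == 0) | sd.isna()].tolist())
    if dropped:
        log.warning("dropping %d zero-variance feature(s): %s", len(dropped), dropped[:5])
    keep = [c for c in features.columns if c not in dropped]
    return NormalizationStats(
        mean=mean[keep], sd=sd[keep], dropped=dropped, reference_n=len(ref)
    )


def apply_normalization(features: pd.DataFrame, stats: NormalizationStats) -> pd.DataFrame:
    """(x - mean) / sd with the *stored* statistics; never re-estimates."""
    cols = stats.mean.index
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise KeyError(f"features missing columns {missing[:5]}")
    return (features[cols] - stats.mean) / stats.sd
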
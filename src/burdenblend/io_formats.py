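"""On-disk artifacts: genotypes, annotations, phenotypes, score matrices,
association tables and the run configuration.

All tabular artifacts are tab-delimited UTF-8 with a header row. Genotypes
may come as VCF (GT-based, biallelic sites only) or as a plain dosage table
(samples x variants, first column = sample id). Floats are written with
17 significant digits so every value survives a write/read round-trip
exactly.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

#: sentinel for a missing genotype call in the integer dosage matrix
MISSING = -1

FLOAT_FMT = "%.17g"

ANNOTATION_COLUMNS = ("variant_id", "gene", "af", "score")
COVARIATE_COLUMNS = ("age", "sex", "bmi", "pc1", "pc2", "pc3", "pc4")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Samples x variants matrix of alternate-allele counts.

    ``dosages`` holds integers in {0, 1, 2}; a missing call is stored as
    :data:`MISSING` (-1), never silently as 0.
    """

    sample_ids: np.ndarray
    variant_ids: np.ndarray
    dosages: np.ndarray
    panel: str | None = None
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        self.dosages = np.asarray(self.dosages)
        if self.dosages.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise FormatError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variant_ids)} variants"
            )
        for name, ids in (("sample", self.sample_ids), ("variant", self.variant_ids)):
            if len(set(ids)) != len(ids):
                dup = pd.Index(ids)[pd.Index(ids).duplicated()].tolist()
                raise FormatError(f"duplicated {name} id(s): {dup[:5]}")
        d = self.dosages
        if d.dtype.kind in "iu":
            bad = (d < MISSING) | (d > 2)
        else:
            bad = ~np.isin(d, (MISSING, 0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"dosage {self.dosages[i, j]!r} at sample {self.sample_ids[i]}, "
                f"variant {self.variant_ids[j]} is not in {{0,1,2}} or missing"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def dosage_float(self, missing: str = "zero") -> np.ndarray:
        """Dosages as float with missing calls imputed.

        ``missing='zero'`` sets missing calls to 0 (no contribution);
        ``'mean'`` substitutes the per-variant mean of observed dosages.
        """
        out = self.dosages.astype(float)
        mask = self.missing_mask
        if not mask.any():
            return out
        if missing == "zero":
            out[mask] = 0.0
        elif missing == "mean":
            obs = np.ma.masked_array(out, mask)
            means = obs.mean(axis=0).filled(0.0)
            out[mask] = np.broadcast_to(means, out.shape)[mask]
        else:
            raise ValueError(f"unknown missing policy {missing!r}")
        return out

    def allele_frequencies(self) -> np.ndarray:
        """Cohort alternate-allele frequency per variant (observed calls only)."""
        obs = np.ma.masked_array(self.dosages.astype(float), self.missing_mask)
        return (obs.mean(axis=0) / 2.0).filled(np.nan)

    def subset_samples(self, ids: Sequence) -> "GenotypeMatrix":
        idx = pd.Index(self.sample_ids).get_indexer(list(ids))
        if (idx < 0).any():
            missing = [i for i, k in zip(ids, idx) if k < 0]
            raise KeyError(f"samples not in genotype matrix: {missing[:5]}")
        return GenotypeMatrix(
            np.asarray(list(ids), dtype=object),
            self.variant_ids.copy(),
            self.dosages[idx],
            panel=self.panel,
            positions=None if self.positions is None else self.positions.copy(),
        )


def _looks_like_vcf(path: Path) -> bool:
    if path.suffix == ".vcf":
        return True
    with open(path, "rt", encoding="utf-8") as fh:
        return fh.readline().startswith("##fileformat=VCF")


def read_genotypes(path, panel: str | None = None) -> GenotypeMatrix:
    """Read a VCF or a dosage table into a :class:`GenotypeMatrix`.

    Dosage = count of alternate alleles from the GT field. Missing calls
    (``./.``) become :data:`MISSING`. Multi-allelic records are rejected —
    split them upstream.
    """
    path = Path(path)
    if _looks_like_vcf(path):
        return _read_vcf(path, panel)
    return _read_dosage_table(path, panel)


def _read_vcf(path: Path, panel: str | None) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise FormatError(f"duplicated sample id in VCF header of {path}")
    variant_ids: list[str] = []
    positions: list[int] = []
    columns: list[np.ndarray] = []
    for line_no, v in enumerate(vcf, start=1):
        if len(v.ALT) != 1:
            raise FormatError(
                f"{path}: record {line_no} ({v.CHROM}:{v.POS}) is not biallelic; "
                "split multi-allelic sites upstream"
            )
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}:{v.REF}:{v.ALT[0]}"
        variant_ids.append(vid)
        positions.append(v.POS)
        col = np.empty(len(samples), dtype=np.int16)
        for i, gt in enumerate(v.genotypes):
            alleles = gt[:-1]
            if any(a < 0 for a in alleles):
                col[i] = MISSING
            else:
                col[i] = sum(1 for a in alleles if a == 1)
        columns.append(col)
    dosages = (
        np.column_stack(columns) if columns else np.empty((len(samples), 0), dtype=np.int16)
    )
    return GenotypeMatrix(
        np.asarray(samples, dtype=object),
        np.asarray(variant_ids, dtype=object),
        dosages,
        panel=panel,
        positions=np.asarray(positions),
    )


def _read_dosage_table(path: Path, panel: str | None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    mat = np.empty(df.shape, dtype=np.int16)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            if raw is np.nan or raw in ("", "NA", "."):
                mat[i, j] = MISSING
                continue
            try:
                val = int(raw)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: line {i + 2}: unparseable dosage {raw!r} "
                    f"for variant {col!r}"
                ) from None
            mat[i, j] = val
    return GenotypeMatrix(
        df.index.to_numpy(dtype=object),
        df.columns.to_numpy(dtype=object),
        mat,
        panel=panel,
    )


def write_genotypes(matrix: GenotypeMatrix, path) -> None:
    """Write genotypes as VCF (``.vcf`` suffix) or as a dosage table."""
    path = Path(path)
    if path.suffix == ".vcf":
        _write_vcf(matrix, path)
    else:
        df = pd.DataFrame(
            matrix.dosages, index=matrix.sample_ids, columns=matrix.variant_ids
        )
        df = df.astype(object).mask(matrix.missing_mask, ".")
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _write_vcf(matrix: GenotypeMatrix, path: Path) -> None:
    pos = (
        matrix.positions
        if matrix.positions is not None
        else np.arange(1, matrix.n_variants + 1) * 100
    )
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, matrix.sample_ids))
            + "\n"
        )
        for j, vid in enumerate(matrix.variant_ids):
            gts = "\t".join(_GT[int(d)] for d in matrix.dosages[:, j])
            fh.write(f"1\t{int(pos[j])}\t{vid}\tA\tC\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# variant annotations
# ---------------------------------------------------------------------------


def validate_annotations(df: pd.DataFrame, source: str = "<table>") -> pd.DataFrame:
    for col in ANNOTATION_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{source}: required annotation column {col!r} is missing")
    df = df.copy()
    if df["variant_id"].duplicated().any():
        dup = df.loc[df["variant_id"].duplicated(), "variant_id"].tolist()
        raise FormatError(f"{source}: duplicated variant_id(s): {dup[:5]}")
    af = pd.to_numeric(df["af"], errors="coerce")
    out_of_range = af.notna() & ((af < 0) | (af > 1))
    if out_of_range.any():
        bad = df.loc[out_of_range, ["variant_id", "af"]].iloc[0]
        raise FormatError(
            f"{source}: allele frequency {bad['af']} for variant "
            f"{bad['variant_id']} outside [0, 1]"
        )
    df["af"] = af
    df["score"] = pd.to_numeric(df["score"], errors="coerce")
    if "functional" not in df.columns:
        df["functional"] = True
    df["functional"] = df["functional"].astype(bool)
    gene_missing = df["gene"].isna() | (df["gene"].astype(str).str.strip() == "")
    # incomplete rows are flagged, never dropped, so the caller decides
    df["complete"] = ~(gene_missing | df["af"].isna() | df["score"].isna())
    if (~df["complete"]).any():
        log.warning(
            "%s: %d annotation row(s) incomplete (missing gene, AF or score)",
            source,
            int((~df["complete"]).sum()),
        )
    return df


def read_annotations(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return validate_annotations(df, source=str(path))


def write_annotations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# phenotypes / covariates
# ---------------------------------------------------------------------------


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype/covariate table indexed by sample_id.

    Required columns: biomarker (missing allowed), age, sex, bmi, pc1..pc4,
    statin (boolean flag).
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = ("sample_id", "biomarker") + COVARIATE_COLUMNS + ("statin",)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: required phenotype column {col!r} is missing")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicated sample_id")
    df = df.set_index("sample_id")
    df["statin"] = df["statin"].astype(bool)
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="sample_id", float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# score matrices and association tables
# ---------------------------------------------------------------------------


def write_score_matrix(scores: pd.DataFrame, path) -> None:
    """Samples x genes (or a single-column PRS) table; deterministic column order."""
    scores = scores.reindex(sorted(scores.columns), axis=1)
    scores.to_csv(path, sep="\t", index=True, index_label="sample_id", float_format=FLOAT_FMT)


def read_score_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id", float_precision="round_trip")


def write_association_table(table: pd.DataFrame, path) -> None:
    """Deterministic row order: by gene symbol, then genomic position."""
    sort_cols = ["gene"] + (["position"] if "position" in table.columns else [])
    out = table.reset_index() if table.index.name == "gene" else table.copy()
    out = out.sort_values(sort_cols, kind="mergesort")
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_association_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "tested" in df.columns:
        df["tested"] = df["tested"].astype(bool)
    return df.set_index("gene")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Analysis-wide constants.

    The defaults are the study conditions: MAF threshold 0.01 with
    Beta(1, 25) up-weighting for the burden scores, a 60/30/10
    construction/training/test split, alpha 0.05 with Bonferroni
    correction, 10-fold cross-validation, and statin back-adjustment
    factors for cholesterol (0.684), LDL (0.749) and apolipoprotein B
    (0.719).
    """

    maf_threshold: float = 0.01
    beta_a: float = 1.0
    beta_b: float = 25.0
    split_fractions: tuple[float, float, float] = (0.6, 0.3, 0.1)
    alpha: float = 0.05
    cv_folds: int = 10
    statin_factors: Mapping[str, float] = field(
        default_factory=lambda: {
            "cholesterol": 0.684,
            "ldl": 0.749,
            "apolipoprotein_b": 0.719,
        }
    )
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.maf_threshold < 1:
            raise ValueError("maf_threshold must lie in (0, 1)")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split_fractions must sum to 1")
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise ValueError("beta shape parameters must be positive")
        for trait, f in self.statin_factors.items():
            if not 0 < f <= 1:
                raise ValueError(f"statin factor for {trait} must lie in (0, 1]")


def load_config(path) -> RunConfig:
    with open(path, "rt", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if "split_fractions" in raw:
        raw["split_fractions"] = tuple(raw["split_fractions"])
    return RunConfig(**raw)


def save_config(config: RunConfig, path) -> None:
    raw = dataclasses.asdict(config)
    raw["split_fractions"] = list(raw["split_fractions"])
    raw["statin_factors"] = dict(raw["statin_factors"])
    with open(path, "wt", encoding="utf-8") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)
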
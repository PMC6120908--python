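"""Genotype, phenotype and PRS-weight tables: containers, validation, I/O.

SNP genotypes use the additive encoding: the dosage of the counted (by
default minor) allele, so 0 = homozygous major, 1 = heterozygous,
2 = homozygous minor.  A missing call is stored as :data:`MISSING` (-1).

Two on-disk dialects are supported:

``csv``
    One row per sample.  Leading columns ``sample_id, status, er_status,
    cohort`` followed by one column per SNP; missing token ``NA``.
``plink_raw``
    Whitespace-separated PLINK ``.raw``-style table with header
    ``FID IID PAT MAT SEX PHENOTYPE`` then one column per SNP.
    ``PHENOTYPE`` is 1 = control / 2 = case; ``FID`` carries the cohort
    label.  ER status is not representable in ``.raw`` and round-trips as
    ``unknown``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1
ER_STATES = ("positive", "negative", "unknown")
_CSV_MISSING_TOKEN = "NA"
_CSV_META_COLUMNS = ["sample_id", "status", "er_status", "cohort"]
_RAW_META_COLUMNS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


class GenotypeError(ValueError):
    """Invalid genotype content (encoding, duplicate ids, shape)."""


class ParseError(GenotypeError):
    """Malformed on-disk table; message names the offending row/column."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))
        raise GenotypeError(f"duplicate {what} id: {dup!r}")


@dataclass(frozen=True)
class GenotypeMatrix:
    """Additive-encoded dosage matrix with sample and SNP identifiers.

    Parameters
    ----------
    sample_ids, snp_ids
        Ordered, unique identifiers matching the matrix dimensions.
    dosage
        ``(n_samples, n_snps)`` integer array with entries in
        ``{0, 1, 2, MISSING}``.
    """

    sample_ids: tuple[str, ...]
    snp_ids: tuple[str, ...]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "snp_ids", tuple(str(s) for s in self.snp_ids))
        dosage = np.asarray(self.dosage)
        if not np.issubdtype(dosage.dtype, np.integer):
            if not np.array_equal(dosage, np.round(dosage)):
                raise GenotypeError("dosage entries must be integers")
            dosage = dosage.astype(np.int8)
        object.__setattr__(self, "dosage", dosage)
        if dosage.ndim != 2 or dosage.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise GenotypeError(
                f"dosage shape {dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.snp_ids, "SNP")
        bad = ~np.isin(dosage, (0, 1, 2, MISSING))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise GenotypeError(
                f"invalid dosage {dosage[r, c]} at sample {self.sample_ids[r]!r}, "
                f"SNP {self.snp_ids[c]!r}; expected 0/1/2 or missing"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} not in matrix") from None

    def restrict_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        """Sub-matrix with SNP columns in the requested order."""
        idx = [self.snp_index(s) for s in snp_ids]
        return GenotypeMatrix(self.sample_ids, tuple(snp_ids), self.dosage[:, idx])

    def take_samples(self, indices: Sequence[int]) -> "GenotypeMatrix":
        indices = np.asarray(indices, dtype=int)
        ids = tuple(self.sample_ids[i] for i in indices)
        return GenotypeMatrix(ids, self.snp_ids, self.dosage[indices])

    def values(self, dtype=np.float64) -> np.ndarray:
        """Dosage as a float array suitable for model fitting."""
        return self.dosage.astype(dtype)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=list(self.sample_ids), columns=list(self.snp_ids))


@dataclass(frozen=True)
class PhenotypeTable:
    """Per-sample case/control status, ER subtype and cohort label.

    ``er_status`` may be ``positive``/``negative`` only for cases
    (``status == 1``); controls are always ``unknown``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        missing = [c for c in _CSV_META_COLUMNS if c not in df.columns]
        if missing:
            raise GenotypeError(f"phenotype table missing columns: {missing}")
        df = df[_CSV_META_COLUMNS].reset_index(drop=True)
        df["sample_id"] = df["sample_id"].astype(str)
        df["status"] = df["status"].astype(int)
        df["er_status"] = df["er_status"].astype(str)
        df["cohort"] = df["cohort"].astype(str)
        _check_unique(list(df["sample_id"]), "sample")
        if not df["status"].isin((0, 1)).all():
            raise GenotypeError("status must be 0 (control) or 1 (case)")
        if not df["er_status"].isin(ER_STATES).all():
            bad = df.loc[~df["er_status"].isin(ER_STATES), "er_status"].iloc[0]
            raise GenotypeError(f"invalid er_status {bad!r}")
        bad_er = (df["status"] == 0) & (df["er_status"] != "unknown")
        if bad_er.any():
            sid = df.loc[bad_er, "sample_id"].iloc[0]
            raise GenotypeError(f"control {sid!r} has non-unknown er_status")
        object.__setattr__(self, "frame", df)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.frame["sample_id"])

    @property
    def status(self) -> np.ndarray:
        return self.frame["status"].to_numpy()

    @property
    def er_status(self) -> np.ndarray:
        return self.frame["er_status"].to_numpy()

    @property
    def cohort(self) -> np.ndarray:
        return self.frame["cohort"].to_numpy()

    def for_samples(self, sample_ids: Sequence[str]) -> "PhenotypeTable":
        """Rows reordered to match ``sample_ids`` (all must be present)."""
        df = self.frame.set_index("sample_id")
        try:
            sub = df.loc[list(sample_ids)].reset_index()
        except KeyError as exc:
            raise GenotypeError(f"sample id missing from phenotype table: {exc}") from None
        return PhenotypeTable(sub)

    def labels_for(self, matrix: GenotypeMatrix) -> np.ndarray:
        """Case/control labels aligned to the matrix's sample order."""
        return self.for_samples(matrix.sample_ids).status


@dataclass(frozen=True)
class SnpAnnotation:
    """Allele bookkeeping for one SNP: which allele the dosage counts."""

    snp_id: str
    chrom: str
    pos: int
    allele_a: str
    allele_b: str
    counted_allele: str

    def __post_init__(self) -> None:
        if self.counted_allele not in (self.allele_a, self.allele_b):
            raise GenotypeError(
                f"{self.snp_id}: counted allele {self.counted_allele!r} is neither "
                f"{self.allele_a!r} nor {self.allele_b!r}"
            )

    @property
    def other_allele(self) -> str:
        return self.allele_b if self.counted_allele == self.allele_a else self.allele_a


@dataclass(frozen=True)
class WeightTable:
    """PRS weights: per-SNP effect allele and published odds ratio."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy().reset_index(drop=True)
        required = ["snp_id", "effect_allele", "odds_ratio"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise GenotypeError(f"weight table missing columns: {missing}")
        df = df[required]
        df["snp_id"] = df["snp_id"].astype(str)
        df["effect_allele"] = df["effect_allele"].astype(str)
        df["odds_ratio"] = df["odds_ratio"].astype(float)
        _check_unique(list(df["snp_id"]), "weight-table SNP")
        if not (df["odds_ratio"] > 0).all():
            raise GenotypeError("odds ratios must be positive")
        object.__setattr__(self, "frame", df)

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(self.frame["snp_id"])

    @property
    def beta(self) -> np.ndarray:
        """Per-SNP log odds ratio, the standard PRS weight."""
        return np.log(self.frame["odds_ratio"].to_numpy())

    @property
    def odds_ratio(self) -> np.ndarray:
        return self.frame["odds_ratio"].to_numpy()

    def effect_allele_of(self, snp_id: str) -> str:
        row = self.frame.loc[self.frame["snp_id"] == snp_id]
        if row.empty:
            raise KeyError(snp_id)
        return row["effect_allele"].iloc[0]

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of aligning dosages to PRS effect alleles."""

    matrix: GenotypeMatrix
    flipped_snps: tuple[str, ...]
    missing_snps: tuple[str, ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# parsing helpers


def _parse_dosage_block(block: pd.DataFrame, snp_cols: Sequence[str], sample_ids: Sequence[str]) -> np.ndarray:
    out = np.empty((len(block), len(snp_cols)), dtype=np.int8)
    for j, col in enumerate(snp_cols):
        tokens = block[col].astype(str).str.strip()
        valid = tokens.isin(("0", "1", "2", _CSV_MISSING_TOKEN, "nan"))
        if not valid.all():
            i = int(np.flatnonzero(~valid.to_numpy())[0])
            raise ParseError(
                f"malformed genotype token {tokens.iloc[i]!r} for sample "
                f"{sample_ids[i]!r}, SNP column {col!r}"
            )
        vals = tokens.replace({_CSV_MISSING_TOKEN: MISSING, "nan": MISSING}).astype(int)
        out[:, j] = vals.to_numpy()
    return out


def read_genotype_table(path, dialect: str = "csv") -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Read a genotype + phenotype table from ``path``.

    Returns the dosage matrix (SNP column order preserved from the file)
    and the phenotype table, row-aligned to the matrix samples.
    """
    path = Path(path)
    if dialect == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in _CSV_META_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing metadata columns {missing}")
        snp_cols = [c for c in df.columns if c not in _CSV_META_COLUMNS]
        sample_ids = tuple(df["sample_id"])
        _check_unique(sample_ids, "sample")
        dosage = _parse_dosage_block(df, snp_cols, sample_ids)
        matrix = GenotypeMatrix(sample_ids, tuple(snp_cols), dosage)
        pheno = PhenotypeTable(df[_CSV_META_COLUMNS])
        return matrix, pheno
    if dialect == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", dtype=str, keep_default_na=False)
        missing = [c for c in _RAW_META_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing .raw columns {missing}")
        snp_cols = [c for c in df.columns if c not in _RAW_META_COLUMNS]
        sample_ids = tuple(df["IID"])
        _check_unique(sample_ids, "sample")
        dosage = _parse_dosage_block(df, snp_cols, sample_ids)
        matrix = GenotypeMatrix(sample_ids, tuple(snp_cols), dosage)
        phen_raw = df["PHENOTYPE"].astype(str)
        if not phen_raw.isin(("1", "2")).all():
            bad = phen_raw[~phen_raw.isin(("1", "2"))].iloc[0]
            raise ParseError(f"{path}: PHENOTYPE must be 1 (control) or 2 (case); got {bad!r}")
        pheno = PhenotypeTable(
            pd.DataFrame(
                {
                    "sample_id": list(sample_ids),
                    "status": (phen_raw == "2").astype(int),
                    "er_status": "unknown",
                    "cohort": df["FID"].astype(str),
                }
            )
        )
        return matrix, pheno
    raise ValueError(f"unknown dialect {dialect!r}; expected 'csv' or 'plink_raw'")


def write_genotype_table(matrix: GenotypeMatrix, phenotypes: PhenotypeTable, path, dialect: str = "csv") -> None:
    """Write ``matrix`` + ``phenotypes`` so that :func:`read_genotype_table`
    recovers identical content (ER status is lost in the ``plink_raw``
    dialect, which cannot represent it)."""
    path = Path(path)
    pheno = phenotypes.for_samples(matrix.sample_ids)
    dos = matrix.dosage.astype(object)
    dos_str = np.where(dos == MISSING, _CSV_MISSING_TOKEN, dos).astype(str)
    geno = pd.DataFrame(dos_str, columns=list(matrix.snp_ids))
    if dialect == "csv":
        out = pd.concat([pheno.frame.reset_index(drop=True), geno], axis=1)
        out.to_csv(path, index=False)
        return
    if dialect == "plink_raw":
        meta = pd.DataFrame(
            {
                "FID": pheno.cohort,
                "IID": list(pheno.sample_ids),
                "PAT": "0",
                "MAT": "0",
                "SEX": "0",
                "PHENOTYPE": pheno.status + 1,
            }
        )
        out = pd.concat([meta, geno], axis=1)
        out.to_csv(path, sep=" ", index=False)
        return
    raise ValueError(f"unknown dialect {dialect!r}; expected 'csv' or 'plink_raw'")


def read_weight_table(path) -> WeightTable:
    """Read a PRS weight table CSV with header ``snp_id,effect_allele,odds_ratio``."""
    return WeightTable(pd.read_csv(path, dtype={"snp_id": str, "effect_allele": str}))


def write_weight_table(weights: WeightTable, path) -> None:
    weights.frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# transformations


def drop_missing_snps(matrix: GenotypeMatrix, axis: str = "snp") -> GenotypeMatrix:
    """Remove missing genotype calls.

    The default (``axis='snp'``) drops every SNP column containing at least
    one missing call, leaving the sample set unchanged; ``axis='sample'``
    instead drops samples with any missing call.
    """
    if axis == "snp":
        keep = ~(matrix.dosage == MISSING).any(axis=0)
        if not keep.any():
            raise GenotypeError("no SNPs remain after dropping columns with missing calls")
        if keep.all():
            return matrix
        ids = tuple(s for s, k in zip(matrix.snp_ids, keep) if k)
        return GenotypeMatrix(matrix.sample_ids, ids, matrix.dosage[:, keep])
    if axis == "sample":
        keep = ~(matrix.dosage == MISSING).any(axis=1)
        if not keep.any():
            raise GenotypeError("no samples remain after dropping rows with missing calls")
        if keep.all():
            return matrix
        ids = tuple(s for s, k in zip(matrix.sample_ids, keep) if k)
        return GenotypeMatrix(ids, matrix.snp_ids, matrix.dosage[keep])
    raise ValueError(f"axis must be 'snp' or 'sample', got {axis!r}")


def align_dosages_to_effect_allele(
    matrix: GenotypeMatrix,
    annotations: Mapping[str, SnpAnnotation] | Iterable[SnpAnnotation],
    weights: WeightTable,
) -> AlignmentResult:
    """Flip dosages so each weight-table SNP counts its effect allele.

    For SNPs whose counted allele differs from the weight table's effect
    allele the dosage is reflected ``g -> 2 - g`` (missing calls stay
    missing).  Weight-table SNPs absent from the matrix are reported in
    ``missing_snps``, never invented.
    """
    if not isinstance(annotations, Mapping):
        annotations = {a.snp_id: a for a in annotations}
    dosage = matrix.dosage.copy()
    flipped: list[str] = []
    absent: list[str] = []
    for snp_id in weights.snp_ids:
        if snp_id not in set(matrix.snp_ids):
            absent.append(snp_id)
            continue
        if snp_id not in annotations:
            raise GenotypeError(f"no annotation for weight-table SNP {snp_id!r}")
        ann = annotations[snp_id]
        effect = weights.effect_allele_of(snp_id)
        if effect not in (ann.allele_a, ann.allele_b):
            raise GenotypeError(
                f"{snp_id}: effect allele {effect!r} matches neither annotated allele "
                f"({ann.allele_a!r}/{ann.allele_b!r})"
            )
        if effect != ann.counted_allele:
            j = matrix.snp_index(snp_id)
            col = dosage[:, j]
            nonmiss = col != MISSING
            col[nonmiss] = 2 - col[nonmiss]
            flipped.append(snp_id)
    if absent:
        warnings.warn(f"{len(absent)} weight-table SNPs absent from matrix: {absent[:5]}...")
    aligned = GenotypeMatrix(matrix.sample_ids, matrix.snp_ids, dosage)
    return AlignmentResult(aligned, tuple(flipped), tuple(absent))
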
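"""Genotype and tabular I/O.

The in-memory container is :class:`GenotypeDataset`: a samples x variants
matrix of risk-allele dosages (0/1/2, ``-1`` = missing call) plus variant
metadata and an optional per-sample phenotype/covariate table. Dosage counts
copies of ``allele1``, the designated effect allele (PLINK convention: the
A1 column of a BIM file is the counted allele).

On disk the canonical dialect is the PLINK v1 binary fileset
(BED + BIM + FAM, SNP-major). A whitespace-separated text dialect
(``<prefix>.gt.tsv``) is provided for human-readable fixtures. Coordinates
are 1-based in files, as in BIM; all internal indices are 0-based.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "VariantRecord",
    "GenotypeDataset",
    "read_plink",
    "write_plink",
    "read_plink_text",
    "write_plink_text",
    "read_table",
    "write_table",
    "PHENO_SCHEMA",
]

#: sentinel for a missing genotype call in the dosage matrix
MISSING = -1

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

VARIANT_COLUMNS = ["id", "chrom", "pos", "allele1", "allele2"]

#: phenotype/covariate table schema (TSV)
PHENO_SCHEMA: Mapping[str, type] = {
    "sample_id": str,
    "phenotype": float,
    "sex": float,
    "age": float,
    "status1": float,
    "status2": float,
}


@dataclasses.dataclass(frozen=True)
class VariantRecord:
    """A single biallelic variant; ``allele1`` is the counted (effect) allele."""

    id: str
    chrom: str
    pos: int
    allele1: str
    allele2: str

    def __post_init__(self) -> None:
        if self.allele1 == self.allele2:
            raise ValueError(f"variant {self.id}: allele1 == allele2 ({self.allele1})")
        if self.pos <= 0:
            raise ValueError(f"variant {self.id}: position must be positive, got {self.pos}")


class GenotypeDataset:
    """Samples x variants dosage matrix with metadata.

    Parameters
    ----------
    sample_ids : ordered unique sample identifiers.
    variants : DataFrame with columns id, chrom, pos, allele1, allele2.
    dosages : int8 array, shape (n_samples, n_variants), entries in
        {0, 1, 2, -1} where -1 marks a missing call.
    phenotable : optional DataFrame indexed by sample_id.
    info_scores : optional per-variant imputation quality in [0, 1].
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        variants: pd.DataFrame,
        dosages: np.ndarray,
        phenotable: pd.DataFrame | None = None,
        info_scores: np.ndarray | None = None,
    ) -> None:
        self.sample_ids = list(map(str, sample_ids))
        variants = variants.reset_index(drop=True)[VARIANT_COLUMNS].copy()
        variants["pos"] = variants["pos"].astype(np.int64)
        self.variants = variants
        self.dosages = np.asarray(dosages, dtype=np.int8)
        self.phenotable = phenotable
        self.info_scores = None if info_scores is None else np.asarray(info_scores, float)
        self._validate()

    # -- basic protocol -------------------------------------------------
    def _validate(self) -> None:
        n, m = self.dosages.shape
        if n != len(self.sample_ids):
            raise ValueError(f"dosage rows ({n}) != number of samples ({len(self.sample_ids)})")
        if m != len(self.variants):
            raise ValueError(f"dosage columns ({m}) != number of variants ({len(self.variants)})")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if self.variants["id"].duplicated().any():
            dup = self.variants["id"][self.variants["id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate variant id: {dup}")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2} or -1 for missing")
        if (self.variants["allele1"] == self.variants["allele2"]).any():
            raise ValueError("allele1 must differ from allele2")
        if self.info_scores is not None and len(self.info_scores) != m:
            raise ValueError("info_scores length != number of variants")
        if self.phenotable is not None:
            missing = set(self.sample_ids) - set(self.phenotable.index.astype(str))
            if missing:
                raise ValueError(f"phenotable lacks {len(missing)} sample ids (e.g. {sorted(missing)[:3]})")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_records(self) -> list[VariantRecord]:
        return [
            VariantRecord(str(r.id), str(r.chrom), int(r.pos), str(r.allele1), str(r.allele2))
            for r in self.variants.itertuples(index=False)
        ]

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(
            list(self.sample_ids),
            self.variants.copy(),
            self.dosages.copy(),
            None if self.phenotable is None else self.phenotable.copy(),
            None if self.info_scores is None else self.info_scores.copy(),
        )

    # -- selection ------------------------------------------------------
    def take_samples(self, index: Sequence[int]) -> "GenotypeDataset":
        index = np.asarray(index, dtype=int)
        ids = [self.sample_ids[i] for i in index]
        pheno = None
        if self.phenotable is not None:
            pheno = self.phenotable.loc[ids]
        return GenotypeDataset(ids, self.variants, self.dosages[index], pheno, self.info_scores)

    def take_variants(self, index: Sequence[int]) -> "GenotypeDataset":
        index = np.asarray(index, dtype=int)
        info = None if self.info_scores is None else self.info_scores[index]
        return GenotypeDataset(
            self.sample_ids,
            self.variants.iloc[index],
            self.dosages[:, index],
            self.phenotable,
            info,
        )

    # -- summaries ------------------------------------------------------
    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def variant_call_rate(self) -> np.ndarray:
        return 1.0 - self.missing_mask().mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - self.missing_mask().mean(axis=1)

    def allele1_freq(self) -> np.ndarray:
        """Frequency of allele1 among non-missing calls (nan if none)."""
        d = self.dosages.astype(float)
        d[d == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele1_freq()
        return np.minimum(p, 1.0 - p)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.variants.equals(other.variants)
            and np.array_equal(self.dosages, other.dosages)
        )

    def __repr__(self) -> str:
        return f"<GenotypeDataset {self.n_samples} samples x {self.n_variants} variants>"


# ---------------------------------------------------------------------------
# PLINK v1 binary fileset
# ---------------------------------------------------------------------------

# PLINK v1 2-bit genotype codes (SNP-major), low bits = first sample:
#   00 -> homozygous A1 (dosage 2)   01 -> missing
#   10 -> heterozygous  (dosage 1)   11 -> homozygous A2 (dosage 0)
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def write_plink(dataset: GenotypeDataset, prefix: str | Path) -> None:
    """Write ``dataset`` as a PLINK v1 BED/BIM/FAM fileset (SNP-major)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = dataset.dosages.shape

    # BIM: chrom, id, genetic distance (0), pos, allele1, allele2
    bim = pd.DataFrame(
        {
            "chrom": dataset.variants["chrom"],
            "id": dataset.variants["id"],
            "cm": 0,
            "pos": dataset.variants["pos"],
            "allele1": dataset.variants["allele1"],
            "allele2": dataset.variants["allele2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    sex = np.zeros(n, dtype=int)
    if dataset.phenotable is not None and "sex" in dataset.phenotable.columns:
        s = dataset.phenotable.loc[dataset.sample_ids, "sex"].to_numpy(float)
        # FAM: 1 = male, 2 = female, 0 = unknown; internal coding 1 = male, 0 = female
        sex = np.where(np.isnan(s), 0, np.where(s > 0.5, 1, 2)).astype(int)
    fam = pd.DataFrame(
        {
            "fid": dataset.sample_ids,
            "iid": dataset.sample_ids,
            "father": 0,
            "mother": 0,
            "sex": sex,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    # BED payload: one row of ceil(n/4) bytes per variant
    codes = np.empty((m, n), dtype=np.uint8)
    d = dataset.dosages.T  # variant-major
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[d == dosage] = code
    n_pad = (-n) % 4
    if n_pad:
        codes = np.hstack([codes, np.zeros((m, n_pad), dtype=np.uint8)])
    quads = codes.reshape(m, -1, 4)
    packed = (quads[:, :, 0] | (quads[:, :, 1] << 2) | (quads[:, :, 2] << 4) | (quads[:, :, 3] << 6))
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
        fh.write(packed.astype(np.uint8).tobytes())


def read_plink(prefix: str | Path) -> GenotypeDataset:
    """Read a PLINK v1 BED/BIM/FAM fileset into a :class:`GenotypeDataset`."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "allele1", "allele2"],
        dtype={"chrom": str, "id": str, "allele1": str, "allele2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"iid": str},
    )
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise ValueError(
            f"{prefix.with_suffix('.bed')}: bad BED magic bytes at offset 0: "
            f"{raw[:2].hex()} (expected {_BED_MAGIC.hex()})"
        )
    if raw[2] != _SNP_MAJOR:
        raise ValueError(f"{prefix.with_suffix('.bed')}: only SNP-major BED (mode 0x01) is supported")
    bytes_per_variant = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != m * bytes_per_variant:
        raise ValueError(
            f"{prefix.with_suffix('.bed')}: payload of {payload.size} bytes does not match "
            f"{m} variants x {bytes_per_variant} bytes (BIM/FAM length mismatch?)"
        )
    rows = payload.reshape(m, bytes_per_variant)
    codes = np.empty((m, bytes_per_variant * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (rows >> (2 * k)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T  # samples x variants

    variants = pd.DataFrame(
        {
            "id": bim["id"],
            "chrom": bim["chrom"],
            "pos": bim["pos"].astype(np.int64),
            "allele1": bim["allele1"],
            "allele2": bim["allele2"],
        }
    )
    return GenotypeDataset(list(fam["iid"]), variants, dosages)


# ---------------------------------------------------------------------------
# Text dialect (human-readable fixtures)
# ---------------------------------------------------------------------------

def write_plink_text(dataset: GenotypeDataset, prefix: str | Path) -> None:
    """Write the text dialect: ``<prefix>.gt.tsv``, one row per variant.

    Columns: id, chrom, pos, allele1, allele2, then one dosage column per
    sample (NA = missing).
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    d = dataset.dosages.T.astype(object)
    d[d == MISSING] = "NA"
    table = pd.concat(
        [dataset.variants.reset_index(drop=True), pd.DataFrame(d, columns=dataset.sample_ids)],
        axis=1,
    )
    table.to_csv(Path(str(prefix) + ".gt.tsv"), sep="\t", index=False)


def read_plink_text(prefix: str | Path) -> GenotypeDataset:
    path = Path(str(prefix) + ".gt.tsv")
    table = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str, "allele1": str, "allele2": str})
    for col in VARIANT_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    sample_ids = [c for c in table.columns if c not in VARIANT_COLUMNS]
    d = table[sample_ids].to_numpy(dtype=object)
    dosages = np.full(d.shape, MISSING, dtype=np.int8)
    obs = ~pd.isna(d) & (d != "NA")
    dosages[obs] = d[obs].astype(float).astype(np.int8)
    return GenotypeDataset(sample_ids, table[VARIANT_COLUMNS], dosages.T)


# ---------------------------------------------------------------------------
# Generic typed TSV
# ---------------------------------------------------------------------------

def read_table(path: str | Path, schema: Mapping[str, type], index_col: str | None = None) -> pd.DataFrame:
    """Read a TSV with a required typed column schema; 'NA' maps to missing."""
    table = pd.read_csv(path, sep="\t", na_values=["NA"], dtype=str)
    for col in schema:
        if col not in table.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    out = pd.DataFrame(index=table.index)
    for col, typ in schema.items():
        if typ is float:
            out[col] = pd.to_numeric(table[col], errors="raise")
        elif typ is int:
            out[col] = pd.to_numeric(table[col], errors="raise").astype("Int64")
        else:
            out[col] = table[col]
    # keep any extra columns as strings
    for col in table.columns:
        if col not in out.columns:
            out[col] = table[col]
    if index_col is not None:
        out = out.set_index(index_col)
    return out


def write_table(table: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=index, na_rep="NA")


def read_phenotable(path: str | Path) -> pd.DataFrame:
    """Read the phenotype/covariate TSV, indexed by sample_id."""
    return read_table(path, PHENO_SCHEMA, index_col="sample_id")
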
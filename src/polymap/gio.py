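"""Genotype data model plus readers/writers for the formats the pipeline touches.

Coordinate conventions are centralized here: variant positions (VCF, result
tables) are 1-based, BED intervals and sliding windows are 0-based half-open.
Genotypes are stored as alt-allele dosage codes ``{0, 1, 2}`` with ``-1`` for
a missing call; phase is discarded everywhere (the analyses only use dosage).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel code for a missing genotype call.
MISSING: int = -1

_PHENOTYPE_CODES = {"1": "control", "2": "case", "0": None, "-9": None}
_PHENOTYPE_LABELS = {"control": "1", "case": "2", None: "0"}
_SEX_CODES = {"1": "M", "2": "F", "0": None}
_SEX_LABELS = {"M": "1", "F": "2", None: "0"}
_GT_STRINGS = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


class VcfError(ValueError):
    """Malformed or unsupported VCF content."""


class SampleFileError(ValueError):
    """Malformed FAM/PED-style sample file."""


@dataclass(frozen=True)
class VariantSite:
    """One biallelic variant; ``pos`` is 1-based as in VCF."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str | None = None
    vtype: str = "SNP"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if self.vtype not in ("SNP", "INDEL"):
            raise ValueError(f"unknown variant type {self.vtype!r}")

    @classmethod
    def from_alleles(cls, chrom: str, pos: int, ref: str, alt: str,
                     id: str | None = None) -> "VariantSite":
        vtype = "SNP" if len(ref) == 1 and len(alt) == 1 else "INDEL"
        return cls(chrom=chrom, pos=pos, ref=ref, alt=alt, id=id, vtype=vtype)


@dataclass
class GenotypeMatrix:
    """Samples x sites matrix of alt-dosage codes ``{0,1,2}``, ``-1`` missing."""

    sites: list[VariantSite]
    samples: list[str]
    codes: np.ndarray  # (n_samples, n_sites) int8

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D (samples x sites) array")
        n, s = self.codes.shape
        if n != len(self.samples) or s != len(self.sites):
            raise ValueError(
                f"codes shape {self.codes.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.sites)} sites")
        bad = ~np.isin(self.codes, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def dosages(self) -> np.ndarray:
        """Float copy of the codes with missing calls as ``nan``."""
        d = self.codes.astype(float)
        d[self.codes == MISSING] = np.nan
        return d

    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    def chromosomes(self) -> np.ndarray:
        return np.array([s.chrom for s in self.sites], dtype=object)

    def take_sites(self, indices: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=np.intp)
        return GenotypeMatrix(sites=[self.sites[i] for i in idx],
                              samples=list(self.samples),
                              codes=self.codes[:, idx])

    def take_samples(self, which: Sequence[int] | Sequence[str]) -> "GenotypeMatrix":
        if len(which) and isinstance(which[0], str):
            lookup = {s: i for i, s in enumerate(self.samples)}
            idx = np.array([lookup[w] for w in which], dtype=np.intp)
        else:
            idx = np.asarray(which, dtype=np.intp)
        return GenotypeMatrix(sites=list(self.sites),
                              samples=[self.samples[i] for i in idx],
                              codes=self.codes[idx, :])

    def site_index(self, chrom: str, pos: int) -> int:
        for i, s in enumerate(self.sites):
            if s.chrom == chrom and s.pos == pos:
                return i
        raise KeyError(f"no site at {chrom}:{pos}")


@dataclass
class SampleRecord:
    """Pedigree/phenotype record; ``phenotype`` is 'case', 'control' or None."""

    id: str
    family: str = "0"
    sire: str | None = None
    dam: str | None = None
    sex: str | None = None
    generation: str | None = None
    population: str | None = None
    phenotype: str | None = None


@dataclass(frozen=True)
class GeneInterval:
    """Gene/feature interval stored 0-based half-open (BED convention)."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty interval {self.name}: [{self.start}, {self.end})")

    def contains_position(self, pos: int) -> bool:
        """Whether a 1-based variant position falls inside the interval."""
        return self.start <= pos - 1 < self.end


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, multiallelic: str = "error") -> GenotypeMatrix:
    """Read a VCF v4.2 into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    multiallelic
        ``"error"`` rejects records with more than one ALT allele; ``"split"``
        expands them into one biallelic site per ALT (dosage of that allele).
    """
    from cyvcf2 import VCF

    if multiallelic not in ("error", "split"):
        raise ValueError("multiallelic must be 'error' or 'split'")
    path = Path(path)
    try:
        reader = VCF(str(path))
    except Exception as exc:  # htslib reports its own detail
        raise VcfError(f"{path}: cannot parse VCF header ({exc})") from exc
    samples = list(reader.samples)
    sites: list[VariantSite] = []
    columns: list[np.ndarray] = []
    record_no = 0
    try:
        for v in reader:
            record_no += 1
            alts = v.ALT
            if len(alts) == 0:
                continue
            if len(alts) > 1 and multiallelic == "error":
                raise VcfError(
                    f"{path}: multiallelic record {record_no} at "
                    f"{v.CHROM}:{v.POS} (use multiallelic='split')")
            gts = np.array([g[:2] for g in v.genotypes], dtype=np.int16)
            for k, alt in enumerate(alts, start=1):
                code = (gts == k).sum(axis=1).astype(np.int8)
                code[(gts < 0).any(axis=1)] = MISSING
                sites.append(VariantSite.from_alleles(
                    v.CHROM, v.POS, v.REF, alt,
                    id=None if v.ID in (None, ".") else v.ID))
                columns.append(code)
    except VcfError:
        raise
    except Exception as exc:
        raise VcfError(f"{path}: malformed record {record_no + 1} ({exc})") from exc
    if not sites:
        warnings.warn(f"{path}: VCF contains no variant records")
        codes = np.zeros((len(samples), 0), dtype=np.int8)
    else:
        codes = np.stack(columns, axis=1)
    return GenotypeMatrix(sites=sites, samples=samples, codes=codes)


def write_vcf(matrix: GenotypeMatrix, path: str | Path,
              chrom_lengths: Mapping[str, int] | None = None) -> Path:
    """Write a minimal deterministic VCF v4.2 with diploid GT calls."""
    path = Path(path)
    lines = ["##fileformat=VCFv4.2", "##source=polymap"]
    if chrom_lengths:
        for chrom, length in chrom_lengths.items():
            lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples))
    for j, site in enumerate(matrix.sites):
        gts = "\t".join(_GT_STRINGS[int(c)] for c in matrix.codes[:, j])
        lines.append(f"{site.chrom}\t{site.pos}\t{site.id or '.'}\t{site.ref}\t"
                     f"{site.alt}\t.\tPASS\t.\tGT\t{gts}")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# FAM-style sample files
# ---------------------------------------------------------------------------

def read_samples(path: str | Path) -> list[SampleRecord]:
    """Read a 6-column FAM file (family, id, sire, dam, sex, phenotype).

    Phenotype codes follow the FAM convention: 1=control, 2=case, 0/-9=missing.
    """
    path = Path(path)
    records: list[SampleRecord] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.split()
        if len(fields) < 6:
            raise SampleFileError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
        fam, sid, sire, dam, sex, pheno = fields[:6]
        if pheno not in _PHENOTYPE_CODES:
            raise SampleFileError(
                f"{path}:{lineno}: unknown phenotype code {pheno!r} "
                f"(expected one of {sorted(_PHENOTYPE_CODES)})")
        records.append(SampleRecord(
            id=sid, family=fam,
            sire=None if sire == "0" else sire,
            dam=None if dam == "0" else dam,
            sex=_SEX_CODES.get(sex),
            phenotype=_PHENOTYPE_CODES[pheno]))
    if not records:
        warnings.warn(f"{path}: empty sample file")
    return records


def write_samples(records: Iterable[SampleRecord], path: str | Path) -> Path:
    path = Path(path)
    lines = []
    for r in records:
        lines.append("\t".join([
            r.family, r.id, r.sire or "0", r.dam or "0",
            _SEX_LABELS.get(r.sex, "0"), _PHENOTYPE_LABELS[r.phenotype]]))
    path.write_text("\n".join(lines) + "\n")
    return path


def phenotype_vector(records: Sequence[SampleRecord],
                     samples: Sequence[str] | None = None) -> np.ndarray:
    """Binary phenotype vector (1=case, 0=control, nan=missing) aligned to samples."""
    by_id = {r.id: r for r in records}
    order = samples if samples is not None else [r.id for r in records]
    out = np.full(len(order), np.nan)
    for i, sid in enumerate(order):
        rec = by_id.get(sid)
        if rec is None or rec.phenotype is None:
            continue
        out[i] = 1.0 if rec.phenotype == "case" else 0.0
    return out


# ---------------------------------------------------------------------------
# BED gene intervals and chromosome lengths
# ---------------------------------------------------------------------------

def read_genes(path: str | Path) -> list[GeneInterval]:
    """Read BED4(+optional strand in column 6); BED is 0-based half-open."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty BED file")
        return []
    if df.shape[1] < 4:
        raise ValueError(f"{path}: BED4 requires at least 4 columns")
    genes = []
    for row in df.itertuples(index=False):
        strand = row[5] if len(row) >= 6 and row[5] in ("+", "-") else None
        genes.append(GeneInterval(name=str(row[3]), chrom=str(row[0]),
                                  start=int(row[1]), end=int(row[2]),
                                  strand=strand))
    return genes


def write_genes(genes: Iterable[GeneInterval], path: str | Path) -> Path:
    path = Path(path)
    lines = [f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}" +
             (f"\t.\t{g.strand}" if g.strand else "") for g in genes]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    """Two-column (chromosome, length-in-bp) TSV -> ordered mapping."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "length"], dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty chromosome-length file")
        return {}
    out: dict[str, int] = {}
    for chrom, length in zip(df["chrom"], df["length"]):
        length = int(length)
        if length <= 0:
            raise ValueError(f"{path}: non-positive length for chromosome {chrom}")
        out[str(chrom)] = length
    return out
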
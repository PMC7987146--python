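"""Readers, writers and container types for the formats the pipeline touches.

Conventions
-----------
* Coordinates are 1-based inclusive everywhere internally (matching printed
  CanFam3.1 coordinates); BED export converts to 0-based half-open at the
  boundary only.
* Genotype dosages count copies of ``allele2`` and live in ``{0, 1, 2}`` with
  ``-1`` as the missing sentinel.  Missing calls never contribute to allele
  counts; minor-allele frequency uses the non-missing denominator.
* Multi-allelic and indel VCF records are skipped, not decomposed — the
  array markers this pipeline models are biallelic SNVs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1

__all__ = [
    "MISSING",
    "Interval",
    "MarkerMap",
    "GenotypeMatrix",
    "HaplotypeMatrix",
    "read_vcf",
    "write_vcf",
    "read_plink_text",
    "write_plink_text",
    "filter_markers",
    "read_table",
    "write_bed",
]


@dataclass(frozen=True)
class Interval:
    """A 1-based inclusive genomic interval."""

    chrom: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(
                f"start_bp {self.start_bp} > end_bp {self.end_bp} on {self.chrom}"
            )

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start_bp <= pos <= self.end_bp

    def to_bed_fields(self) -> tuple[str, int, int]:
        """0-based half-open conversion, applied only at the BED boundary."""
        return self.chrom, self.start_bp - 1, self.end_bp


@dataclass
class MarkerMap:
    """Ordered marker metadata: ids, chromosome, physical and genetic position."""

    marker_id: np.ndarray  # object / str
    chrom: np.ndarray
    pos_bp: np.ndarray  # int64, 1-based
    pos_cm: Optional[np.ndarray] = None  # float, optional
    allele1: Optional[np.ndarray] = None
    allele2: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.marker_id = np.asarray(self.marker_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        if self.pos_cm is not None:
            self.pos_cm = np.asarray(self.pos_cm, dtype=float)
        if self.allele1 is not None:
            self.allele1 = np.asarray(self.allele1, dtype=object)
        if self.allele2 is not None:
            self.allele2 = np.asarray(self.allele2, dtype=object)
        self.validate()

    def validate(self) -> None:
        n = len(self.marker_id)
        for name in ("chrom", "pos_bp"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"MarkerMap field {name} has inconsistent length")
        for c in pd.unique(self.chrom):
            pos = self.pos_bp[self.chrom == c]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"pos_bp not strictly increasing within {c}")
            if self.pos_cm is not None:
                cm = self.pos_cm[self.chrom == c]
                if np.any(np.diff(cm) < 0):
                    raise ValueError(f"pos_cm decreasing within {c}")

    def __len__(self) -> int:
        return len(self.marker_id)

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        return MarkerMap(
            self.marker_id[idx],
            self.chrom[idx],
            self.pos_bp[idx],
            None if self.pos_cm is None else self.pos_cm[idx],
            None if self.allele1 is None else self.allele1[idx],
            None if self.allele2 is None else self.allele2[idx],
        )

    def indices_in(self, window: Interval) -> np.ndarray:
        """Indices of markers falling inside a 1-based inclusive interval."""
        return np.flatnonzero(
            (self.chrom == window.chrom)
            & (self.pos_bp >= window.start_bp)
            & (self.pos_bp <= window.end_bp)
        )

    def to_dataframe(self) -> pd.DataFrame:
        d = {"marker_id": self.marker_id, "chrom": self.chrom, "pos_bp": self.pos_bp}
        if self.pos_cm is not None:
            d["pos_cm"] = self.pos_cm
        if self.allele1 is not None:
            d["allele1"] = self.allele1
            d["allele2"] = self.allele2
        return pd.DataFrame(d)


@dataclass
class GenotypeMatrix:
    """individuals × markers dosage matrix (copies of allele2; -1 missing)."""

    individuals: list[str]
    markers: MarkerMap
    dosage: np.ndarray  # int8, shape (N, M)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n, m = self.dosage.shape
        if n != len(self.individuals) or m != len(self.markers):
            raise ValueError("dosage dimensions inconsistent with ids/markers")
        bad = ~np.isin(self.dosage, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosage values outside {0,1,2,missing}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def dosage_float(self) -> np.ndarray:
        """Dosages as float with NaN for missing calls."""
        x = self.dosage.astype(float)
        x[self.dosage == MISSING] = np.nan
        return x

    def allele_frequency(self) -> np.ndarray:
        """Per-marker allele2 frequency over non-missing calls (NaN if none)."""
        x = self.dosage_float()
        with np.errstate(invalid="ignore"):
            return np.nansum(x, axis=0) / (2.0 * np.sum(~np.isnan(x), axis=0))

    def call_rate(self) -> np.ndarray:
        return np.mean(self.dosage != MISSING, axis=0)

    def subset_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.individuals), self.markers.subset(idx),
                              self.dosage[:, idx])

    def subset_individuals(self, rows: Sequence[int]) -> "GenotypeMatrix":
        rows = list(rows)
        return GenotypeMatrix([self.individuals[i] for i in rows], self.markers,
                              self.dosage[rows, :])


@dataclass
class HaplotypeMatrix:
    """Phased alleles, two ordered rows per individual, values in {0, 1}."""

    individuals: list[str]
    markers: MarkerMap
    allele: np.ndarray  # uint8, shape (2N, M)

    def __post_init__(self) -> None:
        self.allele = np.asarray(self.allele, dtype=np.uint8)
        if self.allele.shape[0] != 2 * len(self.individuals):
            raise ValueError("HaplotypeMatrix needs exactly two rows per individual")
        if self.allele.shape[1] != len(self.markers):
            raise ValueError("allele columns inconsistent with markers")
        if not np.isin(self.allele, [0, 1]).all():
            raise ValueError("haplotype alleles must be 0/1")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_haplotypes(self) -> int:
        return self.allele.shape[0]

    def rows_of(self, individual_index: int) -> tuple[int, int]:
        return 2 * individual_index, 2 * individual_index + 1

    def collapse(self) -> GenotypeMatrix:
        """Sum row pairs back into a dosage matrix."""
        dos = (self.allele[0::2, :].astype(np.int8)
               + self.allele[1::2, :].astype(np.int8))
        return GenotypeMatrix(list(self.individuals), self.markers, dos)

    def subset_markers(self, idx: np.ndarray) -> "HaplotypeMatrix":
        return HaplotypeMatrix(list(self.individuals), self.markers.subset(idx),
                               self.allele[:, idx])

    def subset_individuals(self, rows: Sequence[int]) -> "HaplotypeMatrix":
        rows = list(rows)
        hap_rows = np.ravel([[2 * i, 2 * i + 1] for i in rows])
        return HaplotypeMatrix([self.individuals[i] for i in rows], self.markers,
                               self.allele[hap_rows, :])


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path) -> tuple[MarkerMap, GenotypeMatrix, Optional[HaplotypeMatrix]]:
    """Read a VCF, keeping biallelic SNVs only.

    Returns the marker map, the dosage matrix, and — when every retained call
    is phased and non-missing — a :class:`HaplotypeMatrix`.  Skipped
    (multi-allelic / indel) record counts are logged.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, a1, a2 = [], [], [], [], []
    dosage_rows, hap_rows = [], []
    skipped = 0
    all_phased = True
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            skipped += 1
            continue
        gts = v.genotypes  # [a0, a1, phased] per sample
        if any(len(g) != 3 for g in gts):
            raise ValueError(f"mixed or non-diploid ploidy at {v.CHROM}:{v.POS}")
        dos = np.empty(len(samples), dtype=np.int8)
        hap = np.zeros((len(samples), 2), dtype=np.int8)
        for i, g in enumerate(gts):
            if g[0] < 0 or g[1] < 0:
                dos[i] = MISSING
                hap[i] = 0
                all_phased = False
            else:
                dos[i] = g[0] + g[1]
                hap[i, 0], hap[i, 1] = g[0], g[1]
                if not g[2]:
                    all_phased = False
        ids.append(v.ID if v.ID and v.ID != "." else f"{v.CHROM}_{v.POS}")
        chroms.append(v.CHROM)
        poss.append(v.POS)
        a1.append(v.REF)
        a2.append(v.ALT[0])
        dosage_rows.append(dos)
        hap_rows.append(hap)
    if skipped:
        log.info("read_vcf: skipped %d non-biallelic-SNV records", skipped)
    if not ids:
        raise ValueError(f"no biallelic SNV records in {path}")
    markers = MarkerMap(np.array(ids, dtype=object), np.array(chroms, dtype=object),
                        np.array(poss), allele1=np.array(a1, dtype=object),
                        allele2=np.array(a2, dtype=object))
    g = GenotypeMatrix(samples, markers, np.array(dosage_rows).T)
    h = None
    if all_phased:
        # hap_rows: list over markers of (N, 2); rearrange to (2N, M)
        arr = np.array(hap_rows)  # (M, N, 2)
        allele = np.transpose(arr, (1, 2, 0)).reshape(2 * len(samples), len(ids))
        h = HaplotypeMatrix(samples, markers, allele.astype(np.uint8))
    g.skipped_records = skipped  # type: ignore[attr-defined]
    return markers, g, h


def write_vcf(path, g: GenotypeMatrix, h: Optional[HaplotypeMatrix] = None) -> None:
    """Write a minimal VCF 4.2; phased GT when a haplotype matrix is given."""
    m = g.markers
    ref = m.allele1 if m.allele1 is not None else np.full(len(m), "A", dtype=object)
    alt = m.allele2 if m.allele2 is not None else np.full(len(m), "C", dtype=object)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in pd.unique(m.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.individuals) + "\n")
        for k in range(len(m)):
            if h is not None:
                gts = [f"{h.allele[2*i, k]}|{h.allele[2*i+1, k]}"
                       for i in range(g.n_individuals)]
            else:
                enc = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
                gts = [enc[int(d)] for d in g.dosage[:, k]]
            fh.write(f"{m.chrom[k]}\t{m.pos_bp[k]}\t{m.marker_id[k]}\t"
                     f"{ref[k]}\t{alt[k]}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# PLINK text
# ---------------------------------------------------------------------------

def read_plink_text(ped_path, map_path) -> tuple[MarkerMap, GenotypeMatrix]:
    """Read PLINK .ped/.map text files.

    Dosage counts the lexicographically larger of the two observed alleles at
    each marker ("0 0" → missing).
    """
    mp = pd.read_csv(map_path, sep=r"\s+", header=None,
                     names=["chrom", "marker_id", "pos_cm", "pos_bp"],
                     dtype={"chrom": str, "marker_id": str})
    n_markers = len(mp)
    ids, rows = [], []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_markers:
                raise ValueError(
                    f"ped line for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts)} columns, expected {6 + 2 * n_markers}")
            ids.append(parts[1])
            rows.append(parts[6:])
    alleles = np.array(rows, dtype=object).reshape(len(ids), n_markers, 2)
    dosage = np.full((len(ids), n_markers), MISSING, dtype=np.int8)
    a1s = np.empty(n_markers, dtype=object)
    a2s = np.empty(n_markers, dtype=object)
    for k in range(n_markers):
        col = alleles[:, k, :]
        present = col[col != "0"]
        uniq = sorted(set(present.tolist()))
        if len(uniq) > 2:
            raise ValueError(f"marker {mp.marker_id[k]} has >2 alleles")
        a1 = uniq[0] if uniq else "0"
        # monomorphic marker: the sole observed allele is allele1, dosage 0
        a2 = uniq[1] if len(uniq) > 1 else "."
        a1s[k], a2s[k] = a1, a2
        missing = (col[:, 0] == "0") | (col[:, 1] == "0")
        dosage[:, k] = (col[:, 0] == a2).astype(np.int8) + (col[:, 1] == a2)
        dosage[missing, k] = MISSING
    markers = MarkerMap(mp.marker_id.to_numpy(dtype=object),
                        mp.chrom.to_numpy(dtype=object),
                        mp.pos_bp.to_numpy(), mp.pos_cm.to_numpy(dtype=float),
                        a1s, a2s)
    return markers, GenotypeMatrix(ids, markers, dosage)


def write_plink_text(ped_path, map_path, g: GenotypeMatrix) -> None:
    m = g.markers
    cm = m.pos_cm if m.pos_cm is not None else np.zeros(len(m))
    with open(map_path, "w") as fh:
        for k in range(len(m)):
            fh.write(f"{m.chrom[k]}\t{m.marker_id[k]}\t{cm[k]}\t{m.pos_bp[k]}\n")
    a1 = m.allele1 if m.allele1 is not None else np.full(len(m), "A", dtype=object)
    a2 = m.allele2 if m.allele2 is not None else np.full(len(m), "C", dtype=object)
    enc = {0: lambda k: (a1[k], a1[k]), 1: lambda k: (a1[k], a2[k]),
           2: lambda k: (a2[k], a2[k]), MISSING: lambda k: ("0", "0")}
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(g.individuals):
            fields = [ind, ind, "0", "0", "0", "-9"]
            for k in range(len(m)):
                fields.extend(enc[int(g.dosage[i, k])](k))
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Marker filtering
# ---------------------------------------------------------------------------

def filter_markers(g: GenotypeMatrix, maf_min: float = 0.01,
                   call_rate_min: float = 0.0) -> GenotypeMatrix:
    """Retain markers with MAF >= maf_min and call rate >= call_rate_min.

    MAF is computed on non-missing calls; marker order is preserved.
    Idempotent by construction.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    af = g.allele_frequency()
    with np.errstate(invalid="ignore"):
        maf = np.fmin(af, 1.0 - af)
    keep = (np.nan_to_num(maf, nan=-1.0) >= maf_min) & (g.call_rate() >= call_rate_min)
    if maf_min == 0.0:
        keep |= np.isnan(maf) & (g.call_rate() >= call_rate_min)
    if not keep.any():
        log.warning("filter_markers: no markers retained")
    return g.subset_markers(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

_SCHEMAS = {
    "phenotype": ["id", "roan", "tick", "breed", "panel"],
    "lrr": ["id"],  # remaining columns are marker ids
    "depth": ["id", "chrom", "pos", "dp"],
    "readpairs": ["chrom", "pos1", "strand1", "pos2", "strand2"],
}

_ROAN_VALUES = {"case", "control"}
_TICK_VALUES = {0, 1, 2}


def read_table(path, schema: str) -> pd.DataFrame:
    """Read a schematized TSV; validates required columns and enum values.

    Unknown columns are preserved.
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    df = pd.read_csv(path, sep="\t", dtype={"id": str} if schema != "readpairs" else None)
    for col in _SCHEMAS[schema]:
        if col not in df.columns:
            raise ValueError(f"{schema} table missing required column {col!r}")
    if schema == "phenotype":
        bad = set(df["roan"].dropna()) - _ROAN_VALUES
        if bad:
            raise ValueError(f"invalid roan values: {sorted(bad)}")
        tick = df["tick"].dropna()
        if len(tick) and set(tick.astype(int)) - _TICK_VALUES:
            raise ValueError("tick scores must be in {0,1,2}")
    elif schema == "depth":
        df["pos"] = df["pos"].astype(np.int64)
        df["dp"] = df["dp"].astype(float)
    elif schema == "readpairs":
        for c in ("pos1", "pos2"):
            df[c] = df[c].astype(np.int64)
        bad = set(df["strand1"]) | set(df["strand2"]) - {"+", "-"}
        if bad - {"+", "-"}:
            raise ValueError(f"invalid strand values: {sorted(bad - {'+', '-'})}")
    return df


def write_bed(path, intervals: Sequence[Interval], names: Optional[Sequence[str]] = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            chrom, start, end = iv.to_bed_fields()
            name = names[i] if names is not None else f"iv{i}"
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
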
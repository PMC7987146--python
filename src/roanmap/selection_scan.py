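"""Windowed selection signatures: nucleotide diversity, Weir-Cockerham
F_ST, PLINK-parameterized runs of homozygosity, and XP-EHH.

All windowed statistics use sliding windows anchored at position 1 and
emitted at every step, reported by window start/end.  F_ST follows the
Weir & Cockerham (1984) variance-component estimator with r = 2 samples,
windowed as sum(a) / sum(a + b + c).  The ROH scan reproduces the sliding
homozygous-window hit-rate algorithm of PLINK --homozyg with density and
gap checks disabled.  XP-EHH integrates unnormalized site-EHH (identity
classes of haplotypes over the span from the core marker) over genetic
distance and standardizes the log-ratio of integrals genome-wide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix, HaplotypeMatrix, Interval

__all__ = ["windowed_pi", "windowed_fst", "ROHParams", "roh_scan",
           "roh_frequency", "xpehh_scan", "ROHSegment"]


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------

def _site_pi(g_or_h, max_missing_rate: float = 0.5):
    """Per-site pi, allele counts and positions; high-missingness sites excluded."""
    if isinstance(g_or_h, HaplotypeMatrix):
        alt = g_or_h.allele.sum(axis=0).astype(float)
        n = np.full(alt.shape, float(g_or_h.n_haplotypes))
        miss_rate = np.zeros(alt.shape)
        markers = g_or_h.markers
    else:
        g: GenotypeMatrix = g_or_h
        x = g.dosage_float()
        nonmiss = np.sum(~np.isnan(x), axis=0)
        miss_rate = 1.0 - nonmiss / g.n_individuals
        alt = np.nansum(x, axis=0)
        n = 2.0 * nonmiss
        markers = g.markers
    keep = (miss_rate <= max_missing_rate) & (n >= 2)
    c1 = alt
    c0 = n - alt
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * c0 * c1 / (n * (n - 1.0))
    pi[~keep] = np.nan
    return pi, markers


def _sliding_windows(chrom_end: int, window_bp: int, step_bp: int):
    starts = np.arange(1, max(2, chrom_end - window_bp + 2), step_bp, dtype=np.int64)
    return starts, starts + window_bp - 1


def windowed_pi(g_or_h, window_bp: int = 500_000, step_bp: int = 10_000,
                chrom_length_bp: Optional[int] = None) -> pd.DataFrame:
    """Sliding-window nucleotide diversity per bp of window length.

    pi_s = 2 c0 c1 / (n (n-1)) per variant site over non-missing allele
    counts; a window's value is the sum over its sites divided by the
    window length.  Sites with missing rate > 50% are excluded; windows
    without callable sites are missing.  Invariant under allele relabeling.
    """
    pi, markers = _site_pi(g_or_h)
    chroms = pd.unique(markers.chrom)
    if len(chroms) != 1:
        raise ValueError("windowed_pi expects a single chromosome")
    pos = markers.pos_bp
    end = int(chrom_length_bp or pos.max())
    starts, ends = _sliding_windows(end, window_bp, step_bp)
    callable_site = ~np.isnan(pi)
    vals = np.full(len(starts), np.nan)
    csum = np.concatenate(([0.0], np.cumsum(np.nan_to_num(pi))))
    ccnt = np.concatenate(([0], np.cumsum(callable_site.astype(int))))
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, ends, side="right")
    nsites = ccnt[hi] - ccnt[lo]
    with np.errstate(invalid="ignore"):
        vals = np.where(nsites > 0, (csum[hi] - csum[lo]) / window_bp, np.nan)
    return pd.DataFrame({"chrom": chroms[0], "start": starts, "end": ends,
                         "pi": vals, "n_sites": nsites})


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def _wc_components(g1: GenotypeMatrix, g2: GenotypeMatrix):
    """Per-site Weir-Cockerham (1984) a, b, c for two samples."""
    out_a = np.full(len(g1.markers), np.nan)
    out_b = np.full(len(g1.markers), np.nan)
    out_c = np.full(len(g1.markers), np.nan)
    r = 2.0
    x1, x2 = g1.dosage_float(), g2.dosage_float()
    n1 = np.sum(~np.isnan(x1), axis=0).astype(float)
    n2 = np.sum(~np.isnan(x2), axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.nansum(x1, axis=0) / (2 * n1)
        p2 = np.nansum(x2, axis=0) / (2 * n2)
        h1 = np.sum(x1 == 1, axis=0) / n1  # observed het frequency
        h2 = np.sum(x2 == 1, axis=0) / n2
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
                           / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                     - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2.0
    ok = (n1 >= 1) & (n2 >= 1) & (nbar > 1)
    out_a[ok], out_b[ok], out_c[ok] = a[ok], b[ok], c[ok]
    return out_a, out_b, out_c


def windowed_fst(g1: GenotypeMatrix, g2: GenotypeMatrix,
                 window_bp: int = 500_000, step_bp: int = 10_000,
                 chrom_length_bp: Optional[int] = None) -> pd.DataFrame:
    """Sliding-window Weir-Cockerham F_ST = sum(a) / sum(a+b+c).

    Windows where the denominator is <= 0 are missing; small negative
    estimates are legitimate for undifferentiated populations.
    """
    if list(g1.markers.marker_id) != list(g2.markers.marker_id):
        raise ValueError("the two cohorts must share one marker map")
    a, b, c = _wc_components(g1, g2)
    pos = g1.markers.pos_bp
    chroms = pd.unique(g1.markers.chrom)
    if len(chroms) != 1:
        raise ValueError("windowed_fst expects a single chromosome")
    end = int(chrom_length_bp or pos.max())
    starts, ends = _sliding_windows(end, window_bp, step_bp)
    asum = np.concatenate(([0.0], np.cumsum(np.nan_to_num(a))))
    tsum = np.concatenate(([0.0], np.cumsum(np.nan_to_num(a + b + c))))
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, ends, side="right")
    num = asum[hi] - asum[lo]
    den = tsum[hi] - tsum[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(den > 0, num / den, np.nan)
    return pd.DataFrame({"chrom": chroms[0], "start": starts, "end": ends,
                         "fst": fst, "sum_a": num, "sum_abc": den})


def site_fst(g1: GenotypeMatrix, g2: GenotypeMatrix) -> np.ndarray:
    """Per-site a / (a+b+c) (NaN where undefined)."""
    a, b, c = _wc_components(g1, g2)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where((a + b + c) != 0, a / (a + b + c), np.nan)


# ---------------------------------------------------------------------------
# Runs of homozygosity (PLINK --homozyg algorithm)
# ---------------------------------------------------------------------------

@dataclass
class ROHParams:
    window_snp: int = 41
    window_het: int = 0
    window_missing: int = 0
    window_threshold: float = 0.05
    min_snp: int = 41
    min_kb: float = 500.0


@dataclass
class ROHSegment:
    individual: str
    interval: Interval
    n_snp: int


def roh_scan(g: GenotypeMatrix, params: Optional[ROHParams] = None
             ) -> list[ROHSegment]:
    """Sliding-window ROH detection.

    A window of ``window_snp`` consecutive markers is homozygous iff it has
    at most ``window_het`` heterozygous and ``window_missing`` missing
    calls.  A SNP qualifies iff the fraction of homozygous windows spanning
    it reaches ``window_threshold`` and its own call is homozygous; maximal
    runs of qualifying SNPs with >= min_snp markers and >= min_kb kb become
    segments.  Density and gap checks are intentionally not applied.
    """
    params = params or ROHParams()
    W = params.window_snp
    segments: list[ROHSegment] = []
    markers = g.markers
    for chrom in pd.unique(markers.chrom):
        cols = np.flatnonzero(markers.chrom == chrom)
        if len(cols) < W:
            continue
        pos = markers.pos_bp[cols]
        dos = g.dosage[:, cols]
        m = len(cols)
        n_windows = m - W + 1
        for i, ind in enumerate(g.individuals):
            row = dos[i]
            het = (row == 1).astype(np.int32)
            mis = (row == MISSING).astype(np.int32)
            het_in_win = np.convolve(het, np.ones(W, dtype=np.int32), "valid")
            mis_in_win = np.convolve(mis, np.ones(W, dtype=np.int32), "valid")
            win_ok = ((het_in_win <= params.window_het)
                      & (mis_in_win <= params.window_missing)).astype(np.int32)
            # windows spanning SNP j are those with start in [j-W+1, j]
            ok_csum = np.concatenate(([0], np.cumsum(win_ok)))
            j = np.arange(m)
            w_lo = np.clip(j - W + 1, 0, n_windows - 1)
            w_hi = np.minimum(j, n_windows - 1)
            spanning = (w_hi - w_lo + 1).astype(float)
            hits = ok_csum[w_hi + 1] - ok_csum[w_lo]
            qualifies = (hits / spanning >= params.window_threshold) \
                & ((row == 0) | (row == 2))
            # maximal runs of qualifying SNPs
            padded = np.concatenate(([False], qualifies, [False]))
            d = np.diff(padded.astype(np.int8))
            run_starts = np.flatnonzero(d == 1)
            run_ends = np.flatnonzero(d == -1) - 1
            for lo, hi in zip(run_starts, run_ends):
                n_snp = hi - lo + 1
                length_kb = (pos[hi] - pos[lo] + 1) / 1000.0
                if n_snp >= params.min_snp and length_kb >= params.min_kb:
                    segments.append(ROHSegment(
                        ind, Interval(str(chrom), int(pos[lo]), int(pos[hi])),
                        int(n_snp)))
    return segments


def roh_frequency(segments: list[ROHSegment], markers, individuals
                  ) -> pd.DataFrame:
    """Per-marker fraction of individuals with >= 1 overlapping segment."""
    n = len(individuals)
    covered = {ind: [] for ind in individuals}
    for seg in segments:
        covered[seg.individual].append(seg.interval)
    freq = np.zeros(len(markers))
    for ind in individuals:
        hit = np.zeros(len(markers), dtype=bool)
        for iv in covered[ind]:
            hit |= ((markers.chrom == iv.chrom) & (markers.pos_bp >= iv.start_bp)
                    & (markers.pos_bp <= iv.end_bp))
        freq += hit
    return pd.DataFrame({"chrom": markers.chrom, "pos": markers.pos_bp,
                         "roh_freq": freq / max(1, n)})


# ---------------------------------------------------------------------------
# EHH / iES / XP-EHH
# ---------------------------------------------------------------------------

def _ehhs_side(allele: np.ndarray, core: int, direction: int,
               cutoff: float) -> tuple[list[int], list[float]]:
    """Unnormalized site-EHH from the core outward in one direction.

    EHHS(core) = 1; extending to marker x, haplotypes are partitioned by
    identity over the inclusive span [core..x] and EHHS = sum C(k_g, 2) /
    C(n, 2).  Extension stops when EHHS drops below ``cutoff``.
    """
    n, m = allele.shape
    denom = n * (n - 1) / 2.0
    # identity classes span [core..x] inclusive: seed with the core allele
    ids = allele[:, core].astype(np.int64)
    idxs = [core]
    vals = [1.0]
    x = core
    while True:
        x += direction
        if x < 0 or x >= m:
            break
        key = ids * 2 + allele[:, x]
        _, ids = np.unique(key, return_inverse=True)
        counts = np.bincount(ids)
        ehhs = float(np.sum(counts * (counts - 1) / 2.0) / denom)
        if ehhs < cutoff:
            break
        idxs.append(x)
        vals.append(ehhs)
    return idxs, vals


def _ies(allele: np.ndarray, core: int, gpos: np.ndarray,
         cutoff: float) -> float:
    """Trapezoidal integral of site-EHH over genetic distance, both sides."""
    total = 0.0
    for direction in (-1, +1):
        idxs, vals = _ehhs_side(allele, core, direction, cutoff)
        if len(idxs) > 1:
            x = gpos[idxs]
            total += abs(np.trapezoid(vals, x))
    return total


def xpehh_scan(h_obj: HaplotypeMatrix, h_ref: HaplotypeMatrix,
               cutoff: float = 0.05, cm_per_mb: float = 1.0) -> pd.DataFrame:
    """Cross-population extended haplotype homozygosity.

    Per marker: iES (integrated site-EHH, truncated at ``cutoff``) in the
    object and reference panels, raw = ln(iES_obj / iES_ref), and the raw
    value standardized by the genome-wide mean and sd (no frequency
    binning).  Markers with iES_ref = 0 are missing.
    """
    if list(h_obj.markers.marker_id) != list(h_ref.markers.marker_id):
        raise ValueError("object and reference panels must share the marker map")
    markers = h_obj.markers
    gpos = (markers.pos_cm if markers.pos_cm is not None
            else markers.pos_bp * cm_per_mb / 1e6)
    m = len(markers)
    raw = np.full(m, np.nan)
    for k in range(m):
        ies_o = _ies(h_obj.allele, k, gpos, cutoff)
        ies_r = _ies(h_ref.allele, k, gpos, cutoff)
        if ies_r > 0 and ies_o > 0:
            raw[k] = np.log(ies_o / ies_r)
    ok = ~np.isnan(raw)
    std = np.full(m, np.nan)
    if ok.sum() > 1:
        sd = raw[ok].std()
        if sd > 0:
            std[ok] = (raw[ok] - raw[ok].mean()) / sd
        else:
            std[ok] = 0.0
    elif ok.sum() == 1:
        std[ok] = 0.0
    return pd.DataFrame({"chrom": markers.chrom, "pos": markers.pos_bp,
                         "marker_id": markers.marker_id,
                         "xpehh_raw": raw, "xpehh": std})
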
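import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from roanmap.io_formats import GenotypeMatrix, HaplotypeMatrix, Interval, MarkerMap
from roanmap.selection_scan import (ROHParams, ROHSegment, roh_frequency,
                                    roh_scan, site_fst, windowed_fst,
                                    windowed_pi, xpehh_scan, _ehhs_side)


def markers_for(positions, chrom="chr1", cm=None):
    positions = np.asarray(positions)
    return MarkerMap(np.array([f"m{i}" for i in range(len(positions))], dtype=object),
                     np.full(len(positions), chrom, dtype=object), positions,
                     pos_cm=cm)


def geno(dosage, positions=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    pos = positions if positions is not None else (np.arange(m) + 1) * 100
    return GenotypeMatrix([f"i{i}" for i in range(n)], markers_for(pos), dosage)


def haps(rows, positions=None, cm=None):
    rows = np.asarray(rows, dtype=np.uint8)
    n2, m = rows.shape
    pos = positions if positions is not None else (np.arange(m) + 1) * 100
    mk = markers_for(pos, cm=cm)
    return HaplotypeMatrix([f"i{i}" for i in range(n2 // 2)], mk, rows)


class TestWindowedPi:
    def test_monomorphic_window_zero(self):
        g = geno(np.zeros((5, 10)))
        out = windowed_pi(g, window_bp=1000, step_bp=1000, chrom_length_bp=1000)
        assert out["pi"].iloc[0] == 0.0

    def test_single_site_worked_example(self):
        # one site, allele counts 2/2 among n=4: 4 of 6 pairs differ -> 2/3
        h = haps([[0], [0], [1], [1]], positions=[500])
        out = windowed_pi(h, window_bp=1000, step_bp=1000, chrom_length_bp=1000)
        assert out["pi"].iloc[0] == pytest.approx((2 / 3) / 1000)

    def test_matches_naive_pairwise_oracle(self, rng):
        n_hap, m = 20, 60
        rows = rng.integers(0, 2, size=(n_hap, m)).astype(np.uint8)
        pos = np.sort(rng.choice(np.arange(1, 5001), size=m, replace=False))
        h = haps(rows, positions=pos)
        out = windowed_pi(h, window_bp=1000, step_bp=500, chrom_length_bp=5000)
        for _, row in out.iterrows():
            sel = (pos >= row["start"]) & (pos <= row["end"])
            diffs = sum(np.sum(rows[a, sel] != rows[b, sel])
                        for a, b in itertools.combinations(range(n_hap), 2))
            expect = diffs / (n_hap * (n_hap - 1) / 2) / 1000
            if np.isnan(row["pi"]):
                assert not sel.any()
            else:
                assert row["pi"] == pytest.approx(expect, rel=1e-9)

    def test_invariant_under_allele_relabeling(self, rng):
        rows = rng.integers(0, 2, size=(12, 40)).astype(np.uint8)
        h1 = haps(rows)
        h2 = haps(1 - rows)
        a = windowed_pi(h1, window_bp=2000, step_bp=500, chrom_length_bp=4000)
        b = windowed_pi(h2, window_bp=2000, step_bp=500, chrom_length_bp=4000)
        assert np.allclose(a["pi"], b["pi"], equal_nan=True)

    def test_high_missingness_site_excluded(self):
        d = np.array([[1, 1], [1, -1], [0, -1], [1, -1]], dtype=np.int8)
        g = geno(d)
        out = windowed_pi(g, window_bp=1000, step_bp=1000, chrom_length_bp=1000)
        # site 2 has 75% missing -> only site 1 contributes
        c0, c1 = 1, 7
        expect = 0  # site 1: dosages 1,1,0,1 -> alt=3 of 8 -> 2*5*3/(8*7)
        expect = 2 * 5 * 3 / (8 * 7) / 1000
        assert out["pi"].iloc[0] == pytest.approx(expect)


def wc_oracle(d1, d2):
    """Independent loop-based Weir & Cockerham (1984) implementation."""
    out = []
    for k in range(d1.shape[1]):
        x1 = d1[:, k][d1[:, k] >= 0]
        x2 = d2[:, k][d2[:, k] >= 0]
        n1, n2 = len(x1), len(x2)
        p1 = x1.sum() / (2 * n1)
        p2 = x2.sum() / (2 * n2)
        h1 = np.mean(x1 == 1)
        h2 = np.mean(x2 == 1)
        r = 2
        nbar = (n1 + n2) / 2
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                           / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        out.append((a, b, c))
    return out


class TestWindowedFst:
    def test_fixed_difference_site_is_one(self):
        g1 = geno(np.zeros((6, 1)))
        g2 = geno(np.full((6, 1), 2))
        assert site_fst(g1, g2)[0] == pytest.approx(1.0)

    def test_identical_populations_near_zero(self, rng):
        d = rng.integers(0, 3, size=(20, 50)).astype(np.int8)
        g = geno(d)
        out = windowed_fst(g, geno(d), window_bp=5000, step_bp=5000,
                           chrom_length_bp=5000)
        assert out["fst"].iloc[0] < 0.01  # small negative allowed

    def test_matches_independent_wc_oracle(self, rng):
        d1 = rng.integers(0, 3, size=(15, 10)).astype(np.int8)
        d2 = rng.integers(0, 3, size=(25, 10)).astype(np.int8)
        d1[rng.random(d1.shape) < 0.05] = -1
        oracle = wc_oracle(d1, d2)
        sum_a = sum(t[0] for t in oracle)
        sum_abc = sum(sum(t) for t in oracle)
        out = windowed_fst(geno(d1), geno(d2), window_bp=2000, step_bp=2000,
                           chrom_length_bp=1100)
        assert out["fst"].iloc[0] == pytest.approx(sum_a / sum_abc, abs=1e-12)


def roh_reference(dosage_row, pos, params: ROHParams):
    """Exhaustive re-implementation of the sliding-window ROH algorithm."""
    m = len(dosage_row)
    W = params.window_snp
    if m < W:
        return []
    hom = [(d == 0 or d == 2) for d in dosage_row]
    win_ok = []
    for s in range(m - W + 1):
        window = dosage_row[s:s + W]
        het = sum(1 for d in window if d == 1)
        mis = sum(1 for d in window if d == -1)
        win_ok.append(het <= params.window_het and mis <= params.window_missing)
    qualifies = []
    for j in range(m):
        spans = [s for s in range(len(win_ok)) if s <= j <= s + W - 1]
        rate = sum(win_ok[s] for s in spans) / len(spans)
        qualifies.append(rate >= params.window_threshold and hom[j])
    segs = []
    j = 0
    while j < m:
        if qualifies[j]:
            k = j
            while k + 1 < m and qualifies[k + 1]:
                k += 1
            n_snp = k - j + 1
            if n_snp >= params.min_snp and (pos[k] - pos[j] + 1) / 1000 >= params.min_kb:
                segs.append((int(pos[j]), int(pos[k]), n_snp))
            j = k + 1
        else:
            j += 1
    return segs


class TestRohScan:
    def test_fully_heterozygous_no_segments(self):
        g = geno(np.ones((2, 100)), positions=(np.arange(100) + 1) * 10_000)
        assert roh_scan(g) == []

    def test_long_homozygous_run_single_segment(self):
        m = 1200
        pos = (np.arange(m) + 1) * 2000  # 2.4 Mb total
        d = np.ones((1, m), dtype=np.int8)
        d[0, 100:1100] = 2  # 1000 consecutive homozygous SNPs spanning 2 Mb
        g = geno(d, positions=pos)
        segs = roh_scan(g)
        expect = roh_reference(d[0], pos, ROHParams())
        got = [(s.interval.start_bp, s.interval.end_bp, s.n_snp) for s in segs]
        assert got == expect
        assert len(got) == 1
        assert got[0][2] >= 41

    def test_single_het_split_matches_reference(self):
        m = 1200
        pos = (np.arange(m) + 1) * 2000
        d = np.full((1, m), 2, dtype=np.int8)
        d[0, 600] = 1
        g = geno(d, positions=pos)
        got = [(s.interval.start_bp, s.interval.end_bp, s.n_snp)
               for s in roh_scan(g)]
        assert got == roh_reference(d[0], pos, ROHParams())

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_matches_exhaustive_reference_on_random_instances(self, seed):
        r = np.random.default_rng(seed)
        m = int(r.integers(45, 200))
        pos = np.sort(r.choice(np.arange(1, 4_000_000, 997), m, replace=False))
        d = r.choice([0, 1, 2, 2, 2, 0, -1], size=(1, m)).astype(np.int8)
        params = ROHParams(window_snp=11, min_snp=11, min_kb=50.0)
        got = [(s.interval.start_bp, s.interval.end_bp, s.n_snp)
               for s in roh_scan(geno(d, positions=pos), params)]
        assert got == roh_reference(d[0], pos, params)


class TestRohFrequency:
    def test_no_segments_all_zero(self):
        mk = markers_for([100, 200, 300])
        out = roh_frequency([], mk, ["a", "b"])
        assert (out["roh_freq"] == 0).all()

    def test_shared_segment_gives_one(self):
        mk = markers_for([100, 200, 300])
        segs = [ROHSegment(ind, Interval("chr1", 150, 250), 5)
                for ind in ["a", "b"]]
        out = roh_frequency(segs, mk, ["a", "b"])
        assert out["roh_freq"].tolist() == [0.0, 1.0, 0.0]

    def test_matches_interval_overlap_oracle(self, rng):
        mk = markers_for(np.sort(rng.choice(10_000, 50, replace=False) + 1))
        inds = [f"i{k}" for k in range(8)]
        segs = []
        for ind in inds:
            for _ in range(rng.integers(0, 4)):
                a = int(rng.integers(1, 9000))
                segs.append(ROHSegment(ind, Interval("chr1", a,
                                                     a + int(rng.integers(100, 2000))), 1))
        out = roh_frequency(segs, mk, inds)
        for j, p in enumerate(mk.pos_bp):
            covered = {s.individual for s in segs
                       if s.interval.start_bp <= p <= s.interval.end_bp}
            assert out["roh_freq"].iloc[j] == pytest.approx(len(covered) / 8)


class TestXpehh:
    def test_ehhs_at_core_is_one(self, rng):
        rows = rng.integers(0, 2, size=(10, 20)).astype(np.uint8)
        idxs, vals = _ehhs_side(rows, 10, +1, 0.05)
        assert idxs[0] == 10 and vals[0] == 1.0

    def test_ehhs_matches_combinatorial_counting(self):
        rows = np.array([[0, 0, 1, 0, 1],
                         [0, 0, 1, 0, 0],
                         [1, 0, 1, 1, 0],
                         [1, 0, 1, 1, 0],
                         [0, 1, 0, 0, 1],
                         [0, 1, 0, 0, 1]], dtype=np.uint8)
        core = 2
        idxs, vals = _ehhs_side(rows, core, +1, cutoff=0.0)
        n = 6
        denom = n * (n - 1) / 2
        for step, x in enumerate(idxs):
            if x == core:
                expect = 1.0  # convention: the degenerate span groups everyone
            else:
                classes = {}
                for r in range(n):
                    key = tuple(rows[r, core:x + 1])
                    classes[key] = classes.get(key, 0) + 1
                expect = sum(k * (k - 1) / 2 for k in classes.values()) / denom
            assert vals[step] == pytest.approx(expect)

    def test_identical_populations_raw_zero(self, rng):
        rows = rng.integers(0, 2, size=(12, 30)).astype(np.uint8)
        h = haps(rows)
        out = xpehh_scan(h, haps(rows.copy()))
        finite = out["xpehh_raw"].dropna()
        assert len(finite) > 0
        assert np.allclose(finite, 0.0)
        assert np.allclose(out["xpehh"].dropna(), 0.0)

    def test_standardized_mean_zero_sd_one(self, rng):
        rows_o = rng.integers(0, 2, size=(16, 60)).astype(np.uint8)
        rows_r = rng.integers(0, 2, size=(16, 60)).astype(np.uint8)
        out = xpehh_scan(haps(rows_o), haps(rows_r))
        vals = out["xpehh"].dropna()
        assert vals.mean() == pytest.approx(0.0, abs=1e-9)
        assert vals.std() == pytest.approx(1.0, abs=0.05)
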
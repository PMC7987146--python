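import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from roanmap.haplotype_mapping import (build_catalog, carrier_calls_frame,
                                       classify_carrier, genotype_individuals,
                                       make_fine_mapping_example, narrow_region)
from roanmap.io_formats import HaplotypeMatrix, Interval, MarkerMap


def hap_matrix(rows, positions=None, chrom="chr1"):
    rows = np.asarray(rows, dtype=np.uint8)
    n2, m = rows.shape
    pos = positions if positions is not None else (np.arange(m) + 1) * 100
    markers = MarkerMap(np.array([f"m{i}" for i in range(m)], dtype=object),
                        np.full(m, chrom, dtype=object), np.asarray(pos))
    ids = [f"i{i}" for i in range(n2 // 2)]
    return HaplotypeMatrix(ids, markers, rows)


def full_window(h):
    return Interval(str(h.markers.chrom[0]), int(h.markers.pos_bp[0]),
                    int(h.markers.pos_bp[-1]))


class TestBuildCatalog:
    def test_all_identical_single_entry(self):
        h = hap_matrix(np.ones((8, 5)))
        cat = build_catalog(h, full_window(h))
        assert cat.n_entries == 1
        assert cat.counts.tolist() == [8]

    def test_two_patterns_counted(self):
        h = hap_matrix([[0, 0, 0], [1, 1, 1], [1, 1, 1], [0, 0, 0]])
        cat = build_catalog(h, full_window(h))
        assert sorted(cat.counts.tolist()) == [2, 2]

    def test_labels_ordered_by_count_then_first_seen(self):
        h = hap_matrix([[0, 1], [1, 0], [1, 0], [0, 1], [1, 0], [1, 1]])
        cat = build_catalog(h, full_window(h))
        assert cat.counts.tolist() == [3, 2, 1]
        assert cat.haplotypes[0].tolist() == [1, 0]

    def test_empty_window_raises(self):
        h = hap_matrix(np.zeros((4, 3)))
        with pytest.raises(ValueError):
            build_catalog(h, Interval("chr1", 10_000, 20_000))

    def test_against_string_dedup_oracle(self, rng):
        rows = rng.integers(0, 2, size=(500, 12)).astype(np.uint8)
        h = hap_matrix(rows)
        cat = build_catalog(h, full_window(h))
        from collections import Counter
        oracle = Counter("".join(map(str, r)) for r in rows)
        got = {("".join(map(str, cat.haplotypes[e]))): cat.counts[e]
               for e in range(cat.n_entries)}
        assert got == dict(oracle)
        assert cat.counts.sum() == 500
        for row in range(500):
            e = cat.row_to_entry[row]
            assert np.array_equal(rows[row], cat.haplotypes[e])


def narrow_oracle(catalog, carrier_labels, control_ids, rare_count_max):
    """Independent exhaustive re-derivation of the narrowing procedure."""
    entries = [catalog.entry(l) for l in carrier_labels]
    common = [e for e in entries if catalog.counts[e] > rare_count_max]
    if not common:  # vacuous constraint: the full window stands
        return (int(catalog.markers.pos_bp[0]), int(catalog.markers.pos_bp[-1]))
    rows = catalog.haplotypes[common]
    m = rows.shape[1]
    best = None
    for lo in range(m):
        for hi in range(lo, m):
            if all(np.array_equal(rows[0, lo:hi + 1], r[lo:hi + 1]) for r in rows):
                if best is None or (hi - lo) > (best[1] - best[0]):
                    best = (lo, hi)
    if best is None:
        return None
    lo, hi = best
    consensus = catalog.haplotypes[common[int(np.argmax(catalog.counts[common]))]]
    idx = {ind: i for i, ind in enumerate(catalog.individuals)}
    best_pref = best_suff = 0
    for ind in control_ids:
        i = idx[ind]
        h1 = catalog.haplotypes[catalog.row_to_entry[2 * i]]
        h2 = catalog.haplotypes[catalog.row_to_entry[2 * i + 1]]
        match = (h1 == h2) & (h1 == consensus)
        k = 0
        while lo + k <= hi and match[lo + k]:
            k += 1
        best_pref = max(best_pref, k)
        k = 0
        while hi - k >= lo and match[hi - k]:
            k += 1
        best_suff = max(best_suff, k)
    nlo = lo + best_pref - 1 if best_pref > 1 else lo
    nhi = hi - best_suff + 1 if best_suff > 1 else hi
    if nlo > nhi:
        return None
    return int(catalog.markers.pos_bp[nlo]), int(catalog.markers.pos_bp[nhi])


class TestNarrowRegion:
    def test_full_window_when_no_control_matches(self):
        rows = np.vstack([np.tile([1, 0, 1, 1, 0], (6, 1)),
                          np.tile([0, 1, 0, 0, 1], (4, 1))])
        h = hap_matrix(rows)
        cat = build_catalog(h, full_window(h))
        carrier = cat.labels[0]
        res = narrow_region(cat, [carrier], [])
        assert res.interval.start_bp == h.markers.pos_bp[0]
        assert res.interval.end_bp == h.markers.pos_bp[-1]

    def test_canonical_sharing_pattern_gives_119kb(self):
        h, labels, controls, window = make_fine_mapping_example()
        cat = build_catalog(h, window)
        res = narrow_region(cat, labels, controls, rare_count_max=2)
        assert res.interval.start_bp == 11_072_648
        assert res.interval.end_bp == 11_191_833
        assert round(res.interval.length_bp / 1000) == 119

    def test_disagreeing_carriers_yield_diagnostic(self):
        rows = np.vstack([np.tile([1, 0, 1], (4, 1)), np.tile([0, 1, 0], (4, 1))])
        h = hap_matrix(rows)
        cat = build_catalog(h, full_window(h))
        res = narrow_region(cat, cat.labels[:2], [], rare_count_max=0)
        assert res.interval is None
        assert "disagreement" in res.diagnostic

    def test_randomized_instances_match_exhaustive_oracle(self, rng):
        for trial in range(30):
            n_ind, m = 8, rng.integers(4, 10)
            rows = rng.integers(0, 2, size=(2 * n_ind, m)).astype(np.uint8)
            # plant partial sharing among the first six rows
            lo, hi = sorted(rng.integers(0, m, 2).tolist())
            rows[:6, lo:hi + 1] = rows[0, lo:hi + 1]
            h = hap_matrix(rows)
            cat = build_catalog(h, full_window(h))
            carrier_labels = sorted({cat.labels[cat.row_to_entry[r]]
                                     for r in range(6)})
            controls = [f"i{i}" for i in range(4, 8)]
            rcm = int(rng.integers(0, 3))
            res = narrow_region(cat, carrier_labels, controls, rare_count_max=rcm)
            expect = narrow_oracle(cat, carrier_labels, controls, rcm)
            got = None if res.interval is None else \
                (res.interval.start_bp, res.interval.end_bp)
            assert got == expect, f"trial {trial}"

    def test_monotone_in_rare_count_tolerance(self, rng):
        for _ in range(10):
            rows = rng.integers(0, 2, size=(20, 8)).astype(np.uint8)
            rows[:8, 2:6] = rows[0, 2:6]
            h = hap_matrix(rows)
            cat = build_catalog(h, full_window(h))
            labels = sorted({cat.labels[cat.row_to_entry[r]] for r in range(8)})
            prev_len = None
            for rcm in (3, 2, 1, 0):
                res = narrow_region(cat, labels, [], rare_count_max=rcm)
                length = 0 if res.interval is None else res.interval.length_bp
                if prev_len is not None:
                    assert length <= prev_len
                prev_len = length


class TestClassifyCarrier:
    def setup_method(self):
        rows = np.vstack([np.tile([1, 1, 0, 1, 0, 1], (4, 1)),
                          np.tile([0, 0, 1, 0, 1, 0], (4, 1))])
        self.h = hap_matrix(rows)
        self.cat = build_catalog(self.h, full_window(self.h))
        self.carrier_label = self.cat.labels[
            self.cat.row_to_entry[0]]
        self.core = Interval("chr1", 300, 500)  # markers m2..m4

    def test_full_identity_is_core_match(self):
        ok, tag = classify_carrier(np.array([1, 1, 0, 1, 0, 1]), self.cat,
                                   [self.carrier_label], self.core)
        assert ok and tag == "core-match"

    def test_one_core_mismatch_rejects(self):
        ok, _ = classify_carrier(np.array([1, 1, 1, 1, 0, 1]), self.cat,
                                 [self.carrier_label], self.core)
        assert not ok

    def test_core_only_identity_is_recombinant(self):
        ok, tag = classify_carrier(np.array([0, 0, 0, 1, 0, 0]), self.cat,
                                   [self.carrier_label], self.core)
        assert ok and tag == "recombinant-match"

    def test_pure_function_of_core_substring(self, rng):
        core_idx = [2, 3, 4]
        base = np.array([1, 1, 0, 1, 0, 1], dtype=np.uint8)
        ref_call = classify_carrier(base, self.cat, [self.carrier_label],
                                    self.core)[0]
        for _ in range(20):
            variant = base.copy()
            for j in range(6):
                if j not in core_idx and rng.random() < 0.5:
                    variant[j] ^= 1
            assert classify_carrier(variant, self.cat, [self.carrier_label],
                                    self.core)[0] == ref_call


class TestGenotypeIndividuals:
    def test_counts_against_simulator_truth(self, perfect_cohort):
        c = perfect_cohort
        cfg = c.cfg
        dup = cfg.dup_interval
        window = Interval(dup.chrom, dup.start_bp - 100_000, dup.end_bp + 100_000)
        cat = build_catalog(c.haplotypes, window)
        # confirmed carriers: catalog entries of truth-carrier rows
        carrier_labels = sorted({cat.labels[cat.row_to_entry[r]]
                                 for r in np.flatnonzero(c.truth.hap_carrier)})
        calls = genotype_individuals(c.haplotypes, cat, carrier_labels,
                                     cfg.core_interval)
        got = np.array([call.carrier_haps for call in calls])
        assert np.array_equal(got, c.truth.cn - 2)

    def test_no_carriers_all_zero(self):
        rows = np.zeros((6, 4), dtype=np.uint8)
        h = hap_matrix(rows)
        cat = build_catalog(h, full_window(h))
        calls = genotype_individuals(h, cat, [], Interval("chr1", 100, 400))
        assert all(c.carrier_haps == 0 for c in calls)
        frame = carrier_calls_frame(calls)
        assert (frame["cn"] == 2).all()

    def test_double_carrier_is_cn4(self):
        rows = np.vstack([np.tile([1, 0, 1], (2, 1)), np.tile([0, 1, 0], (2, 1))])
        h = hap_matrix(rows)
        cat = build_catalog(h, full_window(h))
        label = cat.labels[cat.row_to_entry[0]]
        calls = genotype_individuals(h, cat, [label], full_window(h))
        assert calls[0].cn == 4
        assert calls[1].cn == 2
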
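import numpy as np
import pytest

from pionuc.intervals import CoverageTrack, GenomicInterval, Peak
from pionuc.peaks import (PeakSet, call_peaks_simple, combine_replicate_peaks,
                          filter_enriched_peaks, union_regions,
                          zscore_filter_peaks)
from pionuc.signal import NormalizedTrack, normalize_chip


def _peak(start, end, summit=None, score=0.0, name="p", chrom="chr1"):
    return Peak(GenomicInterval(chrom, start, end),
                (start + end) // 2 if summit is None else summit, name, score)


def random_peakset(rng, n, span=10_000):
    peaks = []
    for i in range(n):
        s = int(rng.integers(0, span))
        w = int(rng.integers(30, 400))
        peaks.append(_peak(s, s + w, score=float(rng.random()), name=f"p{i}"))
    return PeakSet(peaks)


class TestCaller:
    def test_chip_equal_to_input_yields_no_peaks(self, rng):
        arr = rng.poisson(5, 5000).astype(float)
        track = CoverageTrack({"chr1": arr})
        assert len(call_peaks_simple(track, track, 1e-5)) == 0

    def test_single_block_one_peak_with_summit_at_maximum(self):
        chip = np.ones(5000)
        chip[2000:2300] = 20.0
        chip[2100] = 35.0
        peaks = call_peaks_simple(CoverageTrack({"chr1": chip}),
                                  CoverageTrack({"chr1": np.ones(5000)}), 1e-5)
        assert len(peaks) == 1
        (p,) = peaks
        assert p.summit == 2100
        assert p.start <= 2000 and p.end >= 2300

    def test_nearby_runs_are_merged(self):
        chip = np.ones(5000)
        chip[1000:1100] = 30.0
        chip[1150:1250] = 30.0  # 50 bp gap < 100
        peaks = call_peaks_simple(CoverageTrack({"chr1": chip}),
                                  CoverageTrack({"chr1": np.ones(5000)}), 1e-5)
        assert len(peaks) == 1

    def test_recovers_planted_enhancer_summits(self, small_dataset, small_result):
        arm = small_result.differential["arms"]["wt"]
        summits = {}
        for p in arm.combined_peaks:
            summits.setdefault(p.chrom, []).append(p.summit)
        enh = small_dataset.truth.regions[
            small_dataset.truth.regions.kind == "enhancer"]
        hit = 0
        for r in enh.itertuples():
            cand = np.array(summits.get(r.chrom, [np.inf]))
            if np.abs(cand - r.summit).min() <= 100:
                hit += 1
        assert hit / len(enh) >= 0.9


class TestReplicateCombining:
    def test_brute_force_double_filter(self, rng):
        combined = random_peakset(rng, 60)
        rep1 = random_peakset(rng, 40)
        rep2 = random_peakset(rng, 40)
        got = combine_replicate_peaks(combined, rep1, rep2)

        def overlaps(p, ps):
            return any(p.chrom == q.chrom and max(p.start, q.start) < min(p.end, q.end)
                       for q in ps)

        expected = [p for p in combined if overlaps(p, rep1) and overlaps(p, rep2)]
        assert [(p.chrom, p.start, p.end) for p in got] == \
               [(p.chrom, p.start, p.end) for p in expected]

    def test_output_is_subset_of_combined(self, rng):
        combined = random_peakset(rng, 30)
        got = combine_replicate_peaks(combined, random_peakset(rng, 20),
                                      random_peakset(rng, 20))
        keys = {(p.chrom, p.start, p.end) for p in combined}
        assert all((p.chrom, p.start, p.end) in keys for p in got)


def _norm(data):
    return NormalizedTrack(data, raw=None, scheme="test",
                           background_mean=0.0, background_sd=1.0)


class TestEnrichedFilter:
    def test_enriched_kept_depleted_dropped(self):
        n = 2000
        chip = np.zeros(n); chip[900:1100] = 2.0
        inp = np.full(n, 0.1)
        peaks = PeakSet([_peak(900, 1300, summit=1000)])
        kept = filter_enriched_peaks(peaks, _norm({"chr1": chip}), _norm({"chr1": inp}))
        assert len(kept) == 1
        kept2 = filter_enriched_peaks(peaks, _norm({"chr1": inp}), _norm({"chr1": chip}))
        assert len(kept2) == 0

    def test_excluded_chromosome_dropped_regardless_of_signal(self):
        chip = np.full(2000, 5.0)
        peaks = PeakSet([_peak(900, 1300, summit=1000, chrom="chrU")])
        kept = filter_enriched_peaks(
            peaks, _norm({"chrU": chip}), _norm({"chrU": np.zeros(2000)}),
            excluded_chroms=["chrU"])
        assert len(kept) == 0

    def test_short_peak_uses_whole_region_window(self):
        # chip > input near the summit but < input over the whole 150 bp
        # peak: the whole-region rule must drop it
        n = 1000
        chip = np.zeros(n); inp = np.zeros(n)
        chip[500:520] = 3.0           # strong right at the summit
        inp[400:550] = 1.0            # broad input over the whole peak
        peaks = PeakSet([_peak(400, 550, summit=510)])
        kept = filter_enriched_peaks(peaks, _norm({"chr1": chip}), _norm({"chr1": inp}))
        # whole-region mean chip = 60/150 < input 150/150
        assert len(kept) == 0
        # a 400 bp peak with the same local profile is judged on summit +/-100
        wide = PeakSet([_peak(300, 700, summit=510)])
        kept_wide = filter_enriched_peaks(wide, _norm({"chr1": chip}), _norm({"chr1": inp}))
        # summit window mean chip = 60/201 vs input = 140/201 -> still dropped
        assert len(kept_wide) == 0

    def test_idempotent(self, rng):
        chip = rng.normal(1, 0.1, 5000)
        inp = rng.normal(0, 0.1, 5000)
        peaks = random_peakset(rng, 25, span=4000)
        once = filter_enriched_peaks(peaks, _norm({"chr1": chip}), _norm({"chr1": inp}))
        twice = filter_enriched_peaks(once, _norm({"chr1": chip}), _norm({"chr1": inp}))
        assert [(p.start, p.end) for p in once] == [(p.start, p.end) for p in twice]


class TestZScoreFilter:
    def test_all_below_cutoff_empty(self, rng):
        z = _norm({"chr1": np.zeros(5000)})
        peaks = random_peakset(rng, 10, span=4000)
        assert len(zscore_filter_peaks(peaks, z, 1.6445)) == 0

    def test_minus_infinity_cutoff_is_identity(self, rng):
        z = _norm({"chr1": rng.normal(0, 1, 5000)})
        peaks = random_peakset(rng, 10, span=4000)
        got = zscore_filter_peaks(peaks, z, -np.inf)
        assert len(got) == len(peaks)

    def test_matches_threshold_oracle(self, rng):
        z = _norm({"chr1": rng.normal(0, 2, 10_000)})
        peaks = random_peakset(rng, 50, span=9000)
        got = {(p.start, p.end) for p in zscore_filter_peaks(peaks, z, 1.6445)}
        expected = set()
        for p in peaks:
            if len(p.interval) < 200:
                lo, hi = p.start, p.end
            else:
                lo, hi = p.summit - 100, p.summit + 101
            if z.data["chr1"][lo:hi].mean() >= 1.6445:
                expected.add((p.start, p.end))
        assert got == expected


class TestUnion:
    def test_disjoint_sets_concatenate(self):
        a = PeakSet([_peak(0, 100), _peak(300, 400)])
        b = PeakSet([_peak(150, 250)])
        u = union_regions(a, b)
        assert [(p.start, p.end) for p in u] == [(0, 100), (150, 250), (300, 400)]

    def test_identical_sets_are_idempotent(self, rng):
        a = random_peakset(rng, 30)
        u = union_regions(a, a)
        assert [(p.start, p.end) for p in u] == \
               [(p.start, p.end) for p in union_regions(a, PeakSet([]))]

    def test_commutative(self, rng):
        a = random_peakset(rng, 30)
        b = random_peakset(rng, 30)
        ab = union_regions(a, b)
        ba = union_regions(b, a)
        assert [(p.start, p.end) for p in ab] == [(p.start, p.end) for p in ba]

    def test_per_bp_membership_matches_set_oracle(self, rng):
        a = random_peakset(rng, 40, span=3000)
        b = random_peakset(rng, 40, span=3000)
        u = union_regions(a, b)
        covered = np.zeros(5000, dtype=bool)
        for p in list(a) + list(b):
            covered[p.start:p.end] = True
        got = np.zeros(5000, dtype=bool)
        for p in u:
            got[p.start:p.end] = True
        np.testing.assert_array_equal(got, covered)

    def test_merged_region_keeps_strongest_summit(self):
        a = PeakSet([_peak(0, 100, summit=50, score=1.0, name="weak")])
        b = PeakSet([_peak(50, 200, summit=150, score=9.0, name="strong")])
        (p,) = union_regions(a, b)
        assert (p.start, p.end, p.summit, p.name) == (0, 200, 150, "strong")

    def test_abutting_half_open_intervals_stay_separate(self):
        a = PeakSet([_peak(0, 100)])
        b = PeakSet([_peak(100, 200)])
        assert len(union_regions(a, b)) == 2
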
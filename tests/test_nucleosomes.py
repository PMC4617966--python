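import dataclasses

import numpy as np
import pytest

from pionuc import nucleosomes as N
from pionuc.analysis import delta_profile_halfwidth, mnase_arc
from pionuc.intervals import CoverageTrack, GenomicInterval, Peak
from pionuc.signal import NormalizedTrack, normalize_mnase, pileup
from pionuc.simulate import generate_genome, simulate_mnase, simulate_positioned_mnase

from conftest import small_config


def _norm(data, raw=None):
    return NormalizedTrack(data, raw=raw, scheme="t",
                           background_mean=0, background_sd=1)


class TestCaller:
    def test_flat_zero_coverage_no_calls(self):
        track = CoverageTrack({"chr1": np.zeros(20_000)})
        assert N.call_nucleosomes(track) == []

    def test_triangular_bump_dyad_at_apex(self):
        arr = np.zeros(20_000)
        x = np.arange(20_000)
        arr += np.maximum(0, 73 - np.abs(x - 5000)) / 73
        (call,) = N.call_nucleosomes(CoverageTrack({"chr1": arr}), min_score=0.5)
        assert abs(call.dyad - 5000) <= 5

    def test_planted_array_recovered(self):
        L = 60_000
        dyads = np.arange(300, L - 300, 200)
        frags = simulate_positioned_mnase(dyads, L, coverage=30, seed=5)
        norm = normalize_mnase(pileup(frags, {"chr1": L}))
        calls = np.array([c.dyad for c in N.call_nucleosomes(norm)])
        dist = np.abs(dyads[:, None] - calls[None, :]).min(axis=1)
        assert (dist <= 20).mean() >= 0.9
        false = np.abs(calls[:, None] - dyads[None, :]).min(axis=1) > 20
        assert false.mean() < 0.1

    def test_call_count_invariant_under_uniform_scaling(self, rng):
        arr = rng.poisson(10, 40_000).astype(float)
        a = N.call_nucleosomes(CoverageTrack({"chr1": arr}))
        b = N.call_nucleosomes(CoverageTrack({"chr1": 7.0 * arr}))
        assert [(c.dyad) for c in a] == [(c.dyad) for c in b]

    def test_short_chromosome_skipped_with_warning(self):
        track = CoverageTrack({"tiny": np.ones(50)})
        assert N.call_nucleosomes(track) == []


class TestAnchoring:
    def _peak(self, summit):
        return Peak(GenomicInterval("chr1", summit - 200, summit + 200), summit)

    def _call(self, dyad, chrom="chr1"):
        return N.NucleosomeCall(chrom, dyad, 1.0, 147.0)

    def test_summit_exactly_at_dyad(self):
        ((_, anchor, label),) = N.align_to_nearest_nucleosome(
            [self._peak(1000)], [self._call(1000)])
        assert anchor == 1000 and label == "nucleosomal"

    def test_dyad_beyond_threshold_falls_back_to_summit(self):
        ((_, anchor, label),) = N.align_to_nearest_nucleosome(
            [self._peak(1000)], [self._call(1080)])
        assert anchor == 1000 and label == "non-nucleosomal"

    def test_boundary_distance_is_inclusive(self):
        ((_, anchor, label),) = N.align_to_nearest_nucleosome(
            [self._peak(1000)], [self._call(1075)])
        assert anchor == 1075 and label == "nucleosomal"

    def test_matches_nearest_neighbor_oracle(self, rng):
        dyads = np.sort(rng.integers(0, 100_000, 300))
        calls = [self._call(int(d)) for d in dyads]
        for _ in range(200):
            s = int(rng.integers(500, 99_500))
            ((_, anchor, label),) = N.align_to_nearest_nucleosome(
                [self._peak(s)], calls)
            nearest = int(dyads[np.abs(dyads - s).argmin()])
            if abs(nearest - s) <= 75:
                assert (anchor, label) == (nearest, "nucleosomal")
            else:
                assert (anchor, label) == (s, "non-nucleosomal")


class TestDeltaMNase:
    def _region(self, summit, name="r0"):
        return Peak(GenomicInterval("chr1", summit - 400, summit + 400), summit, name)

    def test_identical_tracks_give_zero(self, rng):
        raw = CoverageTrack({"chr1": rng.poisson(5, 3000).astype(float) + 1})
        t = _norm({"chr1": rng.normal(0, 1, 3000)}, raw=raw)
        (d,) = N.delta_mnase([self._region(1500)], t, t)
        assert d.delta == 0.0 and not d.excluded

    def test_constant_shift_recovered(self, rng):
        raw = CoverageTrack({"chr1": np.ones(3000)})
        base = rng.normal(0, 1, 3000)
        wt = _norm({"chr1": base}, raw=raw)
        mut = _norm({"chr1": base + 0.7}, raw=raw)
        (d,) = N.delta_mnase([self._region(1500)], wt, mut)
        assert d.delta == pytest.approx(0.7)

    def test_antisymmetric_under_genotype_swap(self, rng):
        raw = CoverageTrack({"chr1": rng.poisson(4, 3000).astype(float)})
        wt = _norm({"chr1": rng.normal(0, 1, 3000)}, raw=raw)
        mut = _norm({"chr1": rng.normal(0, 1, 3000)}, raw=raw)
        r = [self._region(1500)]
        (fwd,) = N.delta_mnase(r, wt, mut)
        (rev,) = N.delta_mnase(r, mut, wt)
        assert fwd.delta == -rev.delta

    def test_zero_read_positions_excluded_per_track(self):
        raw_wt = np.ones(3000); raw_wt[1400:1600] = 0
        wt = _norm({"chr1": np.full(3000, -5.0)}, raw=CoverageTrack({"chr1": raw_wt}))
        mut = _norm({"chr1": np.ones(3000)}, raw=CoverageTrack({"chr1": np.ones(3000)}))
        # wt values at zero-read positions must not drag the wt mean down
        (d,) = N.delta_mnase([self._region(1500)], wt, mut)
        assert d.delta == pytest.approx(1.0 - (-5.0))

    def test_region_with_no_reads_flagged_excluded(self):
        zeros = CoverageTrack({"chr1": np.zeros(3000)})
        wt = _norm({"chr1": np.zeros(3000)}, raw=zeros)
        mut = _norm({"chr1": np.zeros(3000)}, raw=zeros)
        (d,) = N.delta_mnase([self._region(1500)], wt, mut)
        assert d.excluded and np.isnan(d.delta)

    def test_per_region_mode(self):
        zeros = CoverageTrack({"chr1": np.zeros(3000)})
        ones = CoverageTrack({"chr1": np.ones(3000)})
        wt = _norm({"chr1": np.zeros(3000)}, raw=zeros)
        mut = _norm({"chr1": np.ones(3000)}, raw=ones)
        (d,) = N.delta_mnase([self._region(1500)], wt, mut, zero_mode="per-region")
        assert d.excluded


class TestMetaprofile:
    def test_single_region_profile_equals_its_window(self, rng):
        arr = rng.normal(0, 1, 5000)
        track = CoverageTrack({"chr1": arr}, normalized=True)
        mp = N.metaprofile([("chr1", 2500)], track, flank=100)
        np.testing.assert_array_equal(mp.profile, arr[2400:2601])
        assert mp.n_regions == 1

    def test_identical_signal_across_regions(self):
        arr = np.tile(np.sin(np.arange(500) / 20.0), 10)
        track = CoverageTrack({"chr1": arr}, normalized=True)
        anchors = [("chr1", 1000 + 500 * i) for i in range(4)]
        mp = N.metaprofile(anchors, track, flank=100)
        np.testing.assert_allclose(mp.profile, arr[900:1101])
        assert np.var(mp.matrix, axis=0).max() == pytest.approx(0.0)

    def test_matches_matrix_mean_oracle(self, rng):
        arr = rng.normal(0, 1, 20_000)
        track = CoverageTrack({"chr1": arr}, normalized=True)
        anchors = [("chr1", int(a)) for a in rng.integers(1000, 19_000, 50)]
        mp = N.metaprofile(anchors, track, flank=500)
        oracle = np.mean([arr[a - 500:a + 501] for _, a in anchors], axis=0)
        np.testing.assert_allclose(mp.profile, oracle)

    def test_out_of_bounds_rows_dropped(self, rng):
        track = CoverageTrack({"chr1": rng.normal(0, 1, 2000)}, normalized=True)
        mp = N.metaprofile([("chr1", 100), ("chr1", 1000)], track, flank=500)
        assert mp.n_regions == 1

    def test_empty_anchor_list_is_an_error(self):
        track = CoverageTrack({"chr1": np.zeros(100)})
        with pytest.raises(ValueError):
            N.metaprofile([], track, flank=10)


class TestIntrinsicModel:
    def test_gc_rich_scores_above_at_rich(self):
        occ = N.predict_intrinsic_occupancy({
            "gc": "GC" * 500, "at": "AT" * 500,
        })
        assert (occ.data["gc"] > occ.data["at"]).all()

    def test_at_runs_penalized(self):
        plain = "ACGT" * 250
        runs = ("ACGTAAAAAAAA" + "ACGT" * 22) * 10
        occ = N.predict_intrinsic_occupancy({"a": plain, "b": runs[:1000]})
        assert occ.data["b"].mean() < occ.data["a"].mean()

    def test_enhancers_score_above_genome_median(self, small_dataset):
        occ = small_dataset.intrinsic
        med = np.median(np.concatenate(list(occ.data.values())))
        enh = small_dataset.truth.regions[
            small_dataset.truth.regions.kind == "enhancer"]
        above = [
            occ.data[r.chrom][r.start:r.end].mean() > med for r in enh.itertuples()
        ]
        assert np.mean(above) >= 0.9


class TestMotifConfigurationFootprint:
    def test_central_motifs_give_narrower_delta_footprint(self):
        """Tightly clustered motifs deplete locally; spread-out motifs
        produce a wider accessibility footprint."""
        widths = {}
        for label, halfwin in (("central", 60), ("flanking", 350)):
            cfg = dataclasses.replace(small_config(), motif_halfwindow=halfwin,
                                      seed=11)
            ds = generate_genome(cfg)
            frags = {
                f"mnase_{g}_rep{r}": simulate_mnase(ds, g, r)
                for g in ("wt", "mutant") for r in (1, 2)
            }
            tracks = mnase_arc(frags, cfg.chrom_lengths)
            enh = ds.truth.regions[ds.truth.regions.kind == "enhancer"]
            anchors = [(r.chrom, int(r.summit)) for r in enh.itertuples()]
            widths[label] = delta_profile_halfwidth(
                anchors, tracks["wt"], tracks["mutant"], flank=800)
        assert widths["flanking"] > widths["central"]
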
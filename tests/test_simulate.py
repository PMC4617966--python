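import numpy as np
import pytest
from scipy import stats

from pionuc.motifs import scan_genome
from pionuc.signal import pileup
from pionuc.simulate import (SyntheticConfig, generate_genome,
                             occupancy_landscape, simulate_chip,
                             simulate_mnase, rng_for)

from conftest import small_config


class TestGenomeGeneration:
    def test_same_seed_reproduces_identical_genome_and_fragments(self):
        a = generate_genome(small_config())
        b = generate_genome(small_config())
        assert a.genome == b.genome
        fa = simulate_mnase(a, "wt", 1)
        fb = simulate_mnase(b, "wt", 1)
        for chrom in fa:
            np.testing.assert_array_equal(fa[chrom], fb[chrom])
        ca = simulate_chip(a, "patterning", "mutant", 2)
        cb = simulate_chip(b, "patterning", "mutant", 2)
        for chrom in ca:
            np.testing.assert_array_equal(ca[chrom], cb[chrom])

    def test_zero_enhancers_yields_only_other_annotations(self):
        cfg = small_config(n_enhancers=0, n_hot_regions=0)
        ds = generate_genome(cfg)
        kinds = set(ds.truth.regions.kind)
        assert "enhancer" not in kinds
        assert kinds <= {"open", "open_distal", "control"}
        assert ds.enhancers == []
        assert ds.hot_regions == []

    def test_planted_motifs_recovered_exactly_by_scanner(self, small_dataset):
        hits = scan_genome(small_dataset.genome, small_dataset.config.scan_motifs)
        assert set(hits) == set(small_dataset.truth.motif_hits)

    def test_every_enhancer_has_at_least_one_motif(self, small_dataset):
        df = small_dataset.truth.regions
        assert (df.loc[df.kind == "enhancer", "n_motifs"] >= 1).all()

    def test_too_many_regions_is_an_error(self):
        cfg = small_config(n_enhancers=5000)
        with pytest.raises(ValueError, match="without overlap"):
            generate_genome(cfg)

    def test_ground_truth_json_roundtrip(self, small_dataset, tmp_path):
        path = tmp_path / "gt.json"
        small_dataset.truth.to_json(path)
        back = type(small_dataset.truth).from_json(path)
        assert back.regions.equals(small_dataset.truth.regions.reset_index(drop=True))
        assert back.motif_hits == small_dataset.truth.motif_hits


class TestMNaseSimulation:
    def test_fragment_count_equals_jittered_depth_exactly(self, small_dataset):
        frags = simulate_mnase(small_dataset, "wt", 1)
        total = sum(len(v) for v in frags.values())
        cfg = small_dataset.config
        jitter = rng_for(cfg.seed, "jitter:mnase:rep1").uniform(
            -cfg.depth_jitter, cfg.depth_jitter)
        assert total == int(round(cfg.mnase_depth * (1 + jitter)))

    def test_fragment_length_mean_near_147(self, small_dataset):
        frags = simulate_mnase(small_dataset, "mutant", 1)
        lengths = np.concatenate([v[:, 1] - v[:, 0] for v in frags.values()])
        assert abs(lengths.mean() - 147) < 1.0

    def test_zero_depletion_makes_genotypes_indistinguishable(self):
        """With no pioneer-driven depletion, the positions of wt and mutant
        MNase fragments around enhancers follow the same distribution."""
        cfg = small_config(depletion_per_motif=0.0, mnase_depth=100_000)
        ds = generate_genome(cfg)
        frags = {g: simulate_mnase(ds, g, 1) for g in ("wt", "mutant")}
        offsets = {g: [] for g in frags}
        enh = ds.truth.regions[ds.truth.regions.kind == "enhancer"]
        for g, per_chrom in frags.items():
            for r in enh.itertuples():
                f = per_chrom[r.chrom]
                mid = (f[:, 0] + f[:, 1]) // 2
                sel = (mid >= r.start) & (mid < r.end)
                offsets[g].append(mid[sel] - r.center)
        wt = np.concatenate(offsets["wt"])
        mut = np.concatenate(offsets["mutant"])
        assert stats.ks_2samp(wt, mut).pvalue > 0.01

    def test_depletion_margin_matches_planted_landscape(self, small_dataset):
        """Coverage deficit in wt at enhancer centers tracks the planted
        occupancy ratio, computed by direct averaging of the landscape at
        the candidate dyads."""
        ds = small_dataset
        cfg = ds.config
        wt_cov = pileup(simulate_mnase(ds, "wt", 1), cfg.chrom_lengths)
        mut_cov = pileup(simulate_mnase(ds, "mutant", 1), cfg.chrom_lengths)
        land = {g: occupancy_landscape(ds, g) for g in ("wt", "mutant")}
        dyads = ds.truth.dyads
        totals: dict = {}
        win: dict = {}
        for g in ("wt", "mutant"):
            weights = {
                c: land[g].data[c][dyads[g][c]] + cfg.dyad_weight_floor
                for c in cfg.chrom_lengths
            }
            totals[g] = sum(w.sum() for w in weights.values())
            win[g] = weights
        enh = ds.truth.regions[ds.truth.regions.kind == "enhancer"]
        w_obs = m_obs = w_exp = m_exp = 0.0
        for r in enh.itertuples():
            sel = np.abs(dyads["wt"][r.chrom] - r.summit) <= 250
            w_obs += wt_cov.data[r.chrom][r.summit - 250:r.summit + 250].mean()
            m_obs += mut_cov.data[r.chrom][r.summit - 250:r.summit + 250].mean()
            w_exp += win["wt"][r.chrom][sel].sum() / totals["wt"]
            m_exp += win["mutant"][r.chrom][sel].sum() / totals["mutant"]
        assert w_obs < m_obs  # wt depleted where the pioneer acts
        # depth jitter is shared across genotypes, so coverage ratios and
        # landscape-weight ratios are directly comparable
        assert (w_obs / m_obs) == pytest.approx(w_exp / m_exp, rel=0.10)


class TestChIPSimulation:
    def test_total_patterning_count_identical_across_genotypes(self, small_dataset):
        for rep in (1, 2):
            n_wt = sum(len(v) for v in
                       simulate_chip(small_dataset, "patterning", "wt", rep).values())
            n_mut = sum(len(v) for v in
                        simulate_chip(small_dataset, "patterning", "mutant", rep).values())
            assert n_wt == n_mut

    def test_null_world_has_equal_enrichment_everywhere(self):
        cfg = small_config(depletion_per_motif=0.0, redistribution_fraction=0.0,
                           chip_depth=400_000)
        ds = generate_genome(cfg)
        wt = pileup(simulate_chip(ds, "patterning", "wt", 1), cfg.chrom_lengths)
        mut = pileup(simulate_chip(ds, "patterning", "mutant", 1), cfg.chrom_lengths)
        ratios = []
        for r in ds.truth.regions.itertuples():
            w = wt.data[r.chrom][r.summit - 125:r.summit + 125].sum()
            m = mut.data[r.chrom][r.summit - 125:r.summit + 125].sum()
            if w + m > 500:
                ratios.append(m / w)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)

    def test_pioneer_enrichment_independent_of_genotype(self, small_dataset):
        cfg = small_dataset.config
        wt = pileup(simulate_chip(small_dataset, "pioneer", "wt", 1), cfg.chrom_lengths)
        mut = pileup(simulate_chip(small_dataset, "pioneer", "mutant", 1), cfg.chrom_lengths)
        enh = small_dataset.truth.regions[small_dataset.truth.regions.kind == "enhancer"]
        ratios = []
        for r in enh.itertuples():
            w = wt.data[r.chrom][r.summit - 125:r.summit + 125].sum()
            m = mut.data[r.chrom][r.summit - 125:r.summit + 125].sum()
            if w + m > 500:
                ratios.append(m / w)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)

    def test_input_is_unenriched_at_regions(self, small_dataset):
        cfg = small_dataset.config
        inp = pileup(simulate_chip(small_dataset, "patterning", "wt", 1, is_input=True),
                     cfg.chrom_lengths)
        genome_mean = inp.total() / sum(cfg.chrom_lengths.values())
        enh = small_dataset.truth.regions[small_dataset.truth.regions.kind == "enhancer"]
        means = [inp.data[r.chrom][r.summit - 125:r.summit + 125].mean()
                 for r in enh.itertuples()]
        assert np.mean(means) < 2 * genome_mean
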
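"""End-to-end orchestration of the three analysis arcs.

Arc 1 (differential binding): call patterning-factor peaks per genotype
with replicate consistency and input-enrichment filtering, take the union
of enriched peak sets as the tested regions, count fragments in summit
windows, run the NB test, and assign Groups I/II/III.

Arc 2 (accessibility): normalize MNase per genotype and compute delta-MNase
(mutant minus wild type) over the tested regions, cross-checked against the
differential direction.

Arc 3 (rank-and-bin): define pioneer-bound non-TSS regions, rank them by
pioneer summit reads / wild-type MNase / delta-MNase, bin, and compute
annotation and motif enrichments, hotness correlations, and the
nucleosome-anchoring partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pionuc import diffbind, motifs as motifs_mod, nucleosomes as nuc
from pionuc.config import RunConfig
from pionuc.enrichment import hotness_per_peak, overlap_enrichment, rank_and_bin
from pionuc.intervals import (CoverageTrack, GenomicInterval, Peak, TSSSet,
                              classify_tss_proximity)
from pionuc.peaks import (PeakSet, call_peaks_simple, combine_replicate_peaks,
                          filter_enriched_peaks, union_regions,
                          zscore_filter_peaks)
from pionuc.signal import (NormalizedTrack, log2_ratio_track, normalize_chip,
                           normalize_mnase, pileup, zscore_outside_peaks)
from pionuc.simulate import SyntheticDataset, simulate_chip, simulate_mnase


def pool_fragments(parts: list[dict[str, np.ndarray]]) -> dict[str, np.ndarray]:
    chroms = {c for p in parts for c in p}
    out = {}
    for c in chroms:
        arrs = [p[c] for p in parts if c in p]
        merged = np.vstack(arrs)
        out[c] = merged[np.lexsort((merged[:, 1], merged[:, 0]))]
    return out


def simulate_all_fragments(dataset: SyntheticDataset) -> dict[str, dict[str, np.ndarray]]:
    """Every sample of the study design, keyed by a descriptive name."""
    frags = {}
    for genotype in ("wt", "mutant"):
        for rep in (1, 2):
            frags[f"mnase_{genotype}_rep{rep}"] = simulate_mnase(dataset, genotype, rep)
            for factor in ("patterning", "pioneer"):
                frags[f"chip_{factor}_{genotype}_rep{rep}"] = simulate_chip(
                    dataset, factor, genotype, rep
                )
                frags[f"input_{factor}_{genotype}_rep{rep}"] = simulate_chip(
                    dataset, factor, genotype, rep, is_input=True
                )
    return frags


@dataclass
class ChIPArm:
    genotype: str
    combined_peaks: PeakSet
    enriched_peaks: PeakSet
    chip_norm: NormalizedTrack
    input_norm: NormalizedTrack


def build_chip_arm(
    fragments: dict[str, dict[str, np.ndarray]],
    factor: str,
    genotype: str,
    chrom_lengths: dict[str, int],
    cfg: RunConfig,
) -> ChIPArm:
    ip = [fragments[f"chip_{factor}_{genotype}_rep{r}"] for r in (1, 2)]
    ctrl = [fragments[f"input_{factor}_{genotype}_rep{r}"] for r in (1, 2)]
    t_ip = pileup(pool_fragments(ip), chrom_lengths)
    t_in = pileup(pool_fragments(ctrl), chrom_lengths)
    combined_raw = call_peaks_simple(t_ip, t_in, cfg.peak_p_cutoff,
                                     sample=f"{factor}_{genotype}")
    rep_sets = [
        call_peaks_simple(pileup(f, chrom_lengths), t_in, cfg.peak_p_cutoff)
        for f in ip
    ]
    combined = combine_replicate_peaks(combined_raw, rep_sets[0], rep_sets[1])
    chip_norm = normalize_chip(t_ip, combined.intervals())
    input_norm = normalize_chip(t_in, combined.intervals())
    enriched = filter_enriched_peaks(
        combined, chip_norm, input_norm, cfg.excluded_chroms, cfg.enrich_filter_window
    )
    return ChIPArm(genotype, combined, enriched, chip_norm, input_norm)


def differential_arc(
    fragments: dict[str, dict[str, np.ndarray]],
    chrom_lengths: dict[str, int],
    cfg: RunConfig,
    factor: str = "patterning",
) -> dict:
    """Peak calling per genotype, union regions, NB test, group labels, and
    the model-free difference cross-check."""
    arms = {
        g: build_chip_arm(fragments, factor, g, chrom_lengths, cfg)
        for g in ("wt", "mutant")
    }
    union = union_regions(arms["wt"].enriched_peaks, arms["mutant"].enriched_peaks)
    regions = [
        Peak(p.interval, p.summit, f"dr_{i}", p.score)
        for i, p in enumerate(union)
    ]
    samples = {
        f"{g}_rep{r}": fragments[f"chip_{factor}_{g}_rep{r}"]
        for g in ("wt", "mutant") for r in (1, 2)
    }
    counts = diffbind.count_in_regions(regions, samples, cfg.count_window)
    design = {s: ("wt" if s.startswith("wt") else "mutant") for s in counts.columns}
    results = diffbind.nb_test(counts, design, baseline="wt", treatment="mutant")
    results["group"] = diffbind.assign_groups(results, cfg.fdr_cutoff)
    deltas = diffbind.simple_difference_check(
        regions, arms["wt"].chip_norm, arms["mutant"].chip_norm, cfg.count_window
    )
    return {
        "arms": arms,
        "regions": regions,
        "counts": counts,
        "results": results,
        "simple_delta": deltas,
        "sign_agreement": diffbind.sign_agreement(results, deltas, cfg.fdr_cutoff),
    }


def mnase_arc(
    fragments: dict[str, dict[str, np.ndarray]],
    chrom_lengths: dict[str, int],
) -> dict[str, NormalizedTrack]:
    out = {}
    for genotype in ("wt", "mutant"):
        pooled = pool_fragments(
            [fragments[f"mnase_{genotype}_rep{r}"] for r in (1, 2)]
        )
        track = pileup(pooled, chrom_lengths)
        track.genotype = genotype
        track.assay = "mnase"
        out[genotype] = normalize_mnase(track)
    return out


def pioneer_region_arc(
    fragments: dict[str, dict[str, np.ndarray]],
    chrom_lengths: dict[str, int],
    tss: TSSSet,
    cfg: RunConfig,
) -> dict:
    """Pioneer-bound non-TSS regions from wild-type ChIP: replicate-
    consistent peaks passing the background Z cutoff on log2(ChIP/input),
    with boundaries farther than the TSS-distance threshold from any TSS."""
    arm = build_chip_arm(fragments, "pioneer", "wt", chrom_lengths, cfg)
    t_ip = pileup(
        pool_fragments([fragments[f"chip_pioneer_wt_rep{r}"] for r in (1, 2)]),
        chrom_lengths,
    )
    t_in = pileup(
        pool_fragments([fragments[f"input_pioneer_wt_rep{r}"] for r in (1, 2)]),
        chrom_lengths,
    )
    ratio = log2_ratio_track(t_ip, t_in)
    ratio_z = zscore_outside_peaks(ratio, arm.combined_peaks.intervals())
    bound = zscore_filter_peaks(
        arm.enriched_peaks, ratio_z, cfg.z_cutoff, cfg.enrich_filter_window,
        cfg.excluded_chroms,
    )
    non_tss = [
        p for p in bound
        if len(tss) == 0
        or classify_tss_proximity(p, tss, cfg.tss_distance) == "non-TSS"
    ]
    regions = [
        Peak(p.interval, p.summit, f"zr_{i}", p.score)
        for i, p in enumerate(non_tss)
    ]
    return {"arm": arm, "ratio_z": ratio_z, "regions": regions}


def rank_bin_arc(
    regions: list[Peak],
    chip_norm: NormalizedTrack,
    mnase: dict[str, NormalizedTrack],
    annotations: dict[str, list[GenomicInterval]],
    genome_motif_hits: list,
    genome_length: int,
    cfg: RunConfig,
) -> dict:
    """The three rankings, bins, and per-bin enrichments."""
    summit_reads = np.array([
        chip_norm.data[p.chrom][p.summit] for p in regions
    ])
    wt_mnase = np.array([
        mnase["wt"].window_mean(p.chrom, p.summit - cfg.delta_window,
                                p.summit + cfg.delta_window + 1)
        for p in regions
    ])
    deltas = nuc.delta_mnase(regions, mnase["wt"], mnase["mutant"], cfg.delta_window)
    delta_vals = np.array([d.delta for d in deltas])

    rankings = {
        "summit_reads": rank_and_bin(
            [p.name for p in regions], summit_reads, ascending=False,
            bin_size=cfg.bin_size, mode="summit-reads desc"),
        "wt_mnase": rank_and_bin(
            [p.name for p in regions], wt_mnase, ascending=True,
            bin_size=cfg.bin_size, mode="wt-MNase asc"),
        "delta_mnase": rank_and_bin(
            [p.name for p in regions], delta_vals, ascending=False,
            bin_size=cfg.bin_size, mode="delta-MNase desc"),
    }
    by_id = {p.name: p.interval for p in regions}
    peaks_by_id = {p.name: p for p in regions}
    enrich_rows = []
    for mode, bins in rankings.items():
        for name, annot in annotations.items():
            for be in overlap_enrichment(bins, by_id, annot, name):
                enrich_rows.append(dict(
                    ranking=mode, annotation=name, bin=be.bin_index,
                    observed=be.observed, expected=be.expected,
                    enrichment=be.enrichment,
                ))
        # motif density enrichment over genome background, per bin
        for b, members in enumerate(bins.bins):
            dens = motifs_mod.motif_density_enrichment(
                [peaks_by_id[m] for m in members], genome_motif_hits,
                genome_length, cfg.motif_density_window,
            )
            enrich_rows.append(dict(
                ranking=mode, annotation="pioneer_motif", bin=b,
                observed=np.nan, expected=np.nan, enrichment=dens,
            ))
    table = pd.DataFrame(enrich_rows)
    stats_df = pd.DataFrame({
        "region": [p.name for p in regions],
        "summit_reads": summit_reads,
        "wt_mnase": wt_mnase,
        "delta_mnase": delta_vals,
    }).set_index("region")
    return {"rankings": rankings, "enrichment": table, "stats": stats_df,
            "deltas": deltas}


def nucleosome_arc(
    regions: list[Peak],
    mnase: dict[str, NormalizedTrack],
    cfg: RunConfig,
    top_n: int = 1000,
) -> dict:
    """Dyad calling on the mutant (pioneer-absent) MNase and the 75 bp
    nearest-nucleosome anchoring partition of the top pioneer summits."""
    calls = nuc.call_nucleosomes(
        mnase["mutant"], cfg.low_pass_fraction, cfg.nucleosome_min_score
    )
    top = regions[:top_n]
    anchored = nuc.align_to_nearest_nucleosome(top, calls, cfg.nucleosome_max_dist)
    n_nucleosomal = sum(1 for _, _, label in anchored if label == "nucleosomal")
    return {
        "calls": calls,
        "anchored": anchored,
        "fraction_nucleosomal": n_nucleosomal / len(top) if top else float("nan"),
    }


def delta_profile_halfwidth(
    anchors: list[tuple[str, int]],
    wt: NormalizedTrack,
    mut: NormalizedTrack,
    flank: int = 1000,
) -> float:
    """Half-width (bp) at half maximum of the |mutant - wt| metaprofile —
    a footprint-size summary for motif-configuration comparisons."""
    mp_wt = nuc.metaprofile(anchors, wt, flank)
    mp_mut = nuc.metaprofile(anchors, mut, flank)
    diff = np.abs(mp_mut.profile - mp_wt.profile)
    peak = diff.max()
    if peak <= 0:
        return 0.0
    above = np.flatnonzero(diff >= peak / 2)
    return float(above.max() - above.min()) / 2


@dataclass
class PipelineResult:
    differential: dict
    mnase: dict
    pioneer: dict
    rankbin: dict
    nucleosome: dict
    delta_results: list
    truth_match: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    def group_counts(self) -> dict[str, int]:
        vc = self.differential["results"]["group"].value_counts()
        return {g: int(vc.get(g, 0)) for g in ("I", "II", "III")}


def match_regions_to_truth(
    regions: list[Peak], truth_df: pd.DataFrame
) -> pd.DataFrame:
    """For each planted region, the overlapping analysis region (if any).

    When several analysis regions overlap a planted region, the one with
    the largest overlap wins.
    """
    rows = []
    by_chrom: dict[str, list[Peak]] = {}
    for p in regions:
        by_chrom.setdefault(p.chrom, []).append(p)
    for r in truth_df.itertuples():
        best, best_ov = None, 0
        for p in by_chrom.get(r.chrom, ()):
            ov = min(p.end, r.end) - max(p.start, r.start)
            if ov > best_ov:
                best, best_ov = p.name, ov
        rows.append(dict(region_id=r.region_id, kind=r.kind, group=r.group,
                         n_motifs=r.n_motifs, matched=best, overlap=best_ov))
    return pd.DataFrame(rows)


def run_pipeline(dataset: SyntheticDataset, cfg: RunConfig,
                 fragments: dict | None = None) -> PipelineResult:
    chrom_lengths = dataset.config.chrom_lengths
    if fragments is None:
        fragments = simulate_all_fragments(dataset)

    diff = differential_arc(fragments, chrom_lengths, cfg)
    mnase = mnase_arc(fragments, chrom_lengths)
    delta_results = nuc.delta_mnase(
        diff["regions"], mnase["wt"], mnase["mutant"], cfg.delta_window
    )
    pio = pioneer_region_arc(fragments, chrom_lengths, dataset.tss, cfg)

    genome_length = sum(chrom_lengths.values())
    genome_hits = motifs_mod.scan_genome(dataset.genome, dataset.config.scan_motifs)
    annotations = {
        "early_enhancer": dataset.enhancers,
        "hot": [iv for iv, h in dataset.hot_regions if h >= cfg.hotness_cutoff],
        "patterning_peak": [p.interval for p in diff["regions"]],
    }
    # rank regions by strength for the top-N analyses before binning
    pio_regions = sorted(
        pio["regions"],
        key=lambda p: -pio["arm"].chip_norm.data[p.chrom][p.summit],
    )
    pio_regions = [
        Peak(p.interval, p.summit, f"zr_{i}", p.score)
        for i, p in enumerate(pio_regions)
    ]
    rankbin = rank_bin_arc(
        pio_regions, pio["arm"].chip_norm, mnase, annotations, genome_hits,
        genome_length, cfg,
    )
    nucarc = nucleosome_arc(pio_regions, mnase, cfg)
    truth_match = match_regions_to_truth(diff["regions"], dataset.truth.regions)

    return PipelineResult(
        differential=diff, mnase=mnase, pioneer=pio, rankbin=rankbin,
        nucleosome=nucarc, delta_results=delta_results,
        truth_match=truth_match,
        extras={"pioneer_regions": pio_regions},
    )


def group_recovery(result: PipelineResult) -> dict[str, float]:
    """Fraction of planted Group-I / Group-III regions recovered with the
    correct label, and the delta-MNase vs log2FC coupling among planted
    Group-I regions."""
    tm = result.truth_match
    res = result.differential["results"]
    deltas = {d.region: d.delta for d in result.delta_results}
    out: dict[str, float] = {}
    for planted, label in (("I", "group_I_recovery"), ("III", "group_III_recovery")):
        sub = tm[(tm.group == planted) & tm.matched.notna()]
        planted_total = int((tm.group == planted).sum())
        if planted_total == 0:
            out[label] = float("nan")
            continue
        hit = sum(
            1 for m in sub.matched
            if m in res.index and res.loc[m, "group"] == planted
        )
        out[label] = hit / planted_total
    sub = tm[(tm.group == "I") & tm.matched.notna()]
    xs, ys = [], []
    for m in sub.matched:
        if m in res.index and m in deltas and np.isfinite(deltas[m]):
            xs.append(deltas[m])
            ys.append(res.loc[m, "log2FC"])
    if len(xs) >= 3 and np.std(xs) > 0 and np.std(ys) > 0:
        out["delta_vs_log2fc_r"] = float(np.corrcoef(xs, ys)[0, 1])
    else:
        out["delta_vs_log2fc_r"] = float("nan")
    return out


def top_bin_enrichment(result: PipelineResult, ranking: str,
                       annotation: str = "early_enhancer") -> float:
    table = result.rankbin["enrichment"]
    sel = table[(table.ranking == ranking) & (table.annotation == annotation)
                & (table.bin == 0)]
    return float(sel.enrichment.iloc[0])


def hotness_correlation(result: PipelineResult, dataset: SyntheticDataset,
                        seed: int = 0) -> tuple[float, float, float]:
    """Pearson r between pioneer summit reads and the hotness score of the
    overlapping HOT annotation (0 when none overlaps)."""
    from pionuc.enrichment import correlate

    regions = result.extras["pioneer_regions"]
    stats_df = result.rankbin["stats"]
    hot = hotness_per_peak(regions, dataset.hot_regions)
    reads = stats_df.loc[[p.name for p in regions], "summit_reads"].to_numpy()
    return correlate(reads, hot.astype(float), permutations=2000, seed=seed)
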
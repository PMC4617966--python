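"""File-based pipeline stages over a self-describing run directory.

Each stage reads the artifacts of its upstream stages from conventional
paths inside the run directory, writes its own outputs plus a JSON
manifest, and never mutates its inputs.  A missing upstream artifact
raises :class:`UpstreamMissing`, naming the subcommand that produces it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from pionuc import io
from pionuc.analysis import (differential_arc, group_recovery,
                             hotness_correlation, mnase_arc,
                             pioneer_region_arc, rank_bin_arc, run_pipeline,
                             simulate_all_fragments)
from pionuc.config import RunConfig, write_manifest
from pionuc.diffbind import group_fractions
from pionuc.intervals import GenomicInterval
from pionuc.motifs import scan_genome
from pionuc.nucleosomes import call_nucleosomes, predict_intrinsic_occupancy
from pionuc.signal import pileup
from pionuc.simulate import GroundTruth, SyntheticDataset, generate_genome


class UpstreamMissing(FileNotFoundError):
    def __init__(self, path: Path, producer: str) -> None:
        super().__init__(
            f"missing {path}; run the '{producer}' subcommand first"
        )


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise UpstreamMissing(path, producer)
    return path


def stage_simulate(cfg: RunConfig, outdir: Path) -> SyntheticDataset:
    outdir.mkdir(parents=True, exist_ok=True)
    dataset = generate_genome(cfg.synthetic_config())
    io.write_fasta(outdir / "genome.fa", dataset.genome)
    io.write_tss_bed(outdir / "tss.bed", dataset.tss)
    io.write_intervals(outdir / "enhancers.bed", dataset.enhancers)
    io.write_bed6(
        outdir / "hot_regions.bed",
        [(iv, f"hot_{i}", float(h), ".") for i, (iv, h) in enumerate(dataset.hot_regions)],
    )
    dataset.truth.to_json(outdir / "ground_truth.json")
    frag_dir = outdir / "fragments"
    frag_dir.mkdir(exist_ok=True)
    for name, frags in simulate_all_fragments(dataset).items():
        io.write_fragments(frag_dir / f"{name}.bed", frags)
    cfg.to_yaml(outdir / "config.yaml")
    write_manifest(outdir / "manifest_simulate.json", "simulate", cfg,
                   n_regions=len(dataset.truth.regions))
    return dataset


def load_dataset(outdir: Path) -> SyntheticDataset:
    cfg = RunConfig.from_yaml(_require(outdir / "config.yaml", "simulate"))
    genome = io.read_fasta(_require(outdir / "genome.fa", "simulate"))
    truth = GroundTruth.from_json(_require(outdir / "ground_truth.json", "simulate"))
    tss = io.read_tss_bed(_require(outdir / "tss.bed", "simulate"))
    hot_rows = io.read_bed6(_require(outdir / "hot_regions.bed", "simulate"))
    syn = cfg.synthetic_config()
    syn.chrom_lengths = {c: len(s) for c, s in genome.items()}
    dataset = SyntheticDataset(
        config=syn,
        genome=genome,
        truth=truth,
        tss=tss,
        hot_regions=[(iv, int(score)) for iv, _n, score, _s in hot_rows],
        intrinsic=predict_intrinsic_occupancy(genome, syn.intrinsic),
    )
    return dataset


def load_fragments(outdir: Path) -> dict[str, dict[str, np.ndarray]]:
    frag_dir = _require(outdir / "fragments", "simulate")
    return {
        p.stem: io.read_fragments(p) for p in sorted(frag_dir.glob("*.bed"))
    }


def _chrom_lengths(outdir: Path) -> dict[str, int]:
    genome = io.read_fasta(_require(outdir / "genome.fa", "simulate"))
    return {c: len(s) for c, s in genome.items()}


def stage_pileup(cfg: RunConfig, outdir: Path) -> None:
    lengths = _chrom_lengths(outdir)
    cov_dir = outdir / "coverage"
    cov_dir.mkdir(exist_ok=True)
    for name, frags in load_fragments(outdir).items():
        io.write_bedgraph(cov_dir / f"{name}.bedgraph", pileup(frags, lengths))
    write_manifest(outdir / "manifest_pileup.json", "pileup", cfg)


def stage_normalize(cfg: RunConfig, outdir: Path) -> None:
    import json

    lengths = _chrom_lengths(outdir)
    frags = load_fragments(outdir)
    norm_dir = outdir / "norm"
    norm_dir.mkdir(exist_ok=True)
    tracks = mnase_arc(frags, lengths)
    for genotype, track in tracks.items():
        io.write_bedgraph(norm_dir / f"mnase_{genotype}.bedgraph", track)
        with open(norm_dir / f"mnase_{genotype}.json", "w") as fh:
            json.dump({"scheme": track.scheme,
                       "background_mean": track.background_mean,
                       "background_sd": track.background_sd}, fh)
    write_manifest(outdir / "manifest_normalize.json", "normalize", cfg)


def stage_callpeaks(cfg: RunConfig, outdir: Path) -> None:
    from pionuc.analysis import build_chip_arm

    lengths = _chrom_lengths(outdir)
    frags = load_fragments(outdir)
    peak_dir = outdir / "peaks"
    peak_dir.mkdir(exist_ok=True)
    counts = {}
    for factor in ("patterning", "pioneer"):
        for genotype in ("wt", "mutant"):
            arm = build_chip_arm(frags, factor, genotype, lengths, cfg)
            io.write_narrowpeak(
                peak_dir / f"{factor}_{genotype}_combined.narrowPeak",
                list(arm.combined_peaks),
            )
            io.write_narrowpeak(
                peak_dir / f"{factor}_{genotype}_enriched.narrowPeak",
                list(arm.enriched_peaks),
            )
            counts[f"{factor}_{genotype}"] = len(arm.enriched_peaks)
    write_manifest(outdir / "manifest_callpeaks.json", "callpeaks", cfg,
                   peak_counts=counts)


def stage_diffbind(cfg: RunConfig, outdir: Path) -> pd.DataFrame:
    lengths = _chrom_lengths(outdir)
    frags = load_fragments(outdir)
    diff = differential_arc(frags, lengths, cfg)
    dd = outdir / "diffbind"
    dd.mkdir(exist_ok=True)
    diff["counts"].to_csv(dd / "counts.tsv", sep="\t")
    out = diff["results"].copy()
    out["simple_delta"] = diff["simple_delta"]
    out.to_csv(dd / "results.tsv", sep="\t", index_label="id")
    io.write_narrowpeak(dd / "regions.narrowPeak", diff["regions"])
    write_manifest(outdir / "manifest_diffbind.json", "diffbind", cfg,
                   n_regions=len(diff["regions"]),
                   sign_agreement=diff["sign_agreement"])
    return out


def stage_delta_mnase(cfg: RunConfig, outdir: Path) -> pd.DataFrame:
    from pionuc.nucleosomes import delta_mnase

    lengths = _chrom_lengths(outdir)
    frags = load_fragments(outdir)
    regions = io.read_narrowpeak(
        _require(outdir / "diffbind" / "regions.narrowPeak", "diffbind")
    )
    tracks = mnase_arc(frags, lengths)
    deltas = delta_mnase(regions, tracks["wt"], tracks["mutant"], cfg.delta_window)
    df = pd.DataFrame(
        [{"id": d.region, "delta_mnase": d.delta, "excluded": d.excluded}
         for d in deltas]
    )
    df.to_csv(outdir / "delta_mnase.tsv", sep="\t", index=False)
    write_manifest(outdir / "manifest_delta_mnase.json", "delta-mnase", cfg)
    return df


def stage_motifs(cfg: RunConfig, outdir: Path) -> None:
    from pionuc.motifs import (classify_motif_configuration,
                               count_motifs_near_summit)

    dataset = load_dataset(outdir)
    hits = scan_genome(dataset.genome, dataset.config.scan_motifs)
    mdir = outdir / "motifs"
    mdir.mkdir(exist_ok=True)
    io.write_bed6(
        mdir / "hits.bed",
        [(GenomicInterval(h.chrom, h.start, h.end), h.motif, 0.0, h.strand)
         for h in hits],
    )
    regions = io.read_narrowpeak(
        _require(outdir / "diffbind" / "regions.narrowPeak", "diffbind")
    )
    rows = []
    for p in regions:
        conf = classify_motif_configuration(
            p, hits, cfg.central_motif_window, cfg.flank_motif_window
        )
        rows.append(dict(
            id=p.name,
            n_central=conf.n_central, n_flank=conf.n_flank, config=conf.label,
            n_near_summit=count_motifs_near_summit(p, hits, cfg.central_motif_window),
        ))
    pd.DataFrame(rows).to_csv(mdir / "region_motifs.tsv", sep="\t", index=False)
    write_manifest(outdir / "manifest_motifs.json", "motifs", cfg, n_hits=len(hits))


def stage_nucleosomes(cfg: RunConfig, outdir: Path) -> None:
    lengths = _chrom_lengths(outdir)
    frags = load_fragments(outdir)
    tracks = mnase_arc(frags, lengths)
    calls = call_nucleosomes(
        tracks["mutant"], cfg.low_pass_fraction, cfg.nucleosome_min_score
    )
    ndir = outdir / "nucleosomes"
    ndir.mkdir(exist_ok=True)
    io.write_bed6(
        ndir / "dyads.bed",
        [(GenomicInterval(c.chrom, max(c.dyad - 73, 0), c.dyad + 74),
          f"nuc_{i}", c.score, ".") for i, c in enumerate(calls)],
    )
    write_manifest(outdir / "manifest_nucleosomes.json", "nucleosomes", cfg,
                   n_calls=len(calls))


def stage_enrich(cfg: RunConfig, outdir: Path) -> pd.DataFrame:
    dataset = load_dataset(outdir)
    frags = load_fragments(outdir)
    lengths = dataset.config.chrom_lengths
    diff = differential_arc(frags, lengths, cfg)
    mnase = mnase_arc(frags, lengths)
    pio = pioneer_region_arc(frags, lengths, dataset.tss, cfg)
    genome_hits = scan_genome(dataset.genome, dataset.config.scan_motifs)
    annotations = {
        "early_enhancer": dataset.enhancers,
        "hot": [iv for iv, h in dataset.hot_regions if h >= cfg.hotness_cutoff],
        "patterning_peak": [p.interval for p in diff["regions"]],
    }
    rb = rank_bin_arc(pio["regions"], pio["arm"].chip_norm, mnase, annotations,
                      genome_hits, sum(lengths.values()), cfg)
    edir = outdir / "enrich"
    edir.mkdir(exist_ok=True)
    rb["enrichment"].to_csv(edir / "bin_enrichment.tsv", sep="\t", index=False)
    rb["stats"].to_csv(edir / "region_stats.tsv", sep="\t")
    write_manifest(outdir / "manifest_enrich.json", "enrich", cfg,
                   n_regions=len(pio["regions"]))
    return rb["enrichment"]


def stage_report(cfg: RunConfig, outdir: Path) -> dict:
    dataset = load_dataset(outdir)
    frags = load_fragments(outdir)
    result = run_pipeline(dataset, cfg, fragments=frags)
    rdir = outdir / "report"
    rdir.mkdir(exist_ok=True)

    counts = result.group_counts()
    fractions = group_fractions(counts)
    pd.DataFrame(
        [{"group": g, "count": counts[g], "percent": fractions[g]}
         for g in ("I", "II", "III")]
    ).to_csv(rdir / "group_counts.tsv", sep="\t", index=False)

    recovery = group_recovery(result)
    pd.DataFrame([recovery]).to_csv(rdir / "recovery.tsv", sep="\t", index=False)
    result.rankbin["enrichment"].to_csv(rdir / "bin_enrichment.tsv", sep="\t",
                                        index=False)
    r, p_perm, p_t = hotness_correlation(result, dataset, seed=cfg.seed)
    pd.DataFrame([
        {"pair": "summit_reads~hotness", "r": r, "p_permutation": p_perm,
         "p_analytic": p_t},
        {"pair": "delta_mnase~log2FC_groupI", "r": recovery["delta_vs_log2fc_r"],
         "p_permutation": float("nan"), "p_analytic": float("nan")},
    ]).to_csv(rdir / "correlations.tsv", sep="\t", index=False)
    pd.DataFrame([{
        "n_pioneer_regions": len(result.extras["pioneer_regions"]),
        "fraction_nucleosomal": result.nucleosome["fraction_nucleosomal"],
        "n_dyad_calls": len(result.nucleosome["calls"]),
    }]).to_csv(rdir / "nucleosomes.tsv", sep="\t", index=False)

    summary = {
        "group_counts": counts,
        "group_fractions": fractions,
        "n_regions": int(len(result.differential["regions"])),
        **recovery,
    }
    write_manifest(outdir / "manifest_report.json", "report", cfg, **summary)
    return summary
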
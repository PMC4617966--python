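"""Synthetic genome, annotation, and fragment-level ChIP/MNase simulator
with full ground truth.

The simulated world mirrors the biology under study: enhancer-like regions
are embedded in GC-rich, intrinsically nucleosome-favoring sequence (~800
bp, about five nucleosome footprints) and carry a variable number of
planted pioneer-factor heptamer motifs; housekeeping-promoter-like "open"
regions are AT-rich with homopolymer runs and intrinsically disfavor
nucleosomes.  In the wild type, the pioneer factor locally depletes
nucleosomes around each enhancer's motif cluster in proportion to its motif
count; in the mutant (pioneer absent), occupancy reverts to the intrinsic
sequence preference.  Patterning-factor ChIP enrichment scales with
accessibility times motif affinity, so enhancer binding collapses in the
mutant and — by mass action, at fixed nuclear factor concentration — a
conserved fraction of the freed factor redistributes to the constitutively
open regions.

Every region carries a ground-truth group label (I: decreased binding in
the mutant; II: unchanged; III: increased), the planted motif placements,
depletion depth, and a hotness score, so each downstream stage can be
scored against a known answer.

All randomness flows from a single seed through per-stage tagged
substreams; a fixed seed reproduces every emitted file byte for byte.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from pionuc.intervals import CoverageTrack, GenomicInterval, Peak, TSSSet
from pionuc.motifs import PIONEER_MOTIFS, MotifHit, reverse_complement_pattern, scan_genome
from pionuc.nucleosomes import IntrinsicModel, predict_intrinsic_occupancy


def rng_for(seed: int, tag: str) -> np.random.Generator:
    """Deterministic per-stage substream: stable across runs and platforms."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(tag.encode())])


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic dataset.

    Depths, region counts, the 4-fold-scale planted decrease (via the
    accessibility arithmetic), and the motif-count distribution define the
    conditions every recovery test runs under.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000}
    )
    seed: int = 0

    # regions
    n_enhancers: int = 300
    n_open_regions: int = 200        # promoter-like: open + TSS at center
    n_distal_open_regions: int = 150  # open chromatin far from any TSS
    n_control_regions: int = 150
    n_hot_regions: int = 150
    enhancer_width: int = 800
    open_width: int = 400
    control_width: int = 400
    slot_spacing: int = 2400
    edge_margin: int = 2500

    # sequence composition
    gc_background: float = 0.40
    gc_enhancer: float = 0.58
    gc_open: float = 0.22
    open_run_length: tuple[int, int] = (6, 10)
    open_run_period: int = 40

    # motifs
    plant_motifs: tuple[str, ...] = ("CAGGTAG", "CAGGTAA")
    scan_motifs: tuple[str, ...] = PIONEER_MOTIFS
    motif_count_values: tuple[int, ...] = (1, 2, 3, 4)
    motif_count_probs: tuple[float, ...] = (0.2, 0.3, 0.3, 0.2)
    motif_halfwindow: int = 100  # plant midpoints within +/- this of center

    # intrinsic occupancy and pioneer-driven depletion
    intrinsic: IntrinsicModel = field(default_factory=IntrinsicModel)
    depletion_per_motif: float = 0.25
    depletion_max: float = 0.75
    depletion_sd: float = 125.0  # bp, Gaussian footprint around motif cluster
    min_occupancy: float = 0.02

    # MNase fragments
    mnase_depth: int = 2_000_000
    mnase_frag_mean: float = 147.0
    mnase_frag_sd: float = 10.0
    dyad_spacing: int = 185
    dyad_jitter_sd: float = 12.0
    dyad_weight_floor: float = 0.02

    # ChIP fragments
    chip_depth: int = 2_000_000
    chip_fragment_length: int = 150
    chip_summit_sd: float = 60.0
    chip_peak_fraction: float = 0.4  # wild-type fraction of depth in peaks
    chip_input_bias: float = 0.2  # intrinsic-bias amplitude in input
    patterning_open_weight: float = 0.3
    pioneer_open_weight: float = 0.4
    control_weight: float = 1.0
    pioneer_control_weight: float = 0.3
    redistribution_fraction: float = 0.8
    depth_jitter: float = 0.1  # per-replicate uniform depth jitter amplitude

    def validate(self) -> None:
        if any(n < 0 for n in (self.n_enhancers, self.n_open_regions,
                               self.n_distal_open_regions,
                               self.n_control_regions, self.n_hot_regions)):
            raise ValueError("region counts must be >= 0")
        if abs(sum(self.motif_count_probs) - 1.0) > 1e-9:
            raise ValueError("motif_count_probs must sum to 1")
        for p in (self.chip_peak_fraction, self.redistribution_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Per-region truth labels plus planted motif placements."""

    regions: pd.DataFrame  # region_id, chrom, start, end, center, summit,
    #                        kind, n_motifs, depletion, group, hotness,
    #                        is_enhancer
    motif_hits: list[MotifHit]
    dyads: dict[str, dict[str, np.ndarray]]  # genotype -> chrom -> dyad pos

    def to_json(self, path) -> None:
        payload = {
            "regions": self.regions.to_dict(orient="records"),
            "motif_hits": [asdict(h) for h in self.motif_hits],
            "dyads": {
                g: {c: v.tolist() for c, v in per.items()}
                for g, per in self.dyads.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            pd.DataFrame(payload["regions"]),
            [MotifHit(**h) for h in payload["motif_hits"]],
            {
                g: {c: np.array(v, dtype=np.int64) for c, v in per.items()}
                for g, per in payload["dyads"].items()
            },
        )


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: dict[str, str]
    truth: GroundTruth
    tss: TSSSet
    hot_regions: list[tuple[GenomicInterval, int]]
    intrinsic: CoverageTrack

    @property
    def enhancers(self) -> list[GenomicInterval]:
        df = self.truth.regions
        return [
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in df[df.kind == "enhancer"].itertuples()
        ]

    def region_peaks(self) -> list[Peak]:
        """Planted regions as Peak objects (summit = true binding summit)."""
        return [
            Peak(GenomicInterval(r.chrom, int(r.start), int(r.end)),
                 int(r.summit), r.region_id)
            for r in self.truth.regions.itertuples()
        ]


# ---------------------------------------------------------------------------
# genome generation


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=p)


def _open_region_bases(rng: np.random.Generator, n: int, cfg: SyntheticConfig) -> np.ndarray:
    bases = _random_bases(rng, n, cfg.gc_open)
    lo, hi = cfg.open_run_length
    pos = cfg.open_run_period // 2
    while pos < n - hi:
        run = int(rng.integers(lo, hi + 1))
        base = ord("A") if rng.random() < 0.5 else ord("T")
        bases[pos : pos + run] = base
        pos += cfg.open_run_period
    return bases


def _place_motifs(
    rng: np.random.Generator,
    seq: np.ndarray,
    chrom: str,
    center: int,
    k: int,
    cfg: SyntheticConfig,
) -> list[MotifHit]:
    """Plant k non-overlapping motif copies with midpoints within the
    central half-window; strands random."""
    length = len(cfg.plant_motifs[0])
    placed: list[MotifHit] = []
    occupied: list[tuple[int, int]] = []
    attempts = 0
    while len(placed) < k and attempts < 200:
        attempts += 1
        mid = center + int(rng.integers(-cfg.motif_halfwindow, cfg.motif_halfwindow + 1))
        start = mid - length // 2
        if any(start < e + 5 and start + length > s - 5 for s, e in occupied):
            continue
        motif = cfg.plant_motifs[int(rng.integers(len(cfg.plant_motifs)))]
        strand = "+" if rng.random() < 0.5 else "-"
        written = motif if strand == "+" else reverse_complement_pattern(motif)
        seq[start : start + length] = np.frombuffer(written.encode(), dtype=np.uint8)
        occupied.append((start, start + length))
        placed.append(MotifHit(chrom, start, start + length, strand, motif))
    if len(placed) < k:
        raise RuntimeError("could not place motifs without overlap")
    return placed


def _scrub_spurious_motifs(
    genome: dict[str, np.ndarray],
    planted: set[tuple[str, int, int, str]],
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    max_iter: int = 25,
) -> None:
    """Rewrite chance motif occurrences so the scanner's output on the
    emitted genome is exactly the planted placement set (closed loop)."""
    protected = {c: np.zeros(len(genome[c]), dtype=bool) for c in genome}
    for chrom, s, e, _m in planted:
        protected[chrom][s:e] = True
    for _ in range(max_iter):
        seqs = {c: arr.tobytes().decode("ascii") for c, arr in genome.items()}
        hits = scan_genome(seqs, cfg.scan_motifs)
        spurious = [h for h in hits if (h.chrom, h.start, h.end, h.motif) not in planted]
        if not spurious:
            return
        for h in spurious:
            free = np.arange(h.start, h.end)[~protected[h.chrom][h.start : h.end]]
            if free.size == 0:
                continue  # fully inside planted footprints; next pass resolves
            genome[h.chrom][free] = _random_bases(rng, free.size, cfg.gc_background)
    raise RuntimeError("motif scrubbing did not converge")


def generate_genome(config: SyntheticConfig) -> SyntheticDataset:
    """Emit genome sequence, annotations, and ground truth."""
    config.validate()
    rng = rng_for(config.seed, "genome")
    genome = {
        chrom: _random_bases(rng, length, config.gc_background)
        for chrom, length in config.chrom_lengths.items()
    }

    # non-overlapping slots, shuffled deterministically
    max_width = max(config.enhancer_width, config.open_width, config.control_width)
    slots: list[tuple[str, int]] = []
    for chrom, length in config.chrom_lengths.items():
        lo = config.edge_margin
        hi = length - config.edge_margin - max_width
        slots.extend((chrom, int(p)) for p in range(lo, hi, config.slot_spacing))
    rng.shuffle(slots)  # type: ignore[arg-type]
    n_total = (config.n_enhancers + config.n_open_regions
               + config.n_distal_open_regions + config.n_control_regions)
    if n_total > len(slots):
        raise ValueError(
            f"cannot place {n_total} regions without overlap in this genome "
            f"({len(slots)} slots available)"
        )

    records = []
    motif_hits: list[MotifHit] = []
    tss_sites: list[tuple[str, int, str, str]] = []
    cursor = 0

    motif_counts = rng.choice(
        np.array(config.motif_count_values),
        size=config.n_enhancers,
        p=np.array(config.motif_count_probs),
    ) if config.n_enhancers else np.empty(0, dtype=int)

    for i in range(config.n_enhancers):
        chrom, pos = slots[cursor]; cursor += 1
        w = config.enhancer_width
        center = pos + w // 2
        genome[chrom][pos : pos + w] = _random_bases(rng, w, config.gc_enhancer)
        k = int(motif_counts[i])
        placed = _place_motifs(rng, genome[chrom], chrom, center, k, config)
        motif_hits.extend(placed)
        summit = int(np.mean([h.midpoint for h in placed]))
        records.append(dict(
            region_id=f"enh_{i}", chrom=chrom, start=pos, end=pos + w,
            center=center, summit=summit, kind="enhancer", n_motifs=k,
            depletion=min(config.depletion_per_motif * k, config.depletion_max),
            group="I", hotness=0, is_enhancer=True,
        ))

    for i in range(config.n_open_regions):
        chrom, pos = slots[cursor]; cursor += 1
        w = config.open_width
        genome[chrom][pos : pos + w] = _open_region_bases(rng, w, config)
        center = pos + w // 2
        tss_sites.append((chrom, center, "+", f"hk_{i}"))
        records.append(dict(
            region_id=f"open_{i}", chrom=chrom, start=pos, end=pos + w,
            center=center, summit=center, kind="open", n_motifs=0,
            depletion=0.0, group="III", hotness=0, is_enhancer=False,
        ))

    for i in range(config.n_distal_open_regions):
        chrom, pos = slots[cursor]; cursor += 1
        w = config.open_width
        genome[chrom][pos : pos + w] = _open_region_bases(rng, w, config)
        center = pos + w // 2
        records.append(dict(
            region_id=f"dopen_{i}", chrom=chrom, start=pos, end=pos + w,
            center=center, summit=center, kind="open_distal", n_motifs=0,
            depletion=0.0, group="III", hotness=0, is_enhancer=False,
        ))

    for i in range(config.n_control_regions):
        chrom, pos = slots[cursor]; cursor += 1
        w = config.control_width
        center = pos + w // 2
        records.append(dict(
            region_id=f"ctrl_{i}", chrom=chrom, start=pos, end=pos + w,
            center=center, summit=center, kind="control", n_motifs=0,
            depletion=0.0, group="II", hotness=0, is_enhancer=False,
        ))

    planted_keys = {(h.chrom, h.start, h.end, h.motif) for h in motif_hits}
    _scrub_spurious_motifs(genome, planted_keys, config, rng)

    df = pd.DataFrame(records) if records else pd.DataFrame(
        columns=["region_id", "chrom", "start", "end", "center", "summit",
                 "kind", "n_motifs", "depletion", "group", "hotness",
                 "is_enhancer"]
    )

    # hotness: the strongest (most motif-rich) enhancers host the most TFs
    hot_regions: list[tuple[GenomicInterval, int]] = []
    if len(df) and config.n_hot_regions and config.n_enhancers:
        enh = df[df.kind == "enhancer"]
        order = enh.sort_values("n_motifs", ascending=False, kind="stable")
        chosen = order.head(min(config.n_hot_regions, len(order)))
        hot_scores = {}
        for r in chosen.itertuples():
            hotness = int(6 + r.n_motifs + rng.poisson(0.5))
            hot_scores[r.region_id] = hotness
            hot_regions.append(
                (GenomicInterval(r.chrom, int(r.start), int(r.end)), hotness)
            )
        df["hotness"] = df["region_id"].map(hot_scores).fillna(0).astype(int)

    genome_str = {c: arr.tobytes().decode("ascii") for c, arr in genome.items()}
    intrinsic = predict_intrinsic_occupancy(genome_str, config.intrinsic)

    dataset = SyntheticDataset(
        config=config,
        genome=genome_str,
        truth=GroundTruth(df, motif_hits, dyads={}),
        tss=TSSSet(tss_sites),
        hot_regions=hot_regions,
        intrinsic=intrinsic,
    )
    dataset.truth.dyads = {
        g: _candidate_dyads(dataset, g) for g in ("wt", "mutant")
    }
    return dataset


# ---------------------------------------------------------------------------
# occupancy landscapes and MNase


def occupancy_landscape(dataset: SyntheticDataset, genotype: str) -> CoverageTrack:
    """Per-bp nucleosome occupancy: intrinsic preference, minus (wild type
    only) a pioneer-driven depletion field.

    The depletion field is a sum of Gaussian footprints, one per planted
    motif copy, each of depth ``depletion_per_motif`` and width
    ``depletion_sd``, saturating at ``depletion_max`` — so motif-rich
    enhancers are depleted more deeply, and the footprint follows the
    spatial layout of the motifs (tight clusters deplete locally, spread
    motifs deplete a wider span).
    """
    if genotype not in ("wt", "mutant"):
        raise ValueError(f"genotype must be 'wt' or 'mutant', got {genotype!r}")
    cfg = dataset.config
    data = {c: arr.copy() for c, arr in dataset.intrinsic.data.items()}
    if genotype == "wt" and dataset.truth.motif_hits:
        dep = {c: np.zeros(arr.size) for c, arr in data.items()}
        half = int(3 * cfg.depletion_sd)
        for h in dataset.truth.motif_hits:
            arr = dep[h.chrom]
            lo, hi = max(h.midpoint - half, 0), min(h.midpoint + half, arr.size)
            x = np.arange(lo, hi)
            arr[lo:hi] += cfg.depletion_per_motif * np.exp(
                -((x - h.midpoint) ** 2) / (2 * cfg.depletion_sd**2)
            )
        for c in data:
            data[c] -= np.minimum(dep[c], cfg.depletion_max)
    for c in data:
        np.clip(data[c], cfg.min_occupancy, 1.0, out=data[c])
    return CoverageTrack(data, genotype=genotype, assay="occupancy", normalized=True)


def _candidate_dyads(dataset: SyntheticDataset, genotype: str) -> dict[str, np.ndarray]:
    spacing = dataset.config.dyad_spacing
    return {
        chrom: np.arange(spacing // 2, length - spacing // 2, spacing, dtype=np.int64)
        for chrom, length in dataset.config.chrom_lengths.items()
    }


def _replicate_depth(cfg: SyntheticConfig, assay_tag: str, replicate: int, depth: int) -> int:
    jitter = rng_for(cfg.seed, f"jitter:{assay_tag}:rep{replicate}").uniform(
        -cfg.depth_jitter, cfg.depth_jitter
    )
    return int(round(depth * (1 + jitter)))


def _sample_from_weights(
    rng: np.random.Generator, weights: np.ndarray, n: int
) -> np.ndarray:
    cdf = np.cumsum(weights)
    return np.searchsorted(cdf, rng.random(n) * cdf[-1], side="right")


def simulate_mnase(
    dataset: SyntheticDataset, genotype: str, replicate: int
) -> dict[str, np.ndarray]:
    """Paired-end MNase fragment spans for one replicate of one genotype.

    Dyads are drawn from the genotype's occupancy landscape sampled at the
    candidate-dyad grid (plus a small unpositioned floor); fragment lengths
    are ~N(147, 10) and centers jitter around the chosen dyad.
    """
    cfg = dataset.config
    landscape = occupancy_landscape(dataset, genotype)
    chroms = list(cfg.chrom_lengths)
    dyads = dataset.truth.dyads[genotype]
    weights = np.concatenate([
        landscape.data[c][dyads[c]] + cfg.dyad_weight_floor for c in chroms
    ])
    offsets = np.cumsum([0] + [dyads[c].size for c in chroms])
    all_dyads = np.concatenate([dyads[c] for c in chroms])

    depth = _replicate_depth(cfg, "mnase", replicate, cfg.mnase_depth)
    rng = rng_for(cfg.seed, f"mnase:{genotype}:rep{replicate}")
    idx = _sample_from_weights(rng, weights, depth)
    centers = all_dyads[idx] + np.round(
        rng.normal(0, cfg.dyad_jitter_sd, depth)
    ).astype(np.int64)
    lengths = np.clip(
        np.round(rng.normal(cfg.mnase_frag_mean, cfg.mnase_frag_sd, depth)),
        60, 300,
    ).astype(np.int64)
    return _fragments_by_chrom(idx, centers, lengths, chroms, offsets, cfg)


def _fragments_by_chrom(idx, centers, lengths, chroms, offsets, cfg):
    out = {}
    for ci, chrom in enumerate(chroms):
        sel = (idx >= offsets[ci]) & (idx < offsets[ci + 1])
        c = centers[sel]
        ln = lengths[sel]
        start = c - ln // 2
        end = start + ln
        L = cfg.chrom_lengths[chrom]
        start = np.clip(start, 0, L - 1)
        end = np.clip(end, start + 1, L)
        frags = np.column_stack([start, end])
        out[chrom] = frags[np.lexsort((frags[:, 1], frags[:, 0]))]
    return out


# ---------------------------------------------------------------------------
# ChIP


def _region_weights(dataset: SyntheticDataset, factor: str, genotype: str):
    """Per-region binding weights and the background weight, on a common
    mass scale so that total binding mass is conserved across genotypes."""
    cfg = dataset.config
    df = dataset.truth.regions
    if df.empty:
        return df, np.empty(0), 1.0
    occ_wt = occupancy_landscape(dataset, "wt")
    occ_mut = dataset.intrinsic  # mutant landscape is the intrinsic one
    acc_wt = np.array([
        1.0 - occ_wt.data[r.chrom][int(r.summit)] for r in df.itertuples()
    ])
    acc_mut = np.array([
        max(1.0 - occ_mut.data[r.chrom][int(r.summit)], cfg.min_occupancy)
        for r in df.itertuples()
    ])
    kind = df.kind.to_numpy()
    is_open = (kind == "open") | (kind == "open_distal")
    k = df.n_motifs.to_numpy(dtype=float)

    if factor == "pioneer":
        w = np.where(kind == "enhancer", k,
                     np.where(is_open, cfg.pioneer_open_weight,
                              cfg.pioneer_control_weight))
        w_wt = w.astype(float)
        w_g = w_wt
        bg_extra = 0.0
    elif factor == "patterning":
        w_wt = np.where(kind == "enhancer", k * acc_wt,
                        np.where(is_open, cfg.patterning_open_weight,
                                 cfg.control_weight)).astype(float)
        if genotype == "wt":
            w_g = w_wt
            bg_extra = 0.0
        else:
            w_enh_mut = k * acc_mut
            freed = float(np.sum((w_wt - w_enh_mut)[kind == "enhancer"]))
            w_g = w_wt.copy()
            w_g[kind == "enhancer"] = w_enh_mut[kind == "enhancer"]
            open_idx = np.flatnonzero(is_open)
            if open_idx.size:
                share = acc_mut[open_idx] / acc_mut[open_idx].sum()
                w_g[open_idx] += cfg.redistribution_fraction * freed * share
                bg_extra = (1 - cfg.redistribution_fraction) * freed
            else:
                bg_extra = freed
    else:
        raise ValueError(f"factor must be 'pioneer' or 'patterning', got {factor!r}")

    total_wt = float(w_wt.sum())
    background = total_wt * (1 - cfg.chip_peak_fraction) / cfg.chip_peak_fraction
    return df, w_g, background + bg_extra


def simulate_chip(
    dataset: SyntheticDataset,
    factor: str,
    genotype: str,
    replicate: int,
    is_input: bool = False,
) -> dict[str, np.ndarray]:
    """Single-end-style extended ChIP fragments (or matched input).

    ChIP fragments are a two-component mixture: a region component whose
    per-region mass follows accessibility x motif affinity (with mass-action
    redistribution in the mutant), and a background component that is
    uniform with a mild intrinsic-accessibility bias.  Input samples draw
    from the background component only.
    """
    cfg = dataset.config
    chroms = list(cfg.chrom_lengths)
    df, w_g, background_weight = _region_weights(dataset, factor, genotype)

    # background distribution over bp: uniform + intrinsic-bias noise
    bg = {
        c: 1.0 + cfg.chip_input_bias * (1.0 - dataset.intrinsic.data[c])
        for c in chroms
    }
    bg_flat = np.concatenate([bg[c] for c in chroms])
    bp_offsets = np.cumsum([0] + [cfg.chrom_lengths[c] for c in chroms])

    tag = f"chip:{factor}:{'input' if is_input else 'ip'}"
    depth = _replicate_depth(cfg, f"{tag}", replicate, cfg.chip_depth)
    rng = rng_for(cfg.seed, f"{tag}:{genotype}:rep{replicate}")

    total_region = float(w_g.sum()) if w_g.size else 0.0
    if is_input or total_region == 0:
        n_peak = 0
    else:
        p_peak = total_region / (total_region + background_weight)
        n_peak = int(rng.binomial(depth, p_peak))
    n_bg = depth - n_peak

    centers_parts = []
    chrom_idx_parts = []
    if n_peak:
        region_idx = _sample_from_weights(rng, w_g, n_peak)
        summits = df.summit.to_numpy()[region_idx]
        centers_parts.append(
            summits + np.round(rng.normal(0, cfg.chip_summit_sd, n_peak)).astype(np.int64)
        )
        chrom_codes = pd.Categorical(df.chrom, categories=chroms).codes
        chrom_idx_parts.append(np.asarray(chrom_codes)[region_idx])
    if n_bg:
        flat_pos = _sample_from_weights(rng, bg_flat, n_bg)
        ci = np.searchsorted(bp_offsets, flat_pos, side="right") - 1
        centers_parts.append(flat_pos - bp_offsets[ci])
        chrom_idx_parts.append(ci)

    centers = np.concatenate(centers_parts) if centers_parts else np.empty(0, dtype=np.int64)
    chrom_idx = np.concatenate(chrom_idx_parts) if chrom_idx_parts else np.empty(0, dtype=int)
    lengths = np.full(centers.size, cfg.chip_fragment_length, dtype=np.int64)

    out = {}
    for ci, chrom in enumerate(chroms):
        sel = chrom_idx == ci
        c = centers[sel]
        ln = lengths[sel]
        start = c - ln // 2
        end = start + ln
        L = cfg.chrom_lengths[chrom]
        start = np.clip(start, 0, L - 1)
        end = np.clip(end, start + 1, L)
        frags = np.column_stack([start, end])
        out[chrom] = frags[np.lexsort((frags[:, 1], frags[:, 0]))]
    return out


# ---------------------------------------------------------------------------
# simple positioned-nucleosome fixture


def simulate_positioned_mnase(
    dyads: Sequence[int],
    chrom_length: int,
    coverage: float = 30.0,
    frag_mean: float = 147.0,
    frag_sd: float = 10.0,
    jitter_sd: float = 10.0,
    seed: int = 0,
    chrom: str = "chr1",
) -> dict[str, np.ndarray]:
    """Fragments drawn around an explicit dyad array at a target coverage —
    the ground-truth fixture for nucleosome-caller recovery tests."""
    rng = np.random.default_rng(seed)
    n = int(coverage * chrom_length / frag_mean)
    idx = rng.integers(0, len(dyads), n)
    centers = np.asarray(dyads)[idx] + np.round(rng.normal(0, jitter_sd, n)).astype(int)
    lengths = np.clip(np.round(rng.normal(frag_mean, frag_sd, n)), 60, 300).astype(int)
    start = np.clip(centers - lengths // 2, 0, chrom_length - 1)
    end = np.clip(start + lengths, start + 1, chrom_length)
    frags = np.column_stack([start, end])
    return {chrom: frags[np.lexsort((frags[:, 1], frags[:, 0]))]}
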
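"""Nucleosome-dyad calling, summit anchoring, delta-MNase, metaprofiles,
and sequence-intrinsic occupancy prediction.

Dyads are called from MNase coverage after a Fourier low-pass filter
(keeping the lowest fraction of frequency components, which suppresses
sub-nucleosomal noise while preserving ~200 bp periodicity); local maxima
of the filtered, per-chromosome max-normalized signal become dyads, with
close maxima resolved to the higher one.

The delta-MNase statistic is the mutant-minus-wild-type mean of normalized
MNase signal around a peak summit; positions with zero raw reads are
excluded from the corresponding track's mean, since the log/Z transform of
an unsequenced position carries no occupancy information.

The intrinsic-occupancy model is a logistic function of windowed GC content
with a penalty for A/T homopolymer runs, capturing the qualitative contrast
between GC-rich nucleosome-favoring and AT-rich disfavoring sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy.special import expit

from pionuc.intervals import CoverageTrack, Peak
from pionuc.signal import NormalizedTrack

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NucleosomeCall:
    chrom: str
    dyad: int
    score: float
    width: float  # width at half max of the filtered peak, bp


@dataclass(frozen=True)
class DeltaMNase:
    region: str
    delta: float
    excluded: bool  # True when no position with nonzero reads remained


@dataclass
class Metaprofile:
    anchor: str  # "summit" | "dyad" | "tss"
    flank: int
    profile: np.ndarray  # length 2*flank+1, per-offset mean
    n_regions: int
    matrix: np.ndarray  # (n_regions, 2*flank+1), for heatmaps

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank + 1)


def fourier_lowpass(values: np.ndarray, low_pass_fraction: float = 0.02) -> np.ndarray:
    """Zero all but the lowest ``low_pass_fraction`` of frequency components.

    The retained band is independent of chromosome length: frequencies up
    to ``low_pass_fraction / 2`` cycles per bp survive (period >= 100 bp at
    the 2% default), which keeps nucleosome-scale structure.
    """
    n = values.size
    spec = np.fft.rfft(values)
    keep = max(2, int(np.ceil(low_pass_fraction * n / 2)))
    spec[keep:] = 0
    return np.fft.irfft(spec, n=n)


def call_nucleosomes(
    track: CoverageTrack,
    low_pass_fraction: float = 0.02,
    min_score: float = 0.2,
    min_separation: int = 120,
) -> list[NucleosomeCall]:
    """Dyad positions from Fourier-filtered coverage.

    Scores are the filtered signal after per-chromosome max-normalization,
    which makes the call set invariant to uniform coverage scaling; maxima
    closer than ``min_separation`` keep only the higher.
    """
    calls: list[NucleosomeCall] = []
    for chrom, arr in track.data.items():
        if arr.size < 4 / low_pass_fraction:
            logger.warning("chromosome %s too short for the Fourier filter; skipped", chrom)
            continue
        filt = fourier_lowpass(arr.astype(float), low_pass_fraction)
        top = filt.max()
        if top <= 0:
            continue
        norm = filt / top
        idx, props = sps.find_peaks(norm, height=min_score, distance=min_separation)
        if idx.size == 0:
            continue
        widths = sps.peak_widths(norm, idx, rel_height=0.5)[0]
        for pos, h, w in zip(idx, props["peak_heights"], widths):
            calls.append(NucleosomeCall(chrom, int(pos), float(h), float(w)))
    calls.sort(key=lambda c: (c.chrom, c.dyad))
    return calls


def align_to_nearest_nucleosome(
    summits: Sequence[Peak],
    calls: Sequence[NucleosomeCall],
    max_dist: int = 75,
) -> list[tuple[Peak, int, str]]:
    """Anchor each summit at the nearest dyad if one lies within
    ``max_dist`` bp ("nucleosomal"), else at the summit itself
    ("non-nucleosomal")."""
    dyads_by_chrom: dict[str, np.ndarray] = {}
    for c in calls:
        dyads_by_chrom.setdefault(c.chrom, [])
    for c in calls:
        dyads_by_chrom[c.chrom].append(c.dyad)  # type: ignore[union-attr]
    dyads_by_chrom = {k: np.array(sorted(v)) for k, v in dyads_by_chrom.items()}

    out = []
    for p in summits:
        dyads = dyads_by_chrom.get(p.chrom)
        if dyads is None or dyads.size == 0:
            out.append((p, p.summit, "non-nucleosomal"))
            continue
        i = np.searchsorted(dyads, p.summit)
        cand = dyads[max(0, i - 1) : i + 1]
        nearest = int(cand[np.abs(cand - p.summit).argmin()])
        if abs(nearest - p.summit) <= max_dist:
            out.append((p, nearest, "nucleosomal"))
        else:
            out.append((p, p.summit, "non-nucleosomal"))
    return out


def delta_mnase(
    regions: Sequence[Peak],
    wt: NormalizedTrack,
    mut: NormalizedTrack,
    window: int = 250,
    zero_mode: str = "per-position",
) -> list[DeltaMNase]:
    """Mutant minus wild-type mean normalized MNase over summit +/- window.

    zero_mode "per-position" (default): positions whose *raw* count is zero
    in a track are dropped from that track's mean.  zero_mode "per-region":
    a region is excluded entirely if either track has zero total raw reads
    in the window.
    """
    if zero_mode not in ("per-position", "per-region"):
        raise ValueError(f"unknown zero_mode {zero_mode!r}")
    out = []
    for p in regions:
        lo = max(p.summit - window, 0)
        hi = min(p.summit + window + 1, wt.data[p.chrom].size)
        w = wt.data[p.chrom][lo:hi]
        m = mut.data[p.chrom][lo:hi]
        w_raw = wt.raw.data[p.chrom][lo:hi] if wt.raw is not None else np.ones_like(w)
        m_raw = mut.raw.data[p.chrom][lo:hi] if mut.raw is not None else np.ones_like(m)
        if zero_mode == "per-region":
            if w_raw.sum() == 0 or m_raw.sum() == 0:
                out.append(DeltaMNase(p.name, float("nan"), True))
                continue
            out.append(DeltaMNase(p.name, float(m.mean() - w.mean()), False))
            continue
        w_ok = w_raw > 0
        m_ok = m_raw > 0
        if not w_ok.any() or not m_ok.any():
            out.append(DeltaMNase(p.name, float("nan"), True))
            continue
        out.append(DeltaMNase(p.name, float(m[m_ok].mean() - w[w_ok].mean()), False))
    return out


def metaprofile(
    anchors: Sequence[tuple[str, int]],
    track: CoverageTrack,
    flank: int = 1000,
    anchor_type: str = "summit",
) -> Metaprofile:
    """Per-offset mean of the track across regions aligned at anchors.

    Rows whose window exceeds chromosome bounds are dropped (not padded).
    """
    if not anchors:
        raise ValueError("no anchors given")
    rows = []
    for chrom, pos in anchors:
        arr = track.data[chrom]
        lo, hi = pos - flank, pos + flank + 1
        if lo < 0 or hi > arr.size:
            logger.debug("anchor %s:%d window out of bounds; dropped", chrom, pos)
            continue
        rows.append(arr[lo:hi])
    if not rows:
        raise ValueError("all anchor windows fell outside chromosome bounds")
    matrix = np.vstack(rows)
    return Metaprofile(anchor_type, flank, matrix.mean(axis=0), matrix.shape[0], matrix)


# ---------------------------------------------------------------------------
# Intrinsic occupancy


@dataclass(frozen=True)
class IntrinsicModel:
    """Logistic sequence model of nucleosome preference.

    occupancy = expit(alpha * (GC_w - gc0) - beta * ATrun_w), where GC_w is
    the GC fraction in a ``window`` bp window and ATrun_w the fraction of
    window positions inside A/T homopolymers of length >= ``min_run``.
    """

    alpha: float = 12.0
    beta: float = 6.0
    gc0: float = 0.45
    window: int = 147
    min_run: int = 5


def _window_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean with edge shrinkage."""
    cs = np.concatenate(([0.0], np.cumsum(x, dtype=float)))
    half = window // 2
    n = x.size
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + window - half, 0, n)
    return (cs[hi] - cs[lo]) / np.maximum(hi - lo, 1)


def at_run_mask(sequence: str, min_run: int = 5) -> np.ndarray:
    """Boolean mask of positions inside A/T homopolymer runs >= min_run."""
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    mask = np.zeros(arr.size, dtype=bool)
    for base in (ord("A"), ord("T")):
        is_b = arr == base
        edges = np.diff(np.concatenate(([0], is_b.view(np.int8), [0])))
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        for s, e in zip(starts, ends):
            if e - s >= min_run:
                mask[s:e] = True
    return mask


def predict_intrinsic_occupancy(
    genome: dict[str, str],
    model: IntrinsicModel | None = None,
) -> CoverageTrack:
    """Probability-like per-bp intrinsic nucleosome occupancy from sequence."""
    model = model or IntrinsicModel()
    data = {}
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        is_gc = ((arr == ord("G")) | (arr == ord("C"))).astype(float)
        gc = _window_mean(is_gc, model.window)
        atrun = _window_mean(at_run_mask(seq, model.min_run).astype(float), model.window)
        data[chrom] = expit(model.alpha * (gc - model.gc0) - model.beta * atrun)
    return CoverageTrack(data, assay="intrinsic-occupancy", normalized=True)
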
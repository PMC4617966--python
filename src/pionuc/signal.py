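"""Fragment pileup and the two track-normalization schemes.

MNase coverage is log2-transformed (pseudocount 1) and Z-scored over all
genome positions.  ChIP coverage is scaled by the genome-wide median and
Z-scored using the mean and standard deviation of positions lying outside
the combined peak set, so that the peak signal itself does not distort the
background estimate.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import numpy as np

from pionuc.intervals import CoverageTrack, GenomicInterval

logger = logging.getLogger(__name__)


class NormalizedTrack(CoverageTrack):
    """A CoverageTrack on a Z-score scale, carrying its normalization record
    and a reference to the raw counts it came from (needed for zero-read
    masking downstream)."""

    def __init__(
        self,
        data: dict[str, np.ndarray],
        raw: CoverageTrack | None,
        scheme: str,
        background_mean: float,
        background_sd: float,
        excluded_regions: Sequence[GenomicInterval] = (),
        **meta,
    ) -> None:
        super().__init__(data, normalized=True, **meta)
        self.raw = raw
        self.scheme = scheme
        self.background_mean = background_mean
        self.background_sd = background_sd
        self.excluded_regions = list(excluded_regions)


def pileup(fragments: dict[str, np.ndarray], chrom_lengths: dict[str, int]) -> CoverageTrack:
    """Per-bp count of covering fragments via the difference-array trick.

    Fragments extending past a chromosome end are clipped (and logged).
    """
    data = {}
    n_clipped = 0
    for chrom, length in chrom_lengths.items():
        diff = np.zeros(length + 1, dtype=np.int64)
        frags = fragments.get(chrom)
        if frags is not None and len(frags):
            starts = frags[:, 0]
            ends = frags[:, 1]
            n_clipped += int((starts < 0).sum() + (ends > length).sum())
            np.add.at(diff, np.clip(starts, 0, length), 1)
            np.add.at(diff, np.clip(ends, 0, length), -1)
        data[chrom] = np.cumsum(diff[:-1])
    if n_clipped:
        logger.warning("clipped %d fragment ends exceeding chromosome bounds", n_clipped)
    return CoverageTrack(data)


def extend_and_pileup(
    items: dict[str, np.ndarray],
    chrom_lengths: dict[str, int],
    mode: str = "paired-span",
    fragment_length: int | None = None,
) -> CoverageTrack:
    """Build coverage from fragment spans or from single-end reads extended
    to the library fragment length.

    ``items`` maps chromosome to an (n, 2) array: [start, end) spans in
    paired-span mode, or (5'-position, strand) rows with strand +1/-1 in
    single-end-extend mode.
    """
    if mode == "paired-span":
        return pileup(items, chrom_lengths)
    if mode != "single-end-extend":
        raise ValueError(f"unknown mode {mode!r}")
    if fragment_length is None:
        raise ValueError("single-end-extend mode requires fragment_length")
    frags = {}
    for chrom, reads in items.items():
        pos = reads[:, 0].astype(np.int64)
        strand = reads[:, 1]
        start = np.where(strand >= 0, pos, pos - fragment_length + 1)
        frags[chrom] = np.column_stack([start, start + fragment_length])
    return pileup(frags, chrom_lengths)


def normalize_mnase(
    track: CoverageTrack, pseudocount: float = 1.0, stride: int = 1
) -> NormalizedTrack:
    """log2(count + pseudocount), then Z-score over all genome positions."""
    if track.total() == 0:
        raise ValueError("all-zero track cannot be normalized")
    logged = {c: np.log2(arr.astype(float) + pseudocount) for c, arr in track.data.items()}
    flat = np.concatenate([v[::stride] for v in logged.values()])
    mu = float(flat.mean())
    sd = float(flat.std())
    if sd == 0:
        warnings.warn("constant track: Z-scores are all zero", stacklevel=2)
        return NormalizedTrack(
            {c: np.zeros_like(v) for c, v in logged.items()},
            raw=track, scheme="mnase-log2-z", background_mean=mu, background_sd=sd,
            sample=track.sample, genotype=track.genotype, assay=track.assay,
        )
    return NormalizedTrack(
        {c: (v - mu) / sd for c, v in logged.items()},
        raw=track, scheme="mnase-log2-z", background_mean=mu, background_sd=sd,
        sample=track.sample, genotype=track.genotype, assay=track.assay,
    )


def peak_mask(
    peaks: Iterable[GenomicInterval], chrom_lengths: dict[str, int]
) -> dict[str, np.ndarray]:
    """Boolean per-bp mask, True inside any peak."""
    mask = {c: np.zeros(n, dtype=bool) for c, n in chrom_lengths.items()}
    for iv in peaks:
        if iv.chrom in mask:
            mask[iv.chrom][iv.start : iv.end] = True
    return mask


def normalize_chip(
    track: CoverageTrack,
    combined_peaks: Sequence[GenomicInterval] = (),
    stride: int = 1,
) -> NormalizedTrack:
    """Median-scale then Z-score against the out-of-peak background.

    The genome-wide median (zero positions included) removes depth; the
    Z-score is fitted on positions outside every combined peak, so the
    result is exactly invariant to uniform depth rescaling.
    """
    median = float(np.median(track.concatenated()))
    if median == 0:
        raise ValueError("genome-wide median coverage is zero")
    scaled = {c: arr.astype(float) / median for c, arr in track.data.items()}
    mask = peak_mask(combined_peaks, track.chrom_lengths())
    outside = np.concatenate(
        [scaled[c][~mask[c]][::stride] for c in scaled if (~mask[c]).any()]
        or [np.empty(0)]
    )
    if outside.size == 0:
        raise ValueError("combined peaks cover the entire genome")
    mu = float(outside.mean())
    sd = float(outside.std())
    if sd == 0:
        raise ValueError("zero background variance outside peaks")
    intervals = [iv for iv in combined_peaks]
    return NormalizedTrack(
        {c: (v - mu) / sd for c, v in scaled.items()},
        raw=track, scheme="chip-median-z", background_mean=mu, background_sd=sd,
        excluded_regions=intervals,
        sample=track.sample, genotype=track.genotype, assay=track.assay,
    )


def log2_ratio_track(
    chip: CoverageTrack, control: CoverageTrack, pseudocount: float = 1.0
) -> CoverageTrack:
    """Per-bp log2((chip + pc) / (control + pc)) after scaling both tracks
    to equal total mass."""
    scale = chip.total() / control.total() if control.total() else 1.0
    data = {
        c: np.log2((chip.data[c] + pseudocount) / (control.data[c] * scale + pseudocount))
        for c in chip.data
    }
    out = CoverageTrack(data, sample=chip.sample, genotype=chip.genotype,
                        assay=chip.assay, normalized=True)
    return out


def zscore_outside_peaks(
    track: CoverageTrack, peaks: Sequence[GenomicInterval], stride: int = 1
) -> NormalizedTrack:
    """Z-score an (already ratio/log) track using out-of-peak mean and sd."""
    mask = peak_mask(peaks, track.chrom_lengths())
    outside = np.concatenate([track.data[c][~mask[c]][::stride] for c in track.data])
    if outside.size == 0:
        raise ValueError("peaks cover the entire genome")
    mu, sd = float(outside.mean()), float(outside.std())
    if sd == 0:
        raise ValueError("zero background variance")
    return NormalizedTrack(
        {c: (v - mu) / sd for c, v in track.data.items()},
        raw=None, scheme="log2ratio-z", background_mean=mu, background_sd=sd,
        excluded_regions=list(peaks),
        sample=track.sample, genotype=track.genotype, assay=track.assay,
    )
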
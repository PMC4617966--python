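"""Peak calling and the replicate-consistency peak-set algebra.

The simplified caller thresholds a Poisson upper-tail p-value of ChIP
counts against a depth-matched local/global input expectation — a stand-in
adequate for synthetic data; externally called narrowPeak files can be
dropped in anywhere a PeakSet is accepted.

"Combined peaks" are peaks called on pooled replicates that are supported
by at least 1 bp of overlap with a peak in each individual replicate.
"Enriched" peaks additionally show ChIP above input near the summit on the
normalized scale.  The union of enriched combined peak sets from two
genotypes defines the regions tested for differential binding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from pionuc.intervals import CoverageTrack, GenomicInterval, Peak, sort_peaks
from pionuc.signal import NormalizedTrack


@dataclass
class PeakSet:
    peaks: list[Peak]
    sample: str = ""
    caller: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.peaks = sort_peaks(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]


class IntervalIndex:
    """Overlap queries against a fixed interval set in O(log n)."""

    def __init__(self, intervals: Iterable[GenomicInterval]) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._starts: dict[str, np.ndarray] = {}
        self._cummax_end: dict[str, np.ndarray] = {}
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            arr = np.array(pairs, dtype=np.int64)
            self._starts[chrom] = arr[:, 0]
            self._cummax_end[chrom] = np.maximum.accumulate(arr[:, 1])

    def overlaps_any(self, iv: GenomicInterval) -> bool:
        starts = self._starts.get(iv.chrom)
        if starts is None:
            return False
        i = int(np.searchsorted(starts, iv.end, side="left"))
        return i > 0 and int(self._cummax_end[iv.chrom][i - 1]) > iv.start


def _runs_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    edges = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def _local_mean(arr: np.ndarray, window: int) -> np.ndarray:
    cs = np.concatenate(([0.0], np.cumsum(arr, dtype=float)))
    half = window // 2
    n = arr.size
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + window - half, 0, n)
    return (cs[hi] - cs[lo]) / np.maximum(hi - lo, 1)


def call_peaks_simple(
    chip: CoverageTrack,
    control: CoverageTrack,
    p_cutoff: float = 1e-5,
    local_window: int = 1000,
    merge_dist: int = 100,
    sample: str = "",
) -> PeakSet:
    """Poisson-enrichment peak calling on raw coverage.

    The expected count per bp is the larger of the local (``local_window``)
    and global input mean, scaled to ChIP depth.  Contiguous significant
    runs closer than ``merge_dist`` are merged; the summit is the leftmost
    maximum of ChIP coverage within the run.
    """
    depth_ratio = chip.total() / control.total() if control.total() > 0 else 1.0
    peaks: list[Peak] = []
    k = 0
    for chrom in chip.data:
        c = chip.data[chrom].astype(float)
        b = control.data[chrom].astype(float)
        lam = np.maximum(_local_mean(b, local_window), b.mean()) * depth_ratio
        lam = np.maximum(lam, 1e-9)
        pvals = stats.poisson.sf(c - 1, lam)
        runs = _runs_from_mask(pvals < p_cutoff)
        # merge runs separated by < merge_dist
        merged: list[list[int]] = []
        for s, e in runs:
            if merged and s - merged[-1][1] < merge_dist:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for s, e in merged:
            summit = s + int(np.argmax(c[s:e]))
            score = float(-np.log10(max(pvals[s:e].min(), 1e-300)))
            k += 1
            peaks.append(Peak(GenomicInterval(chrom, s, e), summit, f"peak_{k}", score))
    return PeakSet(peaks, sample=sample, caller="poisson-simple")


def combine_replicate_peaks(combined: PeakSet, rep1: PeakSet, rep2: PeakSet) -> PeakSet:
    """Peaks from the pooled-replicate set supported (>= 1 bp overlap) by
    both individual replicate sets."""
    idx1 = IntervalIndex(rep1.intervals())
    idx2 = IntervalIndex(rep2.intervals())
    kept = [
        p for p in combined
        if idx1.overlaps_any(p.interval) and idx2.overlaps_any(p.interval)
    ]
    return PeakSet(kept, sample=combined.sample, caller=combined.caller,
                   provenance={"filter": "replicate-consistent"})


def _summit_window(p: Peak, window: int) -> tuple[int, int]:
    """[lo, hi) around the summit, or the whole peak if it is shorter than
    2*window."""
    if len(p.interval) < 2 * window:
        return p.start, p.end
    return p.summit - window, p.summit + window + 1


def filter_enriched_peaks(
    peaks: PeakSet,
    chip_norm: NormalizedTrack,
    input_norm: NormalizedTrack,
    excluded_chroms: Iterable[str] = (),
    window: int = 100,
) -> PeakSet:
    """Drop peaks on excluded chromosomes and peaks whose mean normalized
    ChIP falls below mean normalized input around the summit."""
    excl = set(excluded_chroms)
    kept = []
    for p in peaks:
        if p.chrom in excl:
            continue
        lo, hi = _summit_window(p, window)
        if chip_norm.window_mean(p.chrom, lo, hi) >= input_norm.window_mean(p.chrom, lo, hi):
            kept.append(p)
    return PeakSet(kept, sample=peaks.sample, caller=peaks.caller,
                   provenance={"filter": "enriched"})


def zscore_filter_peaks(
    peaks: PeakSet,
    ratio_z: NormalizedTrack,
    cutoff: float = 1.6445,
    window: int = 100,
    excluded_chroms: Iterable[str] = (),
) -> PeakSet:
    """Retain peaks whose summit-region mean of the Z-scored log2(ChIP/input)
    track reaches the cutoff (Z >= 1.6445 corresponds to one-sided P < 0.05).

    The summit region is summit +/- ``window`` bp, or the whole peak if it
    is shorter than 2*window.
    """
    excl = set(excluded_chroms)
    kept = []
    for p in peaks:
        if p.chrom in excl:
            continue
        lo, hi = _summit_window(p, window)
        if ratio_z.window_mean(p.chrom, lo, hi) >= cutoff:
            kept.append(p)
    return PeakSet(kept, sample=peaks.sample, caller=peaks.caller,
                   provenance={"filter": f"zscore>={cutoff}"})


def union_regions(set_a: PeakSet, set_b: PeakSet) -> PeakSet:
    """Interval union of two peak sets (overlapping intervals merged).

    Each merged region inherits summit and name from its highest-scoring
    contributor, so the summit always marks the strongest binding event.
    """
    all_peaks = list(set_a) + list(set_b)
    by_chrom: dict[str, list[Peak]] = {}
    for p in all_peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    merged: list[Peak] = []
    for chrom in sorted(by_chrom):
        group: list[Peak] = []
        end = -1
        for p in sorted(by_chrom[chrom], key=lambda q: (q.start, q.end)):
            if group and p.start < end:
                group.append(p)
                end = max(end, p.end)
            else:
                if group:
                    merged.append(_merge_group(group, end))
                group = [p]
                end = p.end
        if group:
            merged.append(_merge_group(group, end))
    return PeakSet(merged, caller="union", provenance={
        "sources": [set_a.sample, set_b.sample]})


def _merge_group(group: list[Peak], end: int) -> Peak:
    best = max(group, key=lambda p: p.score)
    start = min(p.start for p in group)
    return Peak(GenomicInterval(best.chrom, start, end), best.summit, best.name, best.score)
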
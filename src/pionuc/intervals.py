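"""Genomic interval algebra and the basic domain containers.

Coordinates are 0-based half-open throughout (BED-native).  Two regions are
considered overlapping if they share at least 1 bp.  Peaks are unstranded;
summits are stored as absolute genomic positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Peak:
    """An unstranded peak with a single-bp summit.

    The summit is absolute (not an offset from start, as in narrowPeak
    files); converters live in :mod:`pionuc.io`.
    """

    interval: GenomicInterval
    summit: int
    name: str = ""
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside [{self.interval.start}, "
                f"{self.interval.end}) on {self.interval.chrom}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass
class TSSSet:
    """Transcription start sites: (chrom, position, strand, gene id)."""

    sites: list[tuple[str, int, str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sites)

    def positions_on(self, chrom: str) -> np.ndarray:
        return np.array(
            sorted(pos for c, pos, _, _ in self.sites if c == chrom), dtype=np.int64
        )


def intervals_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share at least 1 bp."""
    if a.chrom != b.chrom:
        return False
    return max(a.start, b.start) < min(a.end, b.end)


def interval_distance(a: GenomicInterval, position: int) -> int:
    """Distance from a point to the closer interval boundary (0 if inside)."""
    if position < a.start:
        return a.start - position
    if position >= a.end:
        return position - (a.end - 1)
    return 0


def classify_tss_proximity(
    peak: Peak, tss: TSSSet, threshold: int = 1000
) -> str:
    """Label a peak ``"non-TSS"`` iff both boundaries are > threshold bp from
    every TSS, else ``"TSS-proximal"``.

    Distance is measured from the nearest peak boundary (a TSS inside the
    peak has distance 0).
    """
    if len(tss) == 0:
        raise ValueError("TSS set is empty; provide a TSS annotation")
    positions = tss.positions_on(peak.chrom)
    if positions.size == 0:
        return "non-TSS"
    # distance from interval [start, end) to each TSS position
    d_left = peak.start - positions  # >0 when TSS left of peak
    d_right = positions - (peak.end - 1)  # >0 when TSS right of peak
    dist = np.maximum(np.maximum(d_left, d_right), 0)
    return "non-TSS" if int(dist.min()) > threshold else "TSS-proximal"


class CoverageTrack:
    """Per-chromosome numeric signal at 1 bp resolution.

    Parameters
    ----------
    data
        Mapping chromosome name -> 1D numpy array, one value per bp.
    sample, genotype, assay
        Free-text metadata carried through the pipeline.
    normalized
        Whether the values are on a normalized (Z-score) scale.
    """

    def __init__(
        self,
        data: dict[str, np.ndarray],
        sample: str = "",
        genotype: str = "",
        assay: str = "",
        normalized: bool = False,
    ) -> None:
        self.data = {c: np.asarray(v) for c, v in data.items()}
        self.sample = sample
        self.genotype = genotype
        self.assay = assay
        self.normalized = normalized
        if not normalized:
            for chrom, arr in self.data.items():
                if arr.size and arr.min() < 0:
                    raise ValueError(f"raw track has negative values on {chrom}")

    @property
    def chroms(self) -> list[str]:
        return list(self.data)

    def chrom_lengths(self) -> dict[str, int]:
        return {c: int(v.size) for c, v in self.data.items()}

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))

    def concatenated(self, exclude: Iterable[str] = ()) -> np.ndarray:
        """All per-bp values over non-excluded chromosomes, one flat array."""
        excl = set(exclude)
        parts = [v for c, v in self.data.items() if c not in excl]
        if not parts:
            raise ValueError("no chromosomes left after exclusion")
        return np.concatenate(parts)

    def window_mean(self, chrom: str, start: int, end: int) -> float:
        arr = self.data[chrom]
        lo, hi = max(start, 0), min(end, arr.size)
        if hi <= lo:
            return float("nan")
        return float(arr[lo:hi].mean())

    def like(self, data: dict[str, np.ndarray], normalized: bool | None = None):
        """A new track with the same metadata but different values."""
        return CoverageTrack(
            data,
            sample=self.sample,
            genotype=self.genotype,
            assay=self.assay,
            normalized=self.normalized if normalized is None else normalized,
        )


def sort_peaks(peaks: Sequence[Peak]) -> list[Peak]:
    """Sort by (chrom, start, end) and drop exact duplicate intervals."""
    seen: set[tuple[str, int, int]] = set()
    out: list[Peak] = []
    for p in sorted(peaks, key=lambda p: (p.chrom, p.start, p.end)):
        key = (p.chrom, p.start, p.end)
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out
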
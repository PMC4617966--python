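"""Rank-and-bin enrichment machinery.

Regions are ranked by a per-region statistic (pioneer summit reads
descending, wild-type MNase ascending, or delta-MNase descending), cut into
sequential bins of fixed size (remainder appended to the last bin), and for
each bin the number of members overlapping an annotation (early enhancers,
HOT regions, patterning-factor peaks) is compared with the expected count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from pionuc.intervals import GenomicInterval, Peak
from pionuc.peaks import IntervalIndex


@dataclass
class RankedBins:
    mode: str
    order: list[str]  # region ids, best rank first
    bins: list[list[str]]  # partition of `order` into sequential bins

    @property
    def n_bins(self) -> int:
        return len(self.bins)


def rank_and_bin(
    region_ids: Sequence[str],
    values: Sequence[float],
    ascending: bool = False,
    bin_size: int = 500,
    mode: str = "",
) -> RankedBins:
    """Stable sort by ``values`` then cut into bins of ``bin_size``.

    Ties keep input order (stable sort).  The remainder after the last full
    bin is appended to the last bin, so all bins have size ``bin_size``
    except possibly the last (e.g. 6008 regions at bin size 500 give 12
    bins, the last with 508 regions).
    """
    ids = list(region_ids)
    v = np.asarray(values, dtype=float)
    if v.size != len(ids):
        raise ValueError("region_ids and values differ in length")
    order_idx = np.argsort(v if ascending else -v, kind="stable")
    order = [ids[i] for i in order_idx]
    n = len(order)
    n_bins = max(1, n // bin_size)
    bins = [order[i * bin_size : (i + 1) * bin_size] for i in range(n_bins - 1)]
    bins.append(order[(n_bins - 1) * bin_size :])
    return RankedBins(mode, order, bins)


@dataclass
class BinEnrichment:
    bin_index: int
    annotation: str
    observed: int
    expected: float
    enrichment: float  # observed / expected; NaN when undefined


def overlap_enrichment(
    bins: RankedBins,
    regions_by_id: dict[str, GenomicInterval],
    annotation: Sequence[GenomicInterval],
    annotation_name: str = "annotation",
    expected_mode: str = "per-bin",
) -> list[BinEnrichment]:
    """Observed over expected count of bin members overlapping (>= 1 bp)
    any annotation interval.

    expected_mode "per-bin": expected is the unweighted across-bin average
    of observed counts.  expected_mode "per-region": expected is the overall
    overlap rate times the bin size, which makes the size-weighted mean of
    enrichments across bins exactly 1.
    """
    if expected_mode not in ("per-bin", "per-region"):
        raise ValueError(f"unknown expected_mode {expected_mode!r}")
    index = IntervalIndex(annotation)
    observed = []
    for members in bins.bins:
        observed.append(sum(1 for rid in members if index.overlaps_any(regions_by_id[rid])))
    observed_arr = np.array(observed, dtype=float)
    total = observed_arr.sum()
    out = []
    for b, obs in enumerate(observed):
        if total == 0:
            expected, enr = 0.0, float("nan")
        elif expected_mode == "per-bin":
            expected = float(observed_arr.mean())
            enr = obs / expected
        else:
            expected = total * len(bins.bins[b]) / len(bins.order)
            enr = obs / expected
        out.append(BinEnrichment(b, annotation_name, int(obs), expected, enr))
    return out


def hotness_of_region(
    region: GenomicInterval, hot_regions: Sequence[tuple[GenomicInterval, int]]
) -> int:
    """Highest hotness (number of bound TFs) among overlapping HOT-annotation
    intervals; 0 when none overlaps."""
    best = 0
    for iv, hotness in hot_regions:
        if iv.chrom == region.chrom and max(iv.start, region.start) < min(iv.end, region.end):
            best = max(best, hotness)
    return best


def hotness_per_peak(
    peaks: Sequence[Peak], hot_regions: Sequence[tuple[GenomicInterval, int]]
) -> np.ndarray:
    index: dict[str, list[tuple[int, int, int]]] = {}
    for iv, h in hot_regions:
        index.setdefault(iv.chrom, []).append((iv.start, iv.end, h))
    out = np.zeros(len(peaks), dtype=int)
    for i, p in enumerate(peaks):
        for s, e, h in index.get(p.chrom, ()):
            if max(s, p.start) < min(e, p.end):
                out[i] = max(out[i], h)
    return out


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "pearson",
    permutations: int = 10000,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Correlation with a two-sided permutation p-value.

    Returns (r, p_permutation, p_analytic).  The permutation p uses the
    add-one estimator (1 + hits) / (permutations + 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    if method == "pearson":
        r, p_analytic = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p_analytic = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    xc = (x - x.mean()) / x.std()
    yc = (y - y.mean()) / y.std()
    n = x.size
    hits = 0
    # batched permutation of y against fixed x
    batch = max(1, min(permutations, 2000))
    done = 0
    while done < permutations:
        b = min(batch, permutations - done)
        perm = np.stack([rng.permutation(yc) for _ in range(b)])
        r_perm = perm @ xc / n
        hits += int((np.abs(r_perm) >= abs(r) - 1e-12).sum())
        done += b
    p_perm = (1 + hits) / (permutations + 1)
    return float(r), float(p_perm), float(p_analytic)
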
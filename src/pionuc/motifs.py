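"""Degenerate (IUPAC) motif scanning and motif-configuration analyses.

The patterning-factor motifs are long degenerate decamers/dodecamers
(GGGWWWWCYS family); the pioneer-factor motifs are the CAGGTAG-family
heptamers.  Scanning matches the pattern on the forward strand and the
reverse-complemented pattern on the forward sequence (reported as '-'
strand); a palindromic pattern matching both ways at the same interval
yields a single hit.

The in-silico motif "mutation" replaces every C with T and every G with A
inside hit footprints, the substitution known to abolish pioneer-factor
binding while preserving AT content.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from pionuc.intervals import Peak

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: Pioneer-factor heptamer set (TAGteam family), overridable everywhere.
PIONEER_MOTIFS = (
    "CAGGTAG", "CAGGTAA", "CAGGCAG", "CAGGTAT",
    "CAGGTAC", "TAGGTAG", "CAGGCAA", "CAGGTCG",
)

#: Patterning-factor degenerate motifs.
PATTERNING_MOTIFS = ("GGGWWWWCYS", "GGGWDWWWCYS", "GGGWWWWCCM", "GGGDWDWWWCCM")


def reverse_complement_pattern(pattern: str) -> str:
    return pattern.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class MotifHit:
    chrom: str
    start: int
    end: int
    strand: str
    motif: str

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def _encode(sequence: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _pattern_table(pattern: str) -> np.ndarray:
    """(len, 5) boolean table: table[i, code] = base allowed at position i.

    Code 4 (N/unknown base in the *sequence*) never matches.
    """
    table = np.zeros((len(pattern), 5), dtype=bool)
    for i, ch in enumerate(pattern.upper()):
        if ch not in IUPAC:
            raise ValueError(f"illegal IUPAC code {ch!r} in pattern {pattern!r}")
        for base in IUPAC[ch]:
            table[i, "ACGT".index(base)] = True
    return table


def _match_positions(codes: np.ndarray, pattern: str) -> np.ndarray:
    m = len(pattern)
    table = _pattern_table(pattern)  # validates codes even when no window fits
    if codes.size < m:
        return np.empty(0, dtype=np.int64)
    mask = np.ones(codes.size - m + 1, dtype=bool)
    for i in range(m):
        mask &= table[i][codes[i : codes.size - m + 1 + i]]
    return np.flatnonzero(mask).astype(np.int64)


def scan_iupac(
    sequence: str,
    motifs: Iterable[str] = PIONEER_MOTIFS,
    both_strands: bool = True,
    chrom: str = "",
    offset: int = 0,
) -> list[MotifHit]:
    """All matches of each degenerate pattern in ``sequence``.

    Reverse-strand hits are located by scanning the forward sequence with
    the reverse-complemented pattern; a pattern matching both strands over
    the same interval is reported once (forward strand wins).
    """
    codes = _encode(sequence)
    hits: dict[tuple[int, int, str], MotifHit] = {}
    for pattern in motifs:
        m = len(pattern)
        for pos in _match_positions(codes, pattern):
            key = (int(pos), int(pos) + m, pattern)
            hits[key] = MotifHit(chrom, offset + int(pos), offset + int(pos) + m, "+", pattern)
        if both_strands:
            rc = reverse_complement_pattern(pattern)
            for pos in _match_positions(codes, rc):
                key = (int(pos), int(pos) + m, pattern)
                if key not in hits:  # palindromic double count collapses
                    hits[key] = MotifHit(
                        chrom, offset + int(pos), offset + int(pos) + m, "-", pattern
                    )
    return sorted(hits.values())


def scan_genome(
    genome: dict[str, str], motifs: Iterable[str] = PIONEER_MOTIFS, both_strands: bool = True
) -> list[MotifHit]:
    out: list[MotifHit] = []
    for chrom, seq in genome.items():
        out.extend(scan_iupac(seq, motifs, both_strands, chrom=chrom))
    return out


def _summit_window(peak: Peak, window: int) -> tuple[int, int]:
    """[summit - window, summit + window] inclusive, or the whole region if
    the peak is shorter than 2*window."""
    if len(peak.interval) < 2 * window:
        return peak.start, peak.end - 1
    return peak.summit - window, peak.summit + window


def _hits_in_window(hits: Sequence[MotifHit], chrom: str, lo: int, hi: int) -> int:
    return sum(1 for h in hits if h.chrom == chrom and lo <= h.midpoint <= hi)


def count_motifs_near_summit(
    peak: Peak, hits: Sequence[MotifHit], window: int = 125
) -> int:
    """Number of hits whose midpoint lies within ``window`` bp (inclusive)
    of the peak summit."""
    return sum(
        1
        for h in hits
        if h.chrom == peak.chrom and abs(h.midpoint - peak.summit) <= window
    )


def motif_density_enrichment(
    peaks: Sequence[Peak],
    hits: Sequence[MotifHit],
    genome_length: int,
    window: int = 250,
) -> float:
    """Mean per-bp motif density in summit windows over the genome-wide
    per-bp density.

    The window is summit +/- ``window`` bp, or the entire bound region for
    peaks shorter than ``2 * window``.  Genome density is total hit count
    over total genome length.
    """
    if not peaks:
        raise ValueError("no peaks given")
    genome_density = len(hits) / genome_length
    if genome_density == 0:
        raise ValueError("zero genome-wide motif density")
    by_chrom: dict[str, list[MotifHit]] = {}
    for h in hits:
        by_chrom.setdefault(h.chrom, []).append(h)
    densities = []
    for p in peaks:
        lo, hi = _summit_window(p, window)
        n = _hits_in_window(by_chrom.get(p.chrom, ()), p.chrom, lo, hi)
        densities.append(n / (hi - lo + 1))
    return float(np.mean(densities)) / genome_density


@dataclass(frozen=True)
class MotifConfiguration:
    """Central-vs-flanking classification of motifs around a summit.

    central: >= 2 hits within the central window and none further out
    within the flank window; flanking: exactly 1 central hit plus >= 1
    flank hit; everything else: other.
    """

    region: str
    n_central: int
    n_flank: int
    label: str


def classify_motif_configuration(
    peak: Peak,
    hits: Sequence[MotifHit],
    central_window: int = 125,
    flank_window: int = 400,
) -> MotifConfiguration:
    n_central = 0
    n_flank = 0
    for h in hits:
        if h.chrom != peak.chrom:
            continue
        d = abs(h.midpoint - peak.summit)
        if d <= central_window:
            n_central += 1
        elif d <= flank_window:
            n_flank += 1
    if n_central >= 2 and n_flank == 0:
        label = "central"
    elif n_central == 1 and n_flank >= 1:
        label = "flanking"
    else:
        label = "other"
    return MotifConfiguration(peak.name, n_central, n_flank, label)


_MUTATE = str.maketrans("CG", "TA")


def mutate_motifs_in_silico(sequence: str, hits: Sequence[MotifHit]) -> str:
    """Disrupt motifs by C->T and G->A within hit footprints.

    Overlapping hits are applied once (union of intervals); the operation
    is idempotent.  Positions outside every hit are untouched.
    """
    if not hits:
        return sequence
    out = list(sequence)
    covered = np.zeros(len(sequence), dtype=bool)
    for h in hits:
        if h.start < 0 or h.end > len(sequence):
            raise ValueError(f"hit [{h.start},{h.end}) outside sequence of length {len(sequence)}")
        covered[h.start : h.end] = True
    for pos in np.flatnonzero(covered):
        out[pos] = out[pos].translate(_MUTATE)
    return "".join(out)
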
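"""Readers and writers for the plain-text genomics formats the pipeline uses.

FASTA via Biopython; BED6 / narrowPeak-like 10-column BED / bedGraph as thin
tab-separated parsers with line-number error reporting.  narrowPeak summits
are stored on disk as offsets from the interval start and converted to
absolute positions on load.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from pionuc.intervals import CoverageTrack, GenomicInterval, Peak, TSSSet


class FormatError(ValueError):
    """Malformed line in a genomics text file."""

    def __init__(self, path, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, exclude_chroms: Iterable[str] = ()) -> dict[str, str]:
    """Load a genome as {chrom: uppercase sequence}, dropping excluded names."""
    excl = set(exclude_chroms)
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(path), "fasta")
        if rec.id not in excl
    }


def write_fasta(path, genome: dict[str, str], width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# BED6 (chrom start end name score strand)


def _parse_fields(path, lineno: int, line: str, min_fields: int) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < min_fields:
        raise FormatError(path, lineno, f"expected >= {min_fields} fields, got {len(fields)}")
    return fields


def read_bed(path, exclude_chroms: Iterable[str] = ()) -> list[GenomicInterval]:
    excl = set(exclude_chroms)
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#", "browser")):
                continue
            f = _parse_fields(path, lineno, line, 3)
            try:
                iv = GenomicInterval(f[0], int(f[1]), int(f[2]))
            except ValueError as exc:
                raise FormatError(path, lineno, str(exc)) from exc
            if iv.chrom not in excl:
                out.append(iv)
    return out


def read_bed6(
    path, exclude_chroms: Iterable[str] = ()
) -> list[tuple[GenomicInterval, str, float, str]]:
    """BED6 rows as (interval, name, score, strand)."""
    excl = set(exclude_chroms)
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#", "browser")):
                continue
            f = _parse_fields(path, lineno, line, 3)
            try:
                iv = GenomicInterval(f[0], int(f[1]), int(f[2]))
                name = f[3] if len(f) > 3 else "."
                score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
                strand = f[5] if len(f) > 5 else "."
            except ValueError as exc:
                raise FormatError(path, lineno, str(exc)) from exc
            if iv.chrom not in excl:
                out.append((iv, name, score, strand))
    return out


def write_bed6(path, rows: Iterable[tuple[GenomicInterval, str, float, str]]) -> None:
    with open(path, "w") as fh:
        for iv, name, score, strand in rows:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{strand}\n")


def write_intervals(path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# narrowPeak-like 10-column BED; column 10 is summit offset from start


def read_narrowpeak(path, exclude_chroms: Iterable[str] = ()) -> list[Peak]:
    excl = set(exclude_chroms)
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            f = _parse_fields(path, lineno, line, 10)
            try:
                iv = GenomicInterval(f[0], int(f[1]), int(f[2]))
                offset = int(f[9])
                if offset < 0:  # missing summit convention: use midpoint
                    offset = len(iv) // 2
                peak = Peak(iv, summit=iv.start + offset, name=f[3], score=float(f[4]))
            except ValueError as exc:
                raise FormatError(path, lineno, str(exc)) from exc
            if peak.chrom not in excl:
                peaks.append(peak)
    return peaks


def write_narrowpeak(path, peaks: Sequence[Peak]) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name or '.'}\t{p.score:g}\t.\t"
                f"0\t-1\t-1\t{p.summit - p.start}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph <-> per-bp arrays


def read_bedgraph(
    path, chrom_lengths: dict[str, int], exclude_chroms: Iterable[str] = ()
) -> CoverageTrack:
    """Expand run-length bedGraph records into per-bp arrays."""
    excl = set(exclude_chroms)
    data = {c: np.zeros(n, dtype=float) for c, n in chrom_lengths.items() if c not in excl}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            f = _parse_fields(path, lineno, line, 4)
            chrom = f[0]
            if chrom in excl:
                continue
            if chrom not in data:
                raise FormatError(path, lineno, f"unknown chromosome {chrom!r}")
            try:
                start, end, value = int(f[1]), int(f[2]), float(f[3])
            except ValueError as exc:
                raise FormatError(path, lineno, str(exc)) from exc
            if not 0 <= start < end <= data[chrom].size:
                raise FormatError(path, lineno, f"interval [{start},{end}) out of bounds")
            data[chrom][start:end] = value
    return CoverageTrack(data, normalized=True)


def write_bedgraph(path, track: CoverageTrack) -> None:
    """Run-length encode per-bp arrays; zero runs are written too, so the
    round trip is lossless."""
    with open(path, "w") as fh:
        for chrom, arr in track.data.items():
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]:.6g}\n")


# ---------------------------------------------------------------------------
# Fragments and TSS


def read_fragments(path, exclude_chroms: Iterable[str] = ()) -> dict[str, np.ndarray]:
    """Fragment BED -> {chrom: (n, 2) int array of [start, end)} sorted by start."""
    excl = set(exclude_chroms)
    acc: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            f = _parse_fields(path, lineno, line, 3)
            if f[0] in excl:
                continue
            try:
                s, e = int(f[1]), int(f[2])
            except ValueError as exc:
                raise FormatError(path, lineno, str(exc)) from exc
            if e <= s or s < 0:
                raise FormatError(path, lineno, f"bad fragment [{s},{e})")
            acc.setdefault(f[0], []).append((s, e))
    return {
        c: np.array(sorted(v), dtype=np.int64).reshape(-1, 2) for c, v in acc.items()
    }


def write_fragments(path, fragments: dict[str, np.ndarray]) -> None:
    with open(path, "w") as fh:
        for chrom in fragments:
            for s, e in fragments[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")


def read_tss_bed(path, exclude_chroms: Iterable[str] = ()) -> TSSSet:
    """TSS annotation: BED6 where start is the TSS position (1 bp features
    or wider; the start of the interval is taken as the site)."""
    rows = read_bed6(path, exclude_chroms)
    return TSSSet([(iv.chrom, iv.start, strand, name) for iv, name, _, strand in rows])


def write_tss_bed(path, tss: TSSSet) -> None:
    write_bed6(
        path,
        [
            (GenomicInterval(c, p, p + 1), gene, 0.0, strand)
            for c, p, strand, gene in tss.sites
        ],
    )
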
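"""Readers and writers for the on-disk formats the pipeline touches.

Coordinate convention: 0-based, half-open intervals everywhere (BED native).
A printed 1-based position converts by subtracting 1 from the start only.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CageTag:
    """One collapsed CAGE 5'-end position with its tag count."""

    chrom: str
    pos: int
    strand: str
    count: int

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError("tag position must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError("tag strand must be + or -")
        if self.count < 1:
            raise ValueError(f"tag count must be >= 1, got {self.count}")


class ConservationTrack:
    """Per-chromosome sparse map from position to conservation score.

    Uncovered positions score 0. Holds (starts, ends, values) arrays per
    chromosome, sorted by start, non-overlapping.
    """

    def __init__(self, blocks: Optional[Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]] = None,
                 enabled: bool = True):
        self.blocks = blocks if blocks is not None else {}
        #: False when no conservation file was supplied; the model branch
        #: driven by this track is then disabled.
        self.enabled = enabled

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base scores over [start, end); uncovered positions are 0."""
        out = np.zeros(end - start, dtype=np.float64)
        if chrom not in self.blocks:
            return out
        starts, ends, vals = self.blocks[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            s = max(int(starts[i]), start)
            e = min(int(ends[i]), end)
            if e > s:
                out[s - start:e - start] = vals[i]
        return out

    @classmethod
    def empty(cls) -> "ConservationTrack":
        return cls({}, enabled=False)


def read_fasta(path: str) -> Dict[str, str]:
    """Read a FASTA file into a chrom -> uppercase sequence map.

    Ambiguity codes are preserved (uppercased). Raises :class:`FormatError`
    on an empty file or a malformed header, naming the offending line.
    """
    genome: Dict[str, str] = {}
    name = None
    parts: List[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    genome[name] = "".join(parts).upper()
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                parts = []
            else:
                if name is None:
                    raise FormatError(
                        f"{path}:{lineno}: sequence before any FASTA header"
                    )
                parts.append(line)
    if name is not None:
        genome[name] = "".join(parts).upper()
    if not genome:
        raise FormatError(f"{path}: empty FASTA file")
    return genome


def write_fasta(genome: Dict[str, str], path: str, width: int = 60) -> None:
    """Write a chrom -> sequence map as wrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_ctss(path: str, four_column: bool = False) -> List[CageTag]:
    """Read a ctss-style BED of collapsed CAGE 5'-end tag counts.

    Default dialect is 6 columns (chrom, start, start+1, name, count,
    strand) with the tag count in column 5, the FANTOM convention.
    ``four_column=True`` accepts the alternative compact dialect of one tag
    per line: chrom, 0-based position, strand, count.
    """
    tags: List[CageTag] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            try:
                if four_column:
                    if len(f) < 4:
                        raise FormatError(
                            f"{path}:{lineno}: expected 4 columns, got {len(f)}"
                        )
                    chrom, pos, strand, count = f[0], int(f[1]), f[2], int(f[3])
                else:
                    if len(f) < 6:
                        raise FormatError(
                            f"{path}:{lineno}: expected 6 columns, got {len(f)}"
                        )
                    chrom, start, end = f[0], int(f[1]), int(f[2])
                    count, strand = int(f[4]), f[5]
                    if end != start + 1:
                        raise FormatError(
                            f"{path}:{lineno}: ctss interval must be 1 bp "
                            f"(end == start+1), got [{start}, {end})"
                        )
                    pos = start
                if count < 1:
                    raise FormatError(
                        f"{path}:{lineno}: tag count must be >= 1, got {count}"
                    )
                tags.append(CageTag(chrom, pos, strand, count))
            except ValueError as exc:
                if isinstance(exc, FormatError):
                    raise
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return tags


def sort_tags(tags: Sequence[CageTag]) -> List[CageTag]:
    """Sort tags by (chrom, pos, strand)."""
    return sorted(tags, key=lambda t: (t.chrom, t.pos, t.strand))


def read_intervals(path: str) -> List[GenomicInterval]:
    """Read a BED file (>= 3 columns) into GenomicIntervals.

    Strand is taken from column 6 when present, else '.'.
    """
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 3 BED columns, got {len(f)}"
                )
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start must be < end, got [{start}, {end})"
                )
            strand = f[5] if len(f) >= 6 and f[5] in ("+", "-") else "."
            out.append(GenomicInterval(f[0], start, end, strand))
    return out


def read_conservation(path: Optional[str]) -> ConservationTrack:
    """Read per-base conservation from bigWig or bedGraph.

    ``path=None`` (file not supplied) yields an empty, disabled track; the
    conservation branch of the model is then not used. Uncovered positions
    always score 0.
    """
    if path is None:
        return ConservationTrack.empty()
    if not os.path.exists(path):
        raise IOError(f"conservation file not found: {path}")
    if _looks_like_bigwig(path):
        return _read_bigwig(path)
    return _read_bedgraph(path)


def _looks_like_bigwig(path: str) -> bool:
    with open(path, "rb") as fh:
        magic = fh.read(4)
    return magic in (b"\x26\xfc\x8f\x88", b"\x88\x8f\xfc\x26")


def _read_bigwig(path: str) -> ConservationTrack:
    import pyBigWig  # deferred: optional binary-format dependency

    bw = pyBigWig.open(path)
    blocks: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    try:
        for chrom, length in bw.chroms().items():
            ivals = bw.intervals(chrom, 0, length)
            if not ivals:
                continue
            starts = np.array([iv[0] for iv in ivals], dtype=np.int64)
            ends = np.array([iv[1] for iv in ivals], dtype=np.int64)
            vals = np.array([iv[2] for iv in ivals], dtype=np.float64)
            blocks[chrom] = (starts, ends, vals)
    finally:
        bw.close()
    return ConservationTrack(blocks)


def _read_bedgraph(path: str) -> ConservationTrack:
    per_chrom: Dict[str, List[Tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) < 4:
                raise FormatError(
                    f"{path}:{lineno}: expected 4 bedGraph columns, got {len(f)}"
                )
            try:
                start, end, value = int(f[1]), int(f[2]), float(f[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            per_chrom.setdefault(f[0], []).append((start, end, value))
    blocks = {}
    for chrom, rows in per_chrom.items():
        rows.sort()
        blocks[chrom] = (
            np.array([r[0] for r in rows], dtype=np.int64),
            np.array([r[1] for r in rows], dtype=np.int64),
            np.array([r[2] for r in rows], dtype=np.float64),
        )
    return ConservationTrack(blocks)


def write_scored_bed(peaks, scores: Sequence[float], path: str) -> None:
    """Write peak representatives with model probabilities as BED6.

    One line per peak: the 1 bp representative interval, the probability at
    full precision in the score column, and the peak strand.
    """
    peaks = list(peaks)
    if len(peaks) != len(scores):
        raise ValueError(
            f"{len(peaks)} peaks but {len(scores)} scores"
        )
    for s in scores:
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"score {s} outside [0, 1]")
    with open(path, "w") as fh:
        for peak, s in zip(peaks, scores):
            fh.write(
                f"{peak.interval.chrom}\t{peak.representative}\t"
                f"{peak.representative + 1}\tpeak\t{float(s)!r}\t"
                f"{peak.interval.strand}\n"
            )


def read_bam_tags(path: str, min_mapq: int = 10) -> List[CageTag]:
    """Extract CAGE 5'-end tags from aligned reads (BAM/SAM adapter).

    The 5' end of a plus-strand alignment is its leftmost aligned base; of a
    minus-strand alignment its rightmost aligned base. Soft-clipped bases are
    excluded (pysam reference_start/reference_end already skip them). Reads
    below ``min_mapq`` are dropped, matching the default mapping-quality
    filter of 10.
    """
    import pysam  # deferred: only the optional alignment adapter needs it

    counts: Dict[Tuple[str, int, str], int] = {}
    save = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(path, check_sq=False) as bam:
            for read in bam:
                if read.is_unmapped or read.mapping_quality < min_mapq:
                    continue
                if read.is_reverse:
                    key = (read.reference_name, read.reference_end - 1, "-")
                else:
                    key = (read.reference_name, read.reference_start, "+")
                counts[key] = counts.get(key, 0) + 1
    finally:
        pysam.set_verbosity(save)
    return [
        CageTag(chrom, pos, strand, n)
        for (chrom, pos, strand), n in sorted(counts.items())
    ]
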
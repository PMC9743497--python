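"""CAGE peak calling: single-linkage tag clustering, TPM normalization,
expression filtering and representative selection.

Tags are grouped per (chromosome, strand) by single linkage along the
genome: two 5'-end positions belong to one peak iff their gap is at most
``cluster_distance`` bp, transitively. Expression is normalized to tags per
million (TPM) over the library of quality-passing tags, peaks below the TPM
cutoff are removed, and the position carrying the most 5'-tag ends within
each peak becomes its single-base representative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

from cagetss.io_formats import CageTag, GenomicInterval


@dataclass(frozen=True)
class CagePeak:
    """A clustered run of CAGE tags with expression and representative."""

    interval: GenomicInterval
    tag_count: int
    representative: int
    tpm: Optional[float] = None

    def __post_init__(self):
        if self.tag_count < 1:
            raise ValueError("peak tag_count must be >= 1")
        if not (self.interval.start <= self.representative < self.interval.end):
            raise ValueError(
                f"representative {self.representative} outside peak "
                f"[{self.interval.start}, {self.interval.end})"
            )
        if self.tpm is not None and self.tpm <= 0:
            raise ValueError("tpm must be positive")


@dataclass(frozen=True)
class PeakCallParams:
    """Peak-calling knobs: mapq >= 10, clustering gap <= 50 bp, tpm >= 1."""

    min_mapq: int = 10
    cluster_distance: int = 50
    min_tpm: float = 1.0

    def __post_init__(self):
        if self.min_mapq < 0 or self.cluster_distance < 0 or self.min_tpm < 0:
            raise ValueError("peak-calling parameters must be non-negative")


def _per_position_counts(tags: Sequence[CageTag]) -> Dict[Tuple[str, str], Dict[int, int]]:
    groups: Dict[Tuple[str, str], Dict[int, int]] = {}
    for t in tags:
        pos_counts = groups.setdefault((t.chrom, t.strand), {})
        pos_counts[t.pos] = pos_counts.get(t.pos, 0) + t.count
    return groups


def cluster_tags(tags: Sequence[CageTag], cluster_distance: int = 50) -> List[CagePeak]:
    """Single-linkage clustering of tag positions per (chrom, strand).

    Adjacent positions merge when their gap is <= ``cluster_distance``
    (inclusive). Opposite strands never merge. The peak interval spans
    [min pos, max pos + 1) and its representative is the arg-max position
    (leftmost on ties). Input order is irrelevant: tags are aggregated and
    sorted first.
    """
    peaks: List[CagePeak] = []
    for (chrom, strand), pos_counts in sorted(_per_position_counts(tags).items()):
        positions = sorted(pos_counts)
        run: List[int] = [positions[0]]
        for p in positions[1:]:
            if p - run[-1] <= cluster_distance:
                run.append(p)
            else:
                peaks.append(_finalize(chrom, strand, run, pos_counts))
                run = [p]
        peaks.append(_finalize(chrom, strand, run, pos_counts))
    return peaks


def _finalize(chrom: str, strand: str, run: List[int],
              pos_counts: Dict[int, int]) -> CagePeak:
    total = sum(pos_counts[p] for p in run)
    rep = max(run, key=lambda p: (pos_counts[p], -p))
    return CagePeak(
        interval=GenomicInterval(chrom, run[0], run[-1] + 1, strand),
        tag_count=total,
        representative=rep,
    )


def normalize_tpm(peaks: Sequence[CagePeak], library_size: int) -> List[CagePeak]:
    """Attach tags-per-million expression: tpm = count * 1e6 / library_size.

    ``library_size`` is the total number of quality-passing tags, which may
    exceed the sum of peak counts (normalization precedes filtering).
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    total = sum(p.tag_count for p in peaks)
    if library_size < total:
        raise ValueError(
            f"library_size {library_size} smaller than total peak tags {total}"
        )
    return [replace(p, tpm=p.tag_count * 1e6 / library_size) for p in peaks]


def filter_peaks(peaks: Sequence[CagePeak], min_tpm: float = 1.0) -> List[CagePeak]:
    """Keep peaks with tpm >= min_tpm, preserving order."""
    kept = []
    for p in peaks:
        if p.tpm is None:
            raise ValueError("filter_peaks requires tpm-normalized peaks")
        if p.tpm >= min_tpm:
            kept.append(p)
    return kept


def select_representative(peak: CagePeak, tags: Sequence[CageTag]) -> int:
    """Arg-max of per-position 5'-tag count within the peak.

    Ties break to the smallest genomic coordinate. ``tags`` must already be
    restricted to the peak's interval and strand.
    """
    counts: Dict[int, int] = {}
    for t in tags:
        if not (peak.interval.start <= t.pos < peak.interval.end):
            raise ValueError(f"tag at {t.pos} outside peak interval")
        counts[t.pos] = counts.get(t.pos, 0) + t.count
    if not counts:
        raise ValueError("no tags supplied for representative selection")
    return max(counts, key=lambda p: (counts[p], -p))


def call_peaks(tags: Sequence[CageTag],
               params: PeakCallParams = PeakCallParams(),
               library_size: Optional[int] = None) -> List[CagePeak]:
    """Full peak-calling pass: cluster, normalize, filter.

    ``library_size`` defaults to the total input tag count (ctss inputs are
    assumed already mapq-filtered; the mapping-quality cutoff applies in the
    alignment adapter).
    """
    if not tags:
        return []
    if library_size is None:
        library_size = sum(t.count for t in tags)
    clustered = cluster_tags(tags, params.cluster_distance)
    normalized = normalize_tpm(clustered, library_size)
    return filter_peaks(normalized, params.min_tpm)
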
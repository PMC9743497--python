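"""Training-set construction: positive/negative labeling of CAGE peaks,
sliding-window augmentation, and chromosome-held-out splitting.

Labeling rules (applied per peak, in order):

1. positive — the representative lies within ``tss_proximal`` (default
   1 kb) of an annotated protein-coding TSS AND the peak overlaps at least
   one H3K4me3 peak AND at least one Polymerase II peak;
2. excluded — promoter-proximal: the representative falls in the flanking
   band (tss_proximal, tss_proximal + exclusion_flank] (default 1-10 kb)
   of any TSS; such peaks are removed entirely so functionally rich signal
   never contaminates the negative set;
3. excluded — the peak overlaps either mark without satisfying the positive
   rule;
4. negative — intergenic (no gene-body overlap) and overlapping neither
   mark;
5. anything else is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from intervaltree import IntervalTree

from cagetss.io_formats import GenomicInterval
from cagetss.peaks import CagePeak

#: Sliding-window augmentation offsets: the window starts 100 bp upstream of
#: the representative and advances by 25 bp strides, producing 7 shifted
#: windows in addition to the centered one.
DEFAULT_OFFSETS: Tuple[int, ...] = (-100, -75, -50, -25, 0, 25, 50, 75)

POSITIVE = 1
NEGATIVE = 0
EXCLUDED = -1


@dataclass(frozen=True)
class LabelingParams:
    tss_proximal: int = 1000
    exclusion_flank: int = 9000
    offsets: Tuple[int, ...] = DEFAULT_OFFSETS

    def __post_init__(self):
        if self.exclusion_flank <= 0:
            raise ValueError("exclusion_flank must be positive")
        if 0 not in self.offsets:
            raise ValueError("augmentation offsets must include 0")


@dataclass(frozen=True)
class LabeledExample:
    """One (peak, window offset, label) training example."""

    peak: CagePeak
    offset: int
    label: int

    @property
    def chrom(self) -> str:
        return self.peak.interval.chrom


def _build_tree(intervals: Iterable[GenomicInterval]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def _overlaps(trees: Dict[str, IntervalTree], peak: CagePeak) -> bool:
    tree = trees.get(peak.interval.chrom)
    return bool(tree and tree.overlap(peak.interval.start, peak.interval.end))


def _tss_positions(tss_list: Sequence[GenomicInterval]) -> Dict[str, np.ndarray]:
    per_chrom: Dict[str, List[int]] = {}
    for iv in tss_list:
        # a TSS annotation is a point; minus-strand genes start at end-1
        pos = iv.start if iv.strand != "-" else iv.end - 1
        per_chrom.setdefault(iv.chrom, []).append(pos)
    return {c: np.array(sorted(p), dtype=np.int64) for c, p in per_chrom.items()}


def nearest_tss_distance(positions: Dict[str, np.ndarray], chrom: str,
                         pos: int) -> Optional[int]:
    """Unsigned bp distance from pos to the nearest TSS on chrom."""
    arr = positions.get(chrom)
    if arr is None or arr.size == 0:
        return None
    i = int(np.searchsorted(arr, pos))
    best = None
    for j in (i - 1, i):
        if 0 <= j < arr.size:
            d = abs(int(arr[j]) - pos)
            best = d if best is None else min(best, d)
    return best


def label_peaks(peaks: Sequence[CagePeak],
                tss_list: Sequence[GenomicInterval],
                h3k4me3: Sequence[GenomicInterval],
                polii: Sequence[GenomicInterval],
                gene_bodies: Sequence[GenomicInterval],
                params: LabelingParams = LabelingParams()) -> List[Tuple[CagePeak, int]]:
    """Assign POSITIVE / NEGATIVE / EXCLUDED to every peak.

    Returns one (peak, label) pair per input peak, in input order, so the
    labeled output plus the exclusions always partition the input.
    """
    if not tss_list:
        raise ValueError("cannot label peaks without a TSS annotation")
    tss_pos = _tss_positions(tss_list)
    k4_tree = _build_tree(h3k4me3)
    pol_tree = _build_tree(polii)
    gene_tree = _build_tree(gene_bodies)

    out: List[Tuple[CagePeak, int]] = []
    for peak in peaks:
        d = nearest_tss_distance(tss_pos, peak.interval.chrom,
                                 peak.representative)
        has_k4 = _overlaps(k4_tree, peak)
        has_pol = _overlaps(pol_tree, peak)
        in_gene = _overlaps(gene_tree, peak)

        if d is not None and d <= params.tss_proximal and has_k4 and has_pol:
            out.append((peak, POSITIVE))
        elif d is not None and params.tss_proximal < d <= params.tss_proximal + params.exclusion_flank:
            out.append((peak, EXCLUDED))
        elif has_k4 or has_pol:
            out.append((peak, EXCLUDED))
        elif not in_gene:
            out.append((peak, NEGATIVE))
        else:
            out.append((peak, EXCLUDED))
    return out


def augment(example: LabeledExample,
            offsets: Sequence[int] = DEFAULT_OFFSETS) -> List[LabeledExample]:
    """Expand one labeled peak into one example per window offset.

    The default offset set spans -100..+75 bp in 25 bp strides: 7 shifted
    windows in addition to the centered one, every one still containing the
    representative. Labels are copied unchanged.
    """
    return [LabeledExample(example.peak, off, example.label) for off in offsets]


def make_examples(labeled: Sequence[Tuple[CagePeak, int]],
                  offsets: Sequence[int] = DEFAULT_OFFSETS) -> List[LabeledExample]:
    """Centered examples for every non-excluded peak, then augmented."""
    out: List[LabeledExample] = []
    for peak, label in labeled:
        if label == EXCLUDED:
            continue
        out.extend(augment(LabeledExample(peak, 0, label), offsets))
    return out


def chromosome_split(examples: Sequence[LabeledExample],
                     test_chroms: Set[str],
                     val_chroms: Set[str] = frozenset()) -> Tuple[List[LabeledExample], List[LabeledExample], List[LabeledExample]]:
    """Partition examples by chromosome into (train, val, test).

    Whole chromosomes are held out, so augmented siblings of one peak always
    land in the same partition and no locus leaks across partitions.
    """
    if test_chroms & val_chroms:
        raise ValueError(
            f"test and validation chromosomes overlap: {test_chroms & val_chroms}"
        )
    train: List[LabeledExample] = []
    val: List[LabeledExample] = []
    test: List[LabeledExample] = []
    for ex in examples:
        if ex.chrom in test_chroms:
            test.append(ex)
        elif ex.chrom in val_chroms:
            val.append(ex)
        else:
            train.append(ex)
    return train, val, test
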
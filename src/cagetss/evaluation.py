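"""Annotation-zone and chromatin-overlap benchmarks.

Predictions are judged against zones built around annotated protein-coding
TSSs: a positive zone of +/- 500 bp and a negative zone of +/- 50 kb with
the positive zone carved out. A prediction whose representative falls in a
positive zone is a true positive; in a negative zone it is a false positive
unless the peak overlaps an H3K4me3 peak, in which case it is rescued as a
TP (promoter marks indicate an unannotated initiation event). Predictions
outside both zones are tallied separately, not counted in precision.

Gene-oriented scoring asks instead how many genes have at least one
prediction within +/- 500 bp of one of their TSSs; each gene counts once.
Overlap-percentage metrics (chromatin-state groups, TFBS, H3K4me3) report
the fraction of predictions overlapping at least one region of a set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from intervaltree import IntervalTree

from cagetss.io_formats import GenomicInterval
from cagetss.peaks import CagePeak


def _tss_point(iv: GenomicInterval) -> int:
    return iv.start if iv.strand != "-" else iv.end - 1


@dataclass
class BenchmarkZones:
    """Positive/negative evaluation zones around annotated TSSs.

    Positive membership takes precedence wherever zones of different TSSs
    overlap. ``provenance`` maps each zone interval back to the index of
    the TSS that produced it.
    """

    positive: Dict[str, IntervalTree]
    negative: Dict[str, IntervalTree]
    tss_points: List[Tuple[str, int]]
    pos_radius: int
    neg_radius: int

    def zone_of(self, chrom: str, pos: int) -> str:
        """'positive', 'negative' or 'none' for a 1 bp point."""
        tree = self.positive.get(chrom)
        if tree and tree.overlap(pos, pos + 1):
            return "positive"
        tree = self.negative.get(chrom)
        if tree and tree.overlap(pos, pos + 1):
            return "negative"
        return "none"


def build_zones(tss_list: Sequence[GenomicInterval], pos_radius: int = 500,
                neg_radius: int = 50000) -> BenchmarkZones:
    """Build positive (+/- pos_radius) and negative (+/- neg_radius minus
    the positive zone) zones around each TSS.

    A TSS at p yields positive [p - r, p + r + 1) and negative
    [p - R, p - r) plus [p + r + 1, p + R + 1), all clipped at 0.
    """
    positive: Dict[str, IntervalTree] = {}
    negative: Dict[str, IntervalTree] = {}
    points: List[Tuple[str, int]] = []
    for i, iv in enumerate(tss_list):
        p = _tss_point(iv)
        points.append((iv.chrom, p))
        ptree = positive.setdefault(iv.chrom, IntervalTree())
        ntree = negative.setdefault(iv.chrom, IntervalTree())
        lo, hi = max(0, p - pos_radius), p + pos_radius + 1
        ptree.addi(lo, hi, i)
        nlo = max(0, p - neg_radius)
        if nlo < lo:
            ntree.addi(nlo, lo, i)
        ntree.addi(hi, p + neg_radius + 1, i)
    return BenchmarkZones(positive, negative, points, pos_radius, neg_radius)


@dataclass
class EvalReport:
    """Benchmark tallies: peak-oriented TP/FP, rescues, out-of-zone count,
    and derived precision; gene-oriented counts attach when computed."""

    tp: int = 0
    fp: int = 0
    rescued: int = 0
    out_of_zone: int = 0
    gene_tp: int = 0
    gene_fp: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0


def _build_tree(intervals: Iterable[GenomicInterval]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def classify_predictions(predictions: Sequence[CagePeak],
                         zones: BenchmarkZones,
                         h3k4me3: Sequence[GenomicInterval] = ()) -> EvalReport:
    """Tally TP/FP over positive predictions.

    Zone membership is decided by the 1 bp representative; the H3K4me3
    rescue of negative-zone predictions uses the full peak interval.
    """
    k4 = _build_tree(h3k4me3)
    report = EvalReport()
    for peak in predictions:
        zone = zones.zone_of(peak.interval.chrom, peak.representative)
        if zone == "positive":
            report.tp += 1
        elif zone == "negative":
            tree = k4.get(peak.interval.chrom)
            if tree and tree.overlap(peak.interval.start, peak.interval.end):
                report.tp += 1
                report.rescued += 1
            else:
                report.fp += 1
        else:
            report.out_of_zone += 1
    return report


def sensitivity(report: EvalReport, benchmark_positive_count: int) -> float:
    """TP over the caller-supplied number of benchmark positives."""
    if benchmark_positive_count <= 0:
        raise ValueError("benchmark_positive_count must be positive")
    return report.tp / benchmark_positive_count


def gene_oriented(predictions: Sequence[CagePeak],
                  tss_list: Sequence[GenomicInterval],
                  radius: int = 500) -> Tuple[int, int]:
    """(gene TP, prediction FP) for the gene-oriented benchmark.

    A gene is a TP when at least one prediction lies within ``radius`` of
    any of its TSSs (genes identified by TSS identity; each counted once).
    Predictions near no gene count once each as FPs.
    """
    per_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for i, iv in enumerate(tss_list):
        per_chrom.setdefault(iv.chrom, []).append((_tss_point(iv), i))
    trees: Dict[str, IntervalTree] = {}
    for chrom, pts in per_chrom.items():
        t = IntervalTree()
        for p, i in pts:
            t.addi(max(0, p - radius), p + radius + 1, i)
        trees[chrom] = t
    hit_genes: Set[int] = set()
    fp = 0
    for peak in predictions:
        tree = trees.get(peak.interval.chrom)
        hits = tree.overlap(peak.representative, peak.representative + 1) if tree else ()
        if hits:
            hit_genes.update(h.data for h in hits)
        else:
            fp += 1
    return len(hit_genes), fp


def overlap_fraction(predictions: Sequence[CagePeak],
                     regions: Sequence[GenomicInterval]) -> Tuple[float, int]:
    """(percentage, count) of predictions overlapping >= 1 region.

    Used identically for chromatin-state groups, TFBS and H3K4me3 peaks.
    """
    if not predictions:
        return 0.0, 0
    trees = _build_tree(regions)
    count = 0
    for peak in predictions:
        tree = trees.get(peak.interval.chrom)
        if tree and tree.overlap(peak.interval.start, peak.interval.end):
            count += 1
    return 100.0 * count / len(predictions), count


def precision_recall_sweep(peaks: Sequence[CagePeak],
                           scores: Sequence[float],
                           zones: BenchmarkZones,
                           h3k4me3: Sequence[GenomicInterval],
                           cutoffs: Sequence[float],
                           benchmark_positive_count: Optional[int] = None
                           ) -> List[Dict[str, float]]:
    """One (cutoff, precision, sensitivity, TP, FP) point per score cutoff.

    TP and FP are non-increasing in the cutoff. Sensitivity is reported
    when a benchmark positive count is supplied.
    """
    scores = np.asarray(scores, dtype=float)
    points: List[Dict[str, float]] = []
    for cutoff in cutoffs:
        selected = [p for p, s in zip(peaks, scores) if s >= cutoff]
        report = classify_predictions(selected, zones, h3k4me3)
        point = {
            "cutoff": float(cutoff),
            "tp": report.tp,
            "fp": report.fp,
            "precision": report.precision,
        }
        if benchmark_positive_count:
            point["sensitivity"] = sensitivity(report, benchmark_positive_count)
        points.append(point)
    return points
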
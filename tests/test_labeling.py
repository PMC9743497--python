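import numpy as np
import pytest

from cagetss.io_formats import GenomicInterval
from cagetss.labeling import (
    DEFAULT_OFFSETS,
    EXCLUDED,
    NEGATIVE,
    POSITIVE,
    LabeledExample,
    LabelingParams,
    augment,
    chromosome_split,
    label_peaks,
    make_examples,
)
from cagetss.peaks import CagePeak


def peak(rep, width=20, chrom="chr1", strand="+"):
    return CagePeak(GenomicInterval(chrom, rep - width // 2, rep + width // 2, strand),
                    tag_count=10, representative=rep, tpm=5.0)


def iv(start, end, chrom="chr1", strand="."):
    return GenomicInterval(chrom, start, end, strand)


TSS = [iv(100_000, 100_001, strand="+")]


class TestLabelRules:
    def test_proximal_with_both_marks_is_positive(self):
        marks = [iv(99_000, 101_000)]
        [(_, label)] = label_peaks([peak(100_200)], TSS, marks, marks, [])
        assert label == POSITIVE

    def test_flank_excluded_regardless_of_marks(self):
        marks = [iv(90_000, 110_000)]
        [(_, label)] = label_peaks([peak(105_000)], TSS, marks, marks, [])
        assert label == EXCLUDED

    def test_intergenic_no_marks_is_negative(self):
        [(_, label)] = label_peaks([peak(200_000)], TSS, [], [], [])
        assert label == NEGATIVE

    def test_mark_without_tss_is_excluded(self):
        k4 = [iv(199_000, 201_000)]
        [(_, label)] = label_peaks([peak(200_000)], TSS, k4, [], [])
        assert label == EXCLUDED

    def test_proximal_with_single_mark_is_excluded(self):
        k4 = [iv(99_000, 101_000)]
        [(_, label)] = label_peaks([peak(100_200)], TSS, k4, [], [])
        assert label == EXCLUDED

    def test_genic_peak_without_marks_is_excluded(self):
        genes = [iv(195_000, 205_000)]
        [(_, label)] = label_peaks([peak(200_000)], TSS, [], [], genes)
        assert label == EXCLUDED

    def test_flank_boundaries(self):
        # distance exactly 1,000 is proximal; 1,001..10,000 is the removed
        # band; 10,001 falls outside it
        marks = [iv(90_000, 112_000)]
        labels = {
            d: label_peaks([peak(100_000 + d)], TSS, marks, marks, [])[0][1]
            for d in (1_000, 1_001, 10_000, 10_001)
        }
        assert labels[1_000] == POSITIVE
        assert labels[1_001] == EXCLUDED
        assert labels[10_000] == EXCLUDED
        # at 10,001 bp the flank rule no longer applies; the mark-overlap
        # exclusion still does
        assert labels[10_001] == EXCLUDED

    def test_empty_tss_list_rejected(self):
        with pytest.raises(ValueError):
            label_peaks([peak(1_000)], [], [], [], [])

    def test_output_partitions_input(self, rng):
        peaks = [peak(int(rng.integers(1_000, 500_000))) for _ in range(100)]
        labeled = label_peaks(peaks, TSS, [iv(99_000, 101_000)],
                              [iv(99_500, 100_500)], [iv(100_000, 105_000)])
        assert [p for p, _ in labeled] == peaks
        assert all(l in (POSITIVE, NEGATIVE, EXCLUDED) for _, l in labeled)

    def test_shuffling_input_changes_no_label(self, rng):
        peaks = [peak(int(rng.integers(1_000, 500_000))) for _ in range(50)]
        marks = [iv(99_000, 101_000)]
        ref = dict(
            (p.representative, l)
            for p, l in label_peaks(peaks, TSS, marks, marks, []))
        perm = [peaks[i] for i in rng.permutation(len(peaks))]
        for p, l in label_peaks(perm, TSS, marks, marks, []):
            assert ref[p.representative] == l


class TestBruteForceAgreement:
    """The indexed implementation must agree with a per-peak scan."""

    def oracle_label(self, pk, tss_points, k4, pol, genes, params):
        def dist():
            ds = [abs(t - pk.representative) for c, t in tss_points
                  if c == pk.interval.chrom]
            return min(ds) if ds else None

        def hits(regions):
            return any(pk.interval.overlaps(r) for r in regions)

        d = dist()
        has_k4, has_pol, in_gene = hits(k4), hits(pol), hits(genes)
        if d is not None and d <= params.tss_proximal and has_k4 and has_pol:
            return POSITIVE
        if d is not None and params.tss_proximal < d <= params.tss_proximal + params.exclusion_flank:
            return EXCLUDED
        if has_k4 or has_pol:
            return EXCLUDED
        if not in_gene:
            return NEGATIVE
        return EXCLUDED

    def test_random_fixture_agreement(self, rng):
        params = LabelingParams()
        tss = [iv(int(p), int(p) + 1, chrom=f"chr{c}", strand="+")
               for c in (1, 2)
               for p in rng.integers(20_000, 2_000_000, size=10)]
        tss_points = [(t.chrom, t.start) for t in tss]

        def random_regions(n, width):
            return [iv(int(s), int(s) + width, chrom=f"chr{int(rng.integers(1, 3))}")
                    for s in rng.integers(0, 2_000_000, size=n)]

        k4 = random_regions(40, 2_000)
        pol = random_regions(40, 2_000)
        genes = random_regions(30, 20_000)
        peaks = [peak(int(p), chrom=f"chr{int(rng.integers(1, 3))}")
                 for p in rng.integers(1_000, 2_000_000, size=500)]
        got = label_peaks(peaks, tss, k4, pol, genes, params)
        for pk, label in got:
            assert label == self.oracle_label(pk, tss_points, k4, pol, genes,
                                              params)


class TestAugment:
    def test_eight_windows_seven_shifted(self):
        ex = LabeledExample(peak(100_000), 0, POSITIVE)
        out = augment(ex)
        assert len(out) == 8
        assert sum(1 for e in out if e.offset != 0) == 7
        assert all(e.label == POSITIVE for e in out)
        assert all(abs(e.offset) <= 100 for e in out)

    def test_offsets_span_upstream_to_downstream_in_25bp_strides(self):
        assert DEFAULT_OFFSETS == (-100, -75, -50, -25, 0, 25, 50, 75)

    def test_restricted_to_center_is_identity(self):
        ex = LabeledExample(peak(100_000), 0, NEGATIVE)
        assert augment(ex, (0,)) == [ex]

    def test_make_examples_multiplies_by_offsets(self):
        labeled = [(peak(100_000), POSITIVE), (peak(200_000), NEGATIVE),
                   (peak(300_000), EXCLUDED)]
        out = make_examples(labeled)
        assert len(out) == 2 * len(DEFAULT_OFFSETS)

    def test_offsets_must_include_zero(self):
        with pytest.raises(ValueError):
            LabelingParams(offsets=(-25, 25))


class TestChromosomeSplit:
    def _examples(self):
        return [LabeledExample(peak(10_000 + i * 1000, chrom=c), off, POSITIVE)
                for i, c in enumerate(["chr1", "chr14", "chr15"] * 4)
                for off in (0, 25)]

    def test_three_way_disjoint(self):
        tr, va, te = chromosome_split(self._examples(), {"chr15"}, {"chr14"})
        assert {e.chrom for e in tr} == {"chr1"}
        assert {e.chrom for e in va} == {"chr14"}
        assert {e.chrom for e in te} == {"chr15"}

    def test_counts_conserved(self):
        ex = self._examples()
        tr, va, te = chromosome_split(ex, {"chr15"}, {"chr14"})
        assert len(tr) + len(va) + len(te) == len(ex)

    def test_empty_val_two_way(self):
        tr, va, te = chromosome_split(self._examples(), {"chr15"})
        assert va == [] and {e.chrom for e in te} == {"chr15"}

    def test_siblings_travel_together(self):
        ex = self._examples()
        tr, va, te = chromosome_split(ex, {"chr15"}, {"chr14"})
        for part in (tr, va, te):
            chroms = {e.chrom for e in part}
            for e in ex:
                if e.chrom in chroms:
                    assert any(o.peak == e.peak and o.offset == e.offset
                               for o in part)

    def test_overlapping_partitions_rejected(self):
        with pytest.raises(ValueError):
            chromosome_split(self._examples(), {"chr14"}, {"chr14"})
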
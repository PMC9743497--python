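import numpy as np
import pytest

from cagetss.features import (
    ConfigurationError,
    FeatureBundle,
    StructuralTable,
    WindowOutOfBounds,
    apply_standardizer,
    bendability_table,
    conservation_window,
    dna_walk,
    extract_window,
    featurize_peak,
    fit_standardizer,
    gsp_block,
    kmer_profile,
    load_structural_table,
    one_hot,
    paired_numeric,
    propeller_twist_table,
    reverse_complement,
    structural_block,
    tetrahedron,
    zcurve,
)
from cagetss.io_formats import ConservationTrack
from tests.conftest import random_sequence

# ---------------------------------------------------------------------------
# independent brute-force oracles (prefix counting / direct lookup)

def oracle_zcurve(seq):
    out = np.zeros((3, len(seq)))
    a = c = g = t = 0
    for i, b in enumerate(seq):
        a += b == "A"; c += b == "C"; g += b == "G"; t += b == "T"
        out[0, i] = (a + g) - (c + t)
        out[1, i] = (a + c) - (g + t)
        out[2, i] = (a + t) - (g + c)
    return out


def oracle_walk(seq):
    total, out = 0, []
    for b in seq:
        total += 1 if b in "CT" else (-1 if b in "AG" else 0)
        out.append(total)
    return np.array(out, dtype=float)


def oracle_paired(seq):
    m = {"A": 1, "T": 1, "C": -1, "G": -1}
    return np.array([m.get(b, 0) for b in seq], dtype=float)


def oracle_kmer(seq, table):
    k = table.kmer_size
    return np.array([table.scores.get(seq[i:i + k], 0.0)
                     for i in range(len(seq) - k + 1)])


def oracle_onehot(seq):
    cols = "ACGT"
    return np.array([[1.0 if b == col else 0.0 for col in cols] for b in seq])


# ---------------------------------------------------------------------------

class TestWindow:
    GENOME = None

    @pytest.fixture(autouse=True)
    def _genome(self, rng):
        if TestWindow.GENOME is None:
            TestWindow.GENOME = {"chr1": random_sequence(rng, 1000)}
        self.genome = TestWindow.GENOME

    def test_centered_window(self):
        win = extract_window(self.genome, "chr1", 500, "+")
        assert win.sequence == self.genome["chr1"][200:800]
        assert len(win.sequence) == 600

    def test_shifted_window(self):
        win = extract_window(self.genome, "chr1", 500, "+", offset=100)
        assert win.sequence == self.genome["chr1"][300:900]

    def test_left_overrun_skipped(self):
        with pytest.raises(WindowOutOfBounds):
            extract_window(self.genome, "chr1", 100, "+")

    def test_right_overrun_skipped(self):
        with pytest.raises(WindowOutOfBounds):
            extract_window(self.genome, "chr1", 900, "+")

    def test_minus_strand_reverse_complemented(self):
        plus = extract_window(self.genome, "chr1", 500, "+")
        minus = extract_window(self.genome, "chr1", 500, "-")
        assert minus.sequence == reverse_complement(plus.sequence)

    def test_representative_index_on_plus_strand(self):
        for offset in (-100, 0, 75):
            win = extract_window(self.genome, "chr1", 500, "+", offset=offset)
            assert win.sequence[300 - offset] == self.genome["chr1"][500]


class TestEncoders:
    def test_one_hot_rows(self):
        block = one_hot("AN")
        assert block[0].tolist() == [1, 0, 0, 0]
        assert block[1].tolist() == [0, 0, 0, 0]

    def test_zcurve_acgt(self):
        np.testing.assert_array_equal(
            zcurve("ACGT"),
            [[1, 0, 1, 0], [1, 2, 1, 0], [1, 0, -1, 0]])

    def test_zcurve_all_purine(self):
        np.testing.assert_array_equal(zcurve("AAAA"),
                                      np.tile([1, 2, 3, 4], (3, 1)))

    def test_walk_examples(self):
        np.testing.assert_array_equal(dna_walk("ACGT"), [-1, 0, -1, 0])
        np.testing.assert_array_equal(dna_walk("CCCC"), [1, 2, 3, 4])

    def test_paired_examples(self):
        np.testing.assert_array_equal(paired_numeric("ACGT"), [1, -1, -1, 1])
        np.testing.assert_array_equal(paired_numeric("NNNN"), [0, 0, 0, 0])

    def test_paired_revcomp_symmetry(self, rng):
        for _ in range(20):
            s = random_sequence(rng, 50)
            np.testing.assert_array_equal(
                paired_numeric(reverse_complement(s)),
                paired_numeric(s)[::-1])

    def test_tetrahedron_geometry(self):
        vecs = {b: tetrahedron(b)[:, 0] for b in "ACGT"}
        for v in vecs.values():
            assert np.linalg.norm(v) == pytest.approx(1.0)
        bases = list("ACGT")
        for i in range(4):
            for j in range(i + 1, 4):
                assert vecs[bases[i]] @ vecs[bases[j]] == pytest.approx(-1 / 3)
        assert np.allclose(sum(vecs.values()), 0)
        assert tetrahedron("N")[:, 0].tolist() == [0, 0, 0]

    def test_walk_is_negated_zcurve_x(self, rng):
        s = random_sequence(rng, 200)
        np.testing.assert_array_equal(dna_walk(s), -zcurve(s)[0])

    def test_prefix_count_identity(self, rng):
        # A_n = (x_n + y_n + z_n + n) / 4 for unambiguous sequences
        s = random_sequence(rng, 300)
        x, y, z = zcurve(s)
        n = np.arange(1, len(s) + 1)
        a_n = (x + y + z + n) / 4
        expected = np.cumsum([b == "A" for b in s])
        np.testing.assert_allclose(a_n, expected)

    @pytest.mark.parametrize("encoder,oracle", [
        (zcurve, oracle_zcurve),
        (dna_walk, oracle_walk),
        (paired_numeric, oracle_paired),
        (one_hot, oracle_onehot),
    ])
    def test_oracle_equivalence(self, rng, encoder, oracle):
        for _ in range(50):
            n = int(rng.integers(10, 200))
            s = random_sequence(rng, n)
            if rng.random() < 0.3:  # sprinkle ambiguity codes
                idx = rng.integers(0, n, size=3)
                s = "".join("N" if i in idx else b for i, b in enumerate(s))
            np.testing.assert_allclose(encoder(s), oracle(s))

    def test_encoders_are_pure(self, rng):
        s = random_sequence(rng, 100)
        assert np.array_equal(zcurve(s), zcurve(s))
        assert np.array_equal(gsp_block(s), gsp_block(s))


class TestStructural:
    def test_profile_lengths_on_600bp(self, rng):
        s = random_sequence(rng, 600)
        assert kmer_profile(s, bendability_table()).shape == (598,)
        assert kmer_profile(s, propeller_twist_table()).shape == (599,)

    def test_constant_table_constant_signal(self):
        table = StructuralTable(2, {a + b: 3.25 for a in "ACGT" for b in "ACGT"})
        np.testing.assert_array_equal(kmer_profile("ACGTACGT", table),
                                      np.full(7, 3.25))

    def test_ambiguous_kmer_scores_zero(self):
        table = StructuralTable(2, {a + b: 1.0 for a in "ACGT" for b in "ACGT"})
        np.testing.assert_array_equal(kmer_profile("ANG", table), [0.0, 0.0])

    def test_missing_kmer_is_configuration_error(self):
        scores = {a + b: 1.0 for a in "ACGT" for b in "ACGT"}
        del scores["AC"]
        with pytest.raises(ConfigurationError):
            kmer_profile("ACGT", StructuralTable(2, scores))

    def test_oracle_equivalence(self, rng):
        for table in (bendability_table(), propeller_twist_table()):
            for _ in range(20):
                s = random_sequence(rng, int(rng.integers(10, 100)))
                np.testing.assert_allclose(kmer_profile(s, table),
                                           oracle_kmer(s, table))

    def test_tables_share_revcomp_values(self):
        bend = bendability_table()
        for kmer, val in bend.scores.items():
            assert bend.scores[reverse_complement(kmer)] == val

    def test_block_padded_with_trailing_zeros(self, rng):
        s = random_sequence(rng, 600)
        block = structural_block(s)
        assert block.shape == (600, 2)
        assert block[598:, 0].tolist() == [0.0, 0.0]
        assert block[599, 1] == 0.0

    def test_loader_round_trip(self, tmp_path):
        p = tmp_path / "table.tsv"
        p.write_text("# comment\nAA\t1.0\nAC\t2.0\nAG\t3.0\nAT\t4.0\n"
                     "CA\t5.0\nCC\t6.0\nCG\t7.0\nGA\t8.0\nGC\t9.0\nTA\t10.0\n")
        table = load_structural_table(str(p), kmer_size=2)
        assert table.scores["GT"] == table.scores["AC"] == 2.0


class TestConservationWindow:
    def _track(self):
        return ConservationTrack({
            "chr1": (np.array([450]), np.array([470]), np.array([2.0]))
        })

    def test_plus_strand_span(self):
        vals = conservation_window(self._track(), "chr1", 500, "+")
        assert vals.shape == (600,)
        assert vals[250:270].tolist() == [2.0] * 20
        assert vals.sum() == pytest.approx(40.0)

    def test_minus_strand_reversed(self):
        plus = conservation_window(self._track(), "chr1", 500, "+")
        minus = conservation_window(self._track(), "chr1", 500, "-")
        np.testing.assert_array_equal(minus, plus[::-1])


class TestFeaturize:
    def test_complete_bundle_or_skip_never_partial(self, rng):
        genome = {"chr1": random_sequence(rng, 2000)}
        track = ConservationTrack.empty()
        bundle = featurize_peak(genome, track, "chr1", 1000, "+")
        assert bundle.onehot.shape == (600, 4)
        assert bundle.gsp.shape == (600, 8)
        assert bundle.structural.shape == (600, 2)
        assert bundle.conservation.shape == (600, 1)
        with pytest.warns(UserWarning):
            assert featurize_peak(genome, track, "chr1", 100, "+") is None


class TestStandardizer:
    def _bundles(self, rng, n=10):
        genome = {"chr1": random_sequence(rng, 5000)}
        track = ConservationTrack.empty()
        return [featurize_peak(genome, track, "chr1",
                               int(rng.integers(400, 4600)), "+")
                for _ in range(n)]

    def test_standardized_channels_zero_mean_unit_sd(self, rng):
        bundles = self._bundles(rng)
        stats = fit_standardizer(bundles)
        out = [apply_standardizer(b, stats) for b in bundles]
        gsp = np.concatenate([b.gsp for b in out])
        struct = np.concatenate([b.structural for b in out])
        np.testing.assert_allclose(gsp.mean(axis=0), 0, atol=1e-6)
        np.testing.assert_allclose(gsp.std(axis=0), 1, atol=1e-6)
        np.testing.assert_allclose(struct.mean(axis=0), 0, atol=1e-6)
        np.testing.assert_allclose(struct.std(axis=0), 1, atol=1e-6)

    def test_onehot_and_conservation_untouched(self, rng):
        bundles = self._bundles(rng, n=4)
        stats = fit_standardizer(bundles)
        out = apply_standardizer(bundles[0], stats)
        np.testing.assert_array_equal(out.onehot, bundles[0].onehot)
        np.testing.assert_array_equal(out.conservation, bundles[0].conservation)

    def test_zero_variance_channel_left_alone(self):
        flat = FeatureBundle(
            onehot=np.zeros((600, 4)),
            gsp=np.ones((600, 8)),
            structural=np.zeros((600, 2)),
            conservation=np.zeros((600, 1)),
        )
        stats = fit_standardizer([flat])
        out = apply_standardizer(flat, stats)
        assert np.all(np.isfinite(out.gsp))
        np.testing.assert_array_equal(out.structural, 0)
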
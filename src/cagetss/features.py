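"""Feature extraction around CAGE peak representatives.

Each peak is encoded from the 600 bp window centered on its representative
as four fixed-shape blocks, one per model branch:

* ``onehot`` (600 x 4): the raw sequence, column order A, C, G, T.
* ``gsp`` (600 x 8): genomic-signal-processing encodings — the three
  Z-curve cumulative components (purine/pyrimidine, amino/keto, strong/weak
  hydrogen bonding), the DNA walk, the paired-numeric complementarity
  signal and the three tetrahedron coordinates.
* ``structural`` (600 x 2): trinucleotide bendability and dinucleotide
  propeller twist looked up from published biochemical tables, end-padded
  with zeros from their native 598/599 lengths to 600.
* ``conservation`` (600 x 1): raw per-base evolutionary conservation
  (e.g. phyloP), zeros where no score exists; never standardized.

Minus-strand peaks are reverse-complemented (and their conservation window
reversed) so the model always sees the sense orientation. Ambiguous bases
contribute zeros in every encoding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from cagetss.io_formats import ConservationTrack

WINDOW_SIZE = 600

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# Pointwise encoding constants. Paired numeric assigns complementary bases a
# shared value (A/T = +1, C/G = -1) so reverse-complementing a sequence
# reverses its signal. Tetrahedron vertices are the unit-normalized corners
# of a cube-inscribed regular tetrahedron (pairwise dot products -1/3).
_PAIRED = {"A": 1.0, "T": 1.0, "C": -1.0, "G": -1.0}
_S3 = 1.0 / np.sqrt(3.0)
_TETRA = {
    "A": (_S3, _S3, _S3),
    "C": (-_S3, -_S3, _S3),
    "G": (-_S3, _S3, -_S3),
    "T": (_S3, -_S3, -_S3),
}


class ConfigurationError(ValueError):
    """Raised when a structural table is incomplete."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceWindow:
    """A 600 bp sequence window around (near) a peak representative."""

    sequence: str
    chrom: str
    center: int
    strand: str
    offset: int = 0

    def __post_init__(self):
        if len(self.sequence) != WINDOW_SIZE:
            raise ValueError(
                f"window must be {WINDOW_SIZE} bp, got {len(self.sequence)}"
            )


@dataclass
class FeatureBundle:
    """The four fixed-shape feature blocks for one 600 bp window."""

    onehot: np.ndarray        # (600, 4) float
    gsp: np.ndarray           # (600, 8) float
    structural: np.ndarray    # (600, 2) float
    conservation: np.ndarray  # (600, 1) float

    def __post_init__(self):
        expected = {
            "onehot": (WINDOW_SIZE, 4),
            "gsp": (WINDOW_SIZE, 8),
            "structural": (WINDOW_SIZE, 2),
            "conservation": (WINDOW_SIZE, 1),
        }
        for name, shape in expected.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} block must have shape {shape}, got {arr.shape}")


@dataclass(frozen=True)
class StructuralTable:
    """k-mer -> score lookup for a structural DNA propensity (k = 2 or 3)."""

    kmer_size: int
    scores: Dict[str, float]

    def __post_init__(self):
        if self.kmer_size not in (2, 3):
            raise ValueError("kmer_size must be 2 or 3")

    def validate(self) -> None:
        from itertools import product
        for kmer in ("".join(p) for p in product("ACGT", repeat=self.kmer_size)):
            if kmer not in self.scores:
                raise ConfigurationError(f"structural table missing k-mer {kmer}")


def load_structural_table(path_or_lines, kmer_size: int,
                          expand_revcomp: bool = True) -> StructuralTable:
    """Load a 2-column (kmer, score) text table.

    Published tables often list only one of each reverse-complementary pair;
    ``expand_revcomp`` fills the partner with the same value.
    """
    if isinstance(path_or_lines, (str,)):
        with open(path_or_lines) as fh:
            lines = fh.readlines()
    else:
        lines = list(path_or_lines)
    scores: Dict[str, float] = {}
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        kmer, value = line.split()[:2]
        kmer = kmer.upper()
        scores[kmer] = float(value)
        if expand_revcomp:
            scores.setdefault(reverse_complement(kmer), float(value))
    table = StructuralTable(kmer_size=kmer_size, scores=scores)
    table.validate()
    return table


def _load_packaged(name: str, k: int) -> StructuralTable:
    text = resources.files("cagetss.data").joinpath(name).read_text()
    return load_structural_table(text.splitlines(), kmer_size=k)


_TABLE_CACHE: Dict[str, StructuralTable] = {}


def bendability_table() -> StructuralTable:
    """Trinucleotide DNase I bendability parameters (shipped table)."""
    if "bend" not in _TABLE_CACHE:
        _TABLE_CACHE["bend"] = _load_packaged("bendability.tsv", 3)
    return _TABLE_CACHE["bend"]


def propeller_twist_table() -> StructuralTable:
    """Dinucleotide propeller-twist angles in degrees (shipped table)."""
    if "propel" not in _TABLE_CACHE:
        _TABLE_CACHE["propel"] = _load_packaged("propeller_twist.tsv", 2)
    return _TABLE_CACHE["propel"]


class WindowOutOfBounds(ValueError):
    """The shifted window does not fit inside the chromosome."""


def extract_window(genome: Dict[str, str], chrom: str, center: int,
                   strand: str, size: int = WINDOW_SIZE,
                   offset: int = 0) -> SequenceWindow:
    """Cut the ``size`` bp window covering [center+offset-size/2,
    center+offset+size/2) and orient it by strand.

    Minus-strand windows are reverse-complemented so downstream encoders see
    the sense sequence. Raises :class:`WindowOutOfBounds` when the window
    overruns either chromosome end (callers skip such peaks with a warning).
    """
    half = size // 2
    start = center + offset - half
    end = center + offset + half
    seq = genome[chrom]
    if start < 0 or end > len(seq):
        raise WindowOutOfBounds(
            f"window [{start}, {end}) overruns {chrom} (length {len(seq)})"
        )
    window = seq[start:end]
    if strand == "-":
        window = reverse_complement(window)
    return SequenceWindow(window, chrom, center, strand, offset)


def _base_indices(sequence: str) -> np.ndarray:
    """Map A,C,G,T -> 0..3 and anything else -> 4."""
    lut = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return lut[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def one_hot(sequence: str) -> np.ndarray:
    """One-hot encode a sequence, columns A, C, G, T; ambiguity -> zero row."""
    idx = _base_indices(sequence)
    out = np.zeros((len(sequence), 4), dtype=np.float64)
    valid = idx < 4
    out[np.nonzero(valid)[0], idx[valid]] = 1.0
    return out


def zcurve(sequence: str) -> np.ndarray:
    """The three cumulative Z-curve components, shape (3, n).

    With prefix counts A_n, C_n, G_n, T_n up to position n:
    x separates purines from pyrimidines, x_n = (A+G) - (C+T);
    y separates amino from keto bases,    y_n = (A+C) - (G+T);
    z separates weak from strong H-bonds, z_n = (A+T) - (G+C).
    Ambiguous bases contribute 0 to every component.
    """
    idx = _base_indices(sequence)
    steps = np.zeros((3, len(sequence)), dtype=np.float64)
    # per-base step vectors: A=(+,+,+), C=(-,+,-), G=(+,-,-), T=(-,-,+)
    xs = np.array([1.0, -1.0, 1.0, -1.0, 0.0])
    ys = np.array([1.0, 1.0, -1.0, -1.0, 0.0])
    zs = np.array([1.0, -1.0, -1.0, 1.0, 0.0])
    steps[0] = xs[idx]
    steps[1] = ys[idx]
    steps[2] = zs[idx]
    return np.cumsum(steps, axis=1)


def dna_walk(sequence: str) -> np.ndarray:
    """Cumulative DNA walk: +1 per pyrimidine (C/T), -1 per purine (A/G)."""
    idx = _base_indices(sequence)
    steps = np.array([-1.0, 1.0, -1.0, 1.0, 0.0])[idx]
    return np.cumsum(steps)


def paired_numeric(sequence: str) -> np.ndarray:
    """Pointwise complementarity signal: A/T -> +1, C/G -> -1, other -> 0."""
    idx = _base_indices(sequence)
    return np.array([1.0, -1.0, -1.0, 1.0, 0.0])[idx]


def tetrahedron(sequence: str) -> np.ndarray:
    """Per-base regular-tetrahedron coordinates, shape (3, n).

    Each nucleotide maps to a unit-length vertex of a regular tetrahedron;
    ambiguous bases map to the origin.
    """
    idx = _base_indices(sequence)
    vertices = np.array(
        [_TETRA["A"], _TETRA["C"], _TETRA["G"], _TETRA["T"], (0.0, 0.0, 0.0)]
    )
    return vertices[idx].T


def kmer_profile(sequence: str, table: StructuralTable) -> np.ndarray:
    """Sliding-window k-mer score profile, stride 1, length n - k + 1.

    A 600 bp window yields 598 values for trinucleotide tables and 599 for
    dinucleotide tables. Any k-mer containing an ambiguous base scores 0.
    """
    table.validate()
    k = table.kmer_size
    n = len(sequence)
    seq = sequence.upper()
    out = np.zeros(n - k + 1, dtype=np.float64)
    for i in range(n - k + 1):
        out[i] = table.scores.get(seq[i:i + k], 0.0)
    return out


def conservation_window(track: ConservationTrack, chrom: str, center: int,
                        strand: str, offset: int = 0,
                        size: int = WINDOW_SIZE) -> np.ndarray:
    """Per-base conservation over the same genomic span as the sequence
    window; uncovered positions are 0; minus strand reverses the signal."""
    half = size // 2
    start = center + offset - half
    if start < 0:
        raise WindowOutOfBounds(f"window start {start} < 0 on {chrom}")
    vals = track.values(chrom, start, start + size)
    if strand == "-":
        vals = vals[::-1].copy()
    return vals


def gsp_block(sequence: str) -> np.ndarray:
    """Stack the genomic-signal-processing encodings into a (600, 8) block.

    Channel order: Z-curve x, y, z; DNA walk; paired numeric;
    tetrahedron dims 1-3.
    """
    zc = zcurve(sequence)
    tet = tetrahedron(sequence)
    return np.column_stack([
        zc[0], zc[1], zc[2],
        dna_walk(sequence),
        paired_numeric(sequence),
        tet[0], tet[1], tet[2],
    ])


def structural_block(sequence: str,
                     bend: Optional[StructuralTable] = None,
                     propel: Optional[StructuralTable] = None) -> np.ndarray:
    """Bendability and propeller-twist profiles, zero-padded to (600, 2).

    The native profile lengths are 598 (3-mers) and 599 (2-mers); trailing
    zeros bring both channels to the shared 600 bp spatial length.
    """
    bend = bend or bendability_table()
    propel = propel or propeller_twist_table()
    n = len(sequence)
    out = np.zeros((n, 2), dtype=np.float64)
    bp = kmer_profile(sequence, bend)
    pp = kmer_profile(sequence, propel)
    out[:len(bp), 0] = bp
    out[:len(pp), 1] = pp
    return out


def featurize_peak(genome: Dict[str, str], track: ConservationTrack,
                   chrom: str, center: int, strand: str,
                   offset: int = 0,
                   bend: Optional[StructuralTable] = None,
                   propel: Optional[StructuralTable] = None) -> Optional[FeatureBundle]:
    """Build the complete FeatureBundle for one (possibly shifted) window.

    Returns None (with a warning) when the window overruns the chromosome;
    the output is always either a complete bundle or a skip, never partial.
    """
    try:
        win = extract_window(genome, chrom, center, strand, offset=offset)
        cons = conservation_window(track, chrom, center, strand, offset=offset)
    except WindowOutOfBounds as exc:
        warnings.warn(f"skipping peak at {chrom}:{center}: {exc}")
        return None
    return FeatureBundle(
        onehot=one_hot(win.sequence),
        gsp=gsp_block(win.sequence),
        structural=structural_block(win.sequence, bend, propel),
        conservation=cons.reshape(-1, 1),
    )


@dataclass
class StandardizationStats:
    """Per-channel z-score parameters for the gsp and structural blocks.

    Fit on training data only; channels with zero variance keep sd = 1 so
    standardization is a no-op there. One-hot and conservation blocks are
    never standardized.
    """

    gsp_mean: np.ndarray        # (8,)
    gsp_sd: np.ndarray          # (8,)
    structural_mean: np.ndarray  # (2,)
    structural_sd: np.ndarray    # (2,)

    def to_dict(self) -> Dict[str, list]:
        return {
            "gsp_mean": self.gsp_mean.tolist(),
            "gsp_sd": self.gsp_sd.tolist(),
            "structural_mean": self.structural_mean.tolist(),
            "structural_sd": self.structural_sd.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Dict[str, list]) -> "StandardizationStats":
        return cls(*(np.asarray(d[k], dtype=np.float64) for k in
                     ("gsp_mean", "gsp_sd", "structural_mean", "structural_sd")))


def _safe_sd(sd: np.ndarray) -> np.ndarray:
    sd = sd.copy()
    sd[sd == 0.0] = 1.0
    return sd


def fit_standardizer(bundles: Sequence[FeatureBundle]) -> StandardizationStats:
    """Fit per-channel mean/sd over all positions of all training bundles."""
    if not bundles:
        raise ValueError("cannot fit a standardizer on zero bundles")
    gsp = np.concatenate([b.gsp for b in bundles], axis=0)
    struct = np.concatenate([b.structural for b in bundles], axis=0)
    return StandardizationStats(
        gsp_mean=gsp.mean(axis=0),
        gsp_sd=_safe_sd(gsp.std(axis=0)),
        structural_mean=struct.mean(axis=0),
        structural_sd=_safe_sd(struct.std(axis=0)),
    )


def apply_standardizer(bundle: FeatureBundle,
                       stats: StandardizationStats) -> FeatureBundle:
    """Center and scale the gsp/structural channels; leave one-hot and
    conservation untouched."""
    return FeatureBundle(
        onehot=bundle.onehot,
        gsp=(bundle.gsp - stats.gsp_mean) / stats.gsp_sd,
        structural=(bundle.structural - stats.structural_mean) / stats.structural_sd,
        conservation=bundle.conservation,
    )
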
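"""Self-contained synthetic fixture: genome, CAGE tags, annotation, marks,
chromatin states, conservation and truth labels.

The generator emulates the statistical structure the classifier assumes:

* true TSSs carry a planted promoter consensus (a TATA-like element ~30 bp
  upstream of the initiation site plus an initiator element at it), each
  base degraded independently at a configurable mutation rate;
* true tag clusters are sharp — tag 5' ends fall around the planted TSS
  with geometrically decaying spread so the modal position is the TSS;
* noise clusters are diffuse (uniform over ~200 bp) over background
  sequence, far (>10 kb) from every planted TSS and outside gene bodies;
* H3K4me3 and Polymerase II peaks and an "active" chromatin state surround
  every true TSS; conservation is elevated over true promoters and zero
  elsewhere;
* cluster tag totals are negative-binomial, mimicking CAGE overdispersion.

Planted loci sit on a >= 25 kb grid so evaluation zones are unambiguous by
construction. Everything derives from one seeded generator: the same seed
reproduces the fixture byte for byte.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from cagetss import labeling as lab
from cagetss.features import featurize_peak, reverse_complement
from cagetss.io_formats import (
    ConservationTrack,
    GenomicInterval,
    read_conservation,
    read_ctss,
    read_fasta,
    read_intervals,
    write_fasta,
)
from cagetss.model import ModelConfig, TrainedModel, classify, score, train
from cagetss.peaks import CagePeak, PeakCallParams, call_peaks

BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Planted promoter grammar, as (offset relative to the TSS, base) in sense
#: orientation: a TATA-like element at -30 and an initiator spanning the TSS.
TATA_ELEMENT = "TATAAAA"
INR_ELEMENT = "TCAGTCT"
MOTIF_LAYOUT: Tuple[Tuple[int, str], ...] = tuple(
    [(-30 + i, b) for i, b in enumerate(TATA_ELEMENT)]
    + [(-2 + i, b) for i, b in enumerate(INR_ELEMENT)]
)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_chromosomes: int = 4
    n_true_tss: int = 200
    n_noise_clusters: int = 200
    gc_fraction: float = 0.41
    motif_mutation_rate: float = 0.1
    tag_mean: float = 50.0
    tag_dispersion: float = 5.0
    positional_decay: float = 0.55  # geometric spread of true tag 5' ends
    noise_width: int = 200
    mark_width: int = 2000
    gene_length: int = 5000
    conservation_height: float = 2.0
    conservation_width: int = 600
    spacing: int = 26000  # >= 25 kb keeps evaluation zones unambiguous
    margin: int = 6000

    def __post_init__(self):
        if self.n_true_tss < 0 or self.n_noise_clusters < 0:
            raise ValueError("cluster counts must be >= 0")
        if self.spacing < 25000:
            raise ValueError("spacing must be >= 25000 bp")


@dataclass(frozen=True)
class TruthRecord:
    chrom: str
    position: int
    strand: str
    cls: str  # "true_tss" or "noise"
    cluster_id: int


def _chrom_layout(config: SimulationConfig) -> Tuple[List[str], Dict[str, List[int]]]:
    """Distribute slot center positions round-robin over the chromosomes."""
    n_slots = config.n_true_tss + config.n_noise_clusters
    names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    slots: Dict[str, List[int]] = {name: [] for name in names}
    for i in range(n_slots):
        chrom = names[i % len(names)]
        k = len(slots[chrom])
        slots[chrom].append(config.margin + k * config.spacing)
    return names, slots


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return BASES[rng.choice(4, size=length, p=p)]


def _plant_motifs(seq: np.ndarray, tss: int, strand: str,
                  mutation_rate: float, rng: np.random.Generator) -> None:
    for offset, base in MOTIF_LAYOUT:
        if strand == "+":
            pos, b = tss + offset, base
        else:
            pos, b = tss - offset, _COMP[base]
        if rng.random() < mutation_rate:
            b = str(rng.choice([x for x in "ACGT" if x != b]))
        seq[pos] = b


def _cluster_total(rng: np.random.Generator, config: SimulationConfig) -> int:
    r = config.tag_dispersion
    p = r / (r + config.tag_mean)
    return max(5, int(rng.negative_binomial(r, p)))


def _true_offsets(rng: np.random.Generator, n: int, decay: float) -> np.ndarray:
    """Two-sided geometric offsets: P(|k|) ~ decay^k, decay 0 => all at 0."""
    if decay <= 0.0:
        return np.zeros(n, dtype=np.int64)
    u = rng.random(n)
    mags = np.floor(np.log(np.where(u == 0, 1e-300, u)) / np.log(decay)).astype(np.int64)
    mags = np.minimum(mags, 25)
    signs = rng.choice([-1, 1], size=n)
    return mags * signs


def _noise_offsets(rng: np.random.Generator, n: int, width: int,
                   max_gap: int = 50) -> np.ndarray:
    """Uniform offsets over [-width/2, width/2] with no internal gap larger
    than the peak-calling cluster distance, so one noise locus stays one
    peak."""
    half = width // 2
    for _ in range(50):
        offs = rng.integers(-half, half + 1, size=n)
        pos = np.unique(offs)
        if pos.size == 1 or np.max(np.diff(pos)) <= max_gap:
            return offs
    return rng.integers(-max_gap // 2, max_gap // 2 + 1, size=n)


def simulate(config: SimulationConfig, out_dir: str) -> List[TruthRecord]:
    """Write the full fixture directory and return the truth records.

    Files: genome.fa, ctss.bed, tss.bed, genes.bed, h3k4me3.bed, polii.bed,
    states.bed, conservation.bedGraph, truth.tsv.
    """
    rng = np.random.default_rng(config.seed)
    names, slots = _chrom_layout(config)
    chrom_lengths = {
        name: 2 * config.margin + max(1, len(slots[name])) * config.spacing
        for name in names
    }
    classes = np.array(["true_tss"] * config.n_true_tss
                       + ["noise"] * config.n_noise_clusters)
    rng.shuffle(classes)

    genomes: Dict[str, np.ndarray] = {
        name: _random_sequence(rng, chrom_lengths[name], config.gc_fraction)
        for name in names
    }

    truth: List[TruthRecord] = []
    tag_counts: Dict[Tuple[str, int, str], int] = {}
    cluster_id = 0
    slot_iter = [(name, pos) for name in names for pos in slots[name]]
    for (chrom, center), cls in zip(slot_iter, classes):
        strand = "+" if rng.random() < 0.5 else "-"
        if cls == "true_tss":
            _plant_motifs(genomes[chrom], center, strand,
                          config.motif_mutation_rate, rng)
        total = _cluster_total(rng, config)
        if cls == "true_tss":
            offs = _true_offsets(rng, total, config.positional_decay)
        else:
            offs = _noise_offsets(rng, total, config.noise_width)
        for off in offs:
            key = (chrom, center + int(off), strand)
            tag_counts[key] = tag_counts.get(key, 0) + 1
        truth.append(TruthRecord(chrom, center, strand, cls, cluster_id))
        cluster_id += 1

    os.makedirs(out_dir, exist_ok=True)
    write_fasta({n: "".join(genomes[n]) for n in names},
                os.path.join(out_dir, "genome.fa"))

    with open(os.path.join(out_dir, "ctss.bed"), "w") as fh:
        for (chrom, pos, strand), count in sorted(tag_counts.items()):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\tt\t{count}\t{strand}\n")

    true_records = [t for t in truth if t.cls == "true_tss"]
    with open(os.path.join(out_dir, "tss.bed"), "w") as fh:
        for t in true_records:
            fh.write(f"{t.chrom}\t{t.position}\t{t.position + 1}\t"
                     f"tss_{t.cluster_id}\t0\t{t.strand}\n")
    with open(os.path.join(out_dir, "genes.bed"), "w") as fh:
        for t in true_records:
            if t.strand == "+":
                s, e = t.position, t.position + config.gene_length
            else:
                s, e = t.position + 1 - config.gene_length, t.position + 1
            fh.write(f"{t.chrom}\t{max(0, s)}\t{e}\tgene_{t.cluster_id}\t0\t{t.strand}\n")
    half_mark = config.mark_width // 2
    for mark in ("h3k4me3", "polii"):
        with open(os.path.join(out_dir, f"{mark}.bed"), "w") as fh:
            for t in true_records:
                fh.write(f"{t.chrom}\t{max(0, t.position - half_mark)}\t"
                         f"{t.position + half_mark}\t{mark}_{t.cluster_id}\t0\t.\n")

    # chromatin states: "active" blocks over promoters, "weak" elsewhere
    with open(os.path.join(out_dir, "states.bed"), "w") as fh:
        per_chrom: Dict[str, List[Tuple[int, int]]] = {n: [] for n in names}
        for t in true_records:
            per_chrom[t.chrom].append(
                (max(0, t.position - 1000), t.position + 1000))
        for chrom in names:
            cursor = 0
            for s, e in sorted(per_chrom[chrom]):
                if s > cursor:
                    fh.write(f"{chrom}\t{cursor}\t{s}\tweak\n")
                fh.write(f"{chrom}\t{s}\t{e}\tactive\n")
                cursor = e
            if cursor < chrom_lengths[chrom]:
                fh.write(f"{chrom}\t{cursor}\t{chrom_lengths[chrom]}\tweak\n")

    half_cons = config.conservation_width // 2
    with open(os.path.join(out_dir, "conservation.bedGraph"), "w") as fh:
        for t in true_records:
            fh.write(f"{t.chrom}\t{max(0, t.position - half_cons)}\t"
                     f"{t.position + half_cons}\t{config.conservation_height!r}\n")

    with open(os.path.join(out_dir, "truth.tsv"), "w") as fh:
        fh.write("chrom\tposition\tstrand\tclass\tcluster_id\n")
        for t in truth:
            fh.write(f"{t.chrom}\t{t.position}\t{t.strand}\t{t.cls}\t{t.cluster_id}\n")
    return truth


def load_truth(path: str) -> List[TruthRecord]:
    out: List[TruthRecord] = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            chrom, pos, strand, cls, cid = line.split()
            out.append(TruthRecord(chrom, int(pos), strand, cls, int(cid)))
    return out


def match_truth(peak: CagePeak, truth: Sequence[TruthRecord],
                radius: int = 500) -> Optional[TruthRecord]:
    """The truth record whose planted center is nearest the peak
    representative (same chromosome, within ``radius``), if any."""
    best, best_d = None, radius + 1
    for t in truth:
        if t.chrom != peak.interval.chrom:
            continue
        d = abs(t.position - peak.representative)
        if d < best_d:
            best, best_d = t, d
    return best


def _featurize_examples(examples, genome, track, bend=None, propel=None):
    bundles, labels, kept = [], [], []
    for ex in examples:
        bundle = featurize_peak(
            genome, track, ex.peak.interval.chrom, ex.peak.representative,
            ex.peak.interval.strand, offset=ex.offset)
        if bundle is not None:
            bundles.append(bundle)
            labels.append(ex.label)
            kept.append(ex)
    return bundles, labels, kept


def end_to_end_check(fixture_dir: str,
                     model_config: ModelConfig = ModelConfig(),
                     peak_params: PeakCallParams = PeakCallParams(),
                     labeling_params: lab.LabelingParams = lab.LabelingParams(),
                     val_chroms: frozenset = frozenset({"chr3"}),
                     test_chroms: frozenset = frozenset({"chr4"}),
                     cutoff: float = 0.9,
                     use_conservation: bool = True) -> Dict[str, object]:
    """Run the whole pipeline on a fixture directory and measure it.

    call_peaks -> label_peaks -> augment -> train -> score the held-out
    chromosome's centered windows -> evaluate. Returns held-out AUROC,
    precision and sensitivity at the score cutoff, and the trained model.
    """
    from sklearn.metrics import roc_auc_score

    genome = read_fasta(os.path.join(fixture_dir, "genome.fa"))
    tags = read_ctss(os.path.join(fixture_dir, "ctss.bed"))
    tss = read_intervals(os.path.join(fixture_dir, "tss.bed"))
    k4 = read_intervals(os.path.join(fixture_dir, "h3k4me3.bed"))
    pol = read_intervals(os.path.join(fixture_dir, "polii.bed"))
    genes = read_intervals(os.path.join(fixture_dir, "genes.bed"))
    cons_path = os.path.join(fixture_dir, "conservation.bedGraph")
    track = read_conservation(cons_path if use_conservation else None)
    if not track.enabled and "conservation" in model_config.enabled_branches:
        enabled = tuple(b for b in model_config.enabled_branches
                        if b != "conservation")
        model_config = replace(model_config, enabled_branches=enabled)

    peaks = call_peaks(tags, peak_params)
    labeled = lab.label_peaks(peaks, tss, k4, pol, genes, labeling_params)
    examples = lab.make_examples(labeled, labeling_params.offsets)
    train_ex, val_ex, test_ex = lab.chromosome_split(
        examples, set(test_chroms), set(val_chroms))
    # held-out peaks are scored on their centered window only
    test_ex = [e for e in test_ex if e.offset == 0]

    tr_bundles, tr_labels, _ = _featurize_examples(train_ex, genome, track)
    va_bundles, va_labels, _ = _featurize_examples(val_ex, genome, track)
    te_bundles, te_labels, te_kept = _featurize_examples(test_ex, genome, track)

    model = train(tr_bundles, tr_labels, va_bundles, va_labels, model_config)
    probs = score(model, te_bundles)
    auroc = float(roc_auc_score(te_labels, probs))

    from cagetss.evaluation import build_zones, classify_predictions, sensitivity

    test_tss = [iv for iv in tss if iv.chrom in test_chroms]
    zones = build_zones(test_tss)
    calls = classify(probs, cutoff)
    predicted = [e.peak for e, c in zip(te_kept, calls) if c == 1]
    report = classify_predictions(predicted, zones, k4)
    n_pos = sum(te_labels)
    return {
        "auroc": auroc,
        "precision": report.precision,
        "sensitivity": sensitivity(report, n_pos) if n_pos else float("nan"),
        "n_peaks": len(peaks),
        "n_train": len(tr_bundles),
        "n_val": len(va_bundles),
        "n_test": len(te_bundles),
        "n_test_positive": int(n_pos),
        "report": report,
        "model": model,
        "test_labels": list(te_labels),
        "test_scores": probs,
        "test_peaks": [e.peak for e in te_kept],
        "predicted_positive": predicted,
    }
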
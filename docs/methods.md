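# Methods

## Peak calling

Collapsed CAGE 5'-tag positions are clustered per (chromosome, strand) by
single linkage along the genome: two positions belong to the same peak iff
their gap is at most `cluster_distance` bp (default 50, inclusive),
transitively. The peak interval spans [min position, max position + 1).
Expression is tags per million, tpm = count · 10⁶ / library size, where
the library is every quality-passing tag (normalization precedes the tpm
filter, default cutoff 1). The representative is the arg-max of the
per-position 5'-tag count; ties break to the smallest genomic coordinate,
which makes the result independent of input order. Strands are never
merged. The mapping-quality filter (default 10) applies only in the
optional alignment adapter; ctss inputs are assumed pre-filtered.

## Feature encodings

All encodings operate on the 600 bp window centered on the (possibly
shifted) representative. Minus-strand windows are reverse-complemented,
and their conservation signal reversed, so the network always sees the
sense orientation. Ambiguous bases (N, IUPAC codes) contribute zeros in
every encoding — a neutral value for centered, standardized signals.

* **Z-curve** (cumulative, per prefix of length n with base counts
  Aₙ…Tₙ): xₙ = (Aₙ+Gₙ)−(Cₙ+Tₙ) separates purines from pyrimidines,
  yₙ = (Aₙ+Cₙ)−(Gₙ+Tₙ) amino from keto bases, zₙ = (Aₙ+Tₙ)−(Gₙ+Cₙ) weak
  from strong hydrogen bonding. The identity Aₙ = (xₙ+yₙ+zₙ+mₙ)/4, with
  mₙ the number of unambiguous bases in the prefix, is exploited as a
  cross-check in the tests.
* **DNA walk**: cumulative sum of +1 per pyrimidine and −1 per purine.
  The per-step mapping ignores the previous base; the signal itself is a
  walk (cumulative), and equals −xₙ on unambiguous sequence.
* **Paired numeric**: pointwise A/T → +1, C/G → −1. The polarity is a
  configuration constant; complementary bases share a value, so
  reverse-complementing a sequence reverses the signal — a property the
  tests rely on.
* **Tetrahedron**: each base maps to a unit-length vertex of the
  cube-inscribed regular tetrahedron, A = (1,1,1)/√3, C = (−1,−1,1)/√3,
  G = (−1,1,−1)/√3, T = (1,−1,−1)/√3 (pairwise dot products exactly
  −1/3). Coordinates are a fixed convention; any rigid rotation would be
  equivalent.
* **Structural profiles**: sliding k-mer lookup, stride 1, from the
  shipped trinucleotide DNase-I bendability table (Brukner et al. 1995;
  32 reverse-complement-symmetric values) and dinucleotide propeller-twist
  table (el Hassan & Calladine 1996; degrees). A 600 bp window yields 598
  and 599 values; both channels are end-padded with trailing zeros to the
  shared spatial length of 600 so all branches convolve over the same
  axis. The tables are plain 2-column text files and injectable; every
  windowing test is table-agnostic.
* **Conservation**: raw per-base scores (e.g. phyloP) over the window;
  positions without a score are 0 and the track is never standardized.
  When no conservation file is supplied the corresponding branch is
  dropped from the network.

GSP and structural blocks are z-scored per channel with mean/sd fit on
the training set only; channels with zero variance keep sd = 1. The
statistics are persisted with the model and applied at every scoring
call; scoring without matching statistics is impossible by construction.
Per-channel (rather than per-branch-global) standardization was the open
design choice; it is recorded with the model.

## Training-set construction

With defaults: a peak is **positive** iff its representative lies within
1 kb of an annotated protein-coding TSS *and* the peak overlaps at least
one H3K4me3 peak *and* one Polymerase II peak. Peaks whose representative
falls in the (1 kb, 10 kb] band around any TSS are **removed entirely**,
so promoter-flanking signal never contaminates the negative set. Peaks
overlapping either mark without satisfying the positive rule are also
removed. **Negatives** are intergenic peaks (no gene-body overlap)
touching neither mark; everything else is excluded. Distance is unsigned
representative-to-TSS bp; overlap means ≥ 1 bp intersection. The two
removal rules are both enforced; their relative precedence only matters
for peaks that multiple rules would discard anyway.

Each retained peak is augmented with shifted windows at offsets
{−100, −75, −50, −25, 0, +25, +50, +75} bp — seven additional windows per
representative, chosen so the count of extra windows is exactly 7 (a
closed −100..+100 range at 25 bp stride would give 8). Splits are by
whole chromosome (defaults chr14 validation, chr15 test on real data;
synthetic fixtures hold out their own chromosomes), so augmented siblings
can never leak across partitions. At inference only the centered window
is scored.

## Network and optimization

One branch per feature family; two valid (unpadded, stride-1) 1-D
convolutions per branch, each followed by leaky ReLU (slope 0.01) and
then batch normalization, in that order. Sequence/GSP/structural branches
use 20/10 filters with kernels 16/12; the conservation branch 32/16
filters with kernels 16/8. No pooling; branch outputs are flattened,
concatenated, and passed through dense layers of 120/60/25 units (leaky
ReLU, batch norm, dropout 0.2 after each) to a single sigmoid output.
Loss is binary cross-entropy; the optimizer Adam at 0.001 with batch size
256, at most 60 epochs, early stopping with patience 10 on validation
loss and restoration of the best-validation weights. The published
hyperparameter grid (filters {20,30,40}, kernels {20/15,16/12,12/8},
dense {140/80/40,120/60/25,100/60/20}, lr {0.01,0.001,0.0005,0.0001},
batch {64,...,512}, dropout {0.2..0.35}) is exposed via
`GRID_SEARCH_SPACE` but not exercised by the tests.

The network is implemented directly in NumPy (im2col convolutions over
BLAS matmuls, float32 throughout). All randomness — initialization,
shuffling, dropout — flows through one seeded generator, so a seed plus a
dataset reproduces the training history exactly. Inference uses batch
normalization's running statistics with dropout off, making scores
deterministic and batch-order invariant (up to float32 accumulation,
~1e-4 relative). A non-finite loss aborts training with diagnostics
rather than continuing silently.

## Evaluation

Zones are built per annotated TSS: positive [p−500, p+501), negative
[p−50000, p−500) ∪ [p+501, p+50001), clipped at 0. Zone membership is
decided by the 1 bp representative; positive membership takes precedence
wherever zones of different TSSs overlap. A negative-zone prediction is
rescued to TP when its full peak interval overlaps an H3K4me3 peak —
zones are point-centered, rescue is phrased as overlap, hence the
asymmetric convention (flagged as interpretive). Predictions outside both
zones are counted separately and excluded from precision. The
sensitivity denominator is supplied by the caller (benchmark positive
peaks, or total genes in gene-oriented mode), since no universal formula
exists. Genes with several TSSs count once however many of their TSSs are
hit.

## The synthetic study

`simulate` plants `n_true_tss` promoters and `n_noise_clusters` noise
loci on a ≥ 25 kb grid (so evaluation zones never collide) across four
chromosomes, strands uniform. True promoters carry a TATA-like element
(TATAAAA) 30 bp upstream and an initiator (TCAGTCT) at the TSS, each base
mutated independently at `motif_mutation_rate` (default 0.1); background
composition is 41% GC. Cluster tag totals are negative-binomial (mean 50,
dispersion 5) to mimic CAGE overdispersion — at the resulting library
sizes (~10⁴–10⁵ tags) the default 1-tpm filter keeps essentially every
cluster. True-cluster tag offsets decay geometrically around the TSS
(decay 0.55; decay 0 puts all mass on the mode), noise offsets are
uniform over ~200 bp with internal gaps capped below the clustering
distance so one locus stays one peak. Each true TSS also receives
H3K4me3 and Pol II peaks (±1 kb), a 2 kb "active" chromatin-state block,
a gene body (5 kb downstream) and a ±300 bp conservation block of height
2.0 emitted as bedGraph (text, so the test path needs no binary writers).

What the generator does *not* emulate: realistic promoter grammar beyond
the two planted elements, CpG islands, mapping artifacts, replicate
structure, or expression-dependent noise. Passing tests therefore
demonstrate the pipeline's mechanics and the model's ability to exploit
the planted signal families — not performance on real CAGE and ChIP-seq
data, whose class boundaries are far subtler.

## Desk-scale problem sizes

The learning-sanity checks run on a fixture of 200 true + 200 noise
clusters (motif mutation rate 0.1). The main check trains the default
architecture with windows at offsets {−50, 0, +50} for 5 epochs
(patience 2) and requires held-out AUROC ≥ 0.90; with conservation and
mark-correlated labels the planted classes separate within these few
epochs. The branch-ablation comparison (all four branches vs.
sequence-only, 3 seeds) uses centered windows and up to 30 epochs with
patience 8. These sizes are the package's chosen desk-scale study
conditions; the full augmentation set and 60-epoch schedule remain the
defaults for real data. On synthetic data the all-branch model saturates
(AUROC ≈ 1.0) because conservation alone separates the planted classes;
the sequence-only model, trained on only ~200 centered windows, learns
little of the motif signal — the ablation check asserts the ordering, not
the gap.

## Degenerate inputs and tie-breaks

Empty tag lists yield empty peak lists; an empty TSS annotation is a
labeling error (nothing can be labeled). Windows overrunning a chromosome
end are skipped with a warning — a peak either yields a complete feature
bundle or none. Representative ties break leftmost; zone precedence is
positive-wins; zero-variance standardization channels pass through
unchanged. Scores written to BED keep full float precision so round-trips
are lossless.

## Known limitations

* The NumPy network targets desk-scale data; a 40k-peak genome-wide run
  is feasible (minutes for inference) but training on genome-scale
  augmented sets would take hours on one CPU.
* Only the centered window is scored at inference; averaging over shifted
  windows is a possible, unimplemented variant.
* BigWig conservation requires pyBigWig; bedGraph is the text fallback.
* The structural tables are fixed published sets; alternative scales can
  be injected but no provision is made for k > 3.
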
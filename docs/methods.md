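# Methods

## Problem and model

An *active G4 region* is a ~201-bp stretch of DNA that forms a
G-quadruplex both in purified DNA (in vitro) and in chromatin (in vivo) in
a given cell type. Sequence alone predicts in-vitro folding well, but
in-vivo activity also depends on chromatin state; the model therefore
fuses two inputs: the one-hot 201×4 sequence matrix and the window's mean
chromatin accessibility.

The network is a fixed-topology CNN: 1-D valid convolution (900 kernels,
width 20 bp, ReLU) → non-overlapping local average pooling (width 12) →
global max pooling per kernel → concatenation of the accessibility scalar
→ dropout (rate 0) → dense(100, ReLU) → dense(1, sigmoid), trained with
binary cross-entropy and RMSprop (lr 1e-3, ρ 0.9, ε 1e-7) for 20 epochs
with batch size 128. With the default geometry the convolution yields
182 positions per kernel, pooling 15 windows, and the fused feature vector
has length 901 (900 for the sequence-only ablation). The hyperparameters
are treated as fixed constants of the architecture; the package performs
no hyperparameter search.

Assumptions baked into the architecture: a G4 region is detectable as a
*bag of short motifs* — average pooling merges contiguous kernel hits so
that a run of small G-stretch motifs (e.g. GGGNNNGGG twice with a short
gap) behaves like one detector firing; position within the window carries
no meaning beyond that (global max); and accessibility acts as a single
region-level covariate rather than a base-resolution signal.

### Implementation note

The forward and backward passes are written directly against NumPy/BLAS
(im2col plus matrix products, hand-derived gradients) in `g4net.nn`. The
network is small enough that this trains in seconds to minutes on one CPU,
keeps every source of randomness under a single `numpy` Generator seed,
and makes training bit-reproducible on a given platform. A per-position
loop implementation of the conv→pool→max chain serves as an independent
numerical oracle in the tests (agreement ≤ 1e-5).

### Conventions chosen where the design was open

- **Convolution padding**: valid (no padding), so every kernel placement
  lies fully inside the window — consistent with reading kernels as motif
  detectors.
- **Pooling stride**: equal to pool width (non-overlapping), the common
  default, matching the motif-aggregation reading above.
- **Accessibility normalisation**: the raw mean signal is divided by the
  99th percentile of the *positive training examples'* means and clipped
  to [0, 1]; the divisor is stored in the model bundle and re-applied at
  prediction time, so models transfer across assays with different signal
  scales (DNase vs ATAC).
- **Strand**: windows are always read from the reference strand; no
  reverse-complement augmentation. The scoring task is not strand-specific
  and complementary motifs are merged later by motif clustering.
- **Unknown bases**: letters outside ACGT one-hot-encode as all-zero rows
  (the convolution stays defined); training windows with > 10% ambiguous
  bases are excluded; scan bins ≥ 90% ambiguous are emitted flagged with
  score 0.
- **Scan anchoring**: a 200-b bin is scored on the 201-bp window starting
  at the bin start (1 bp right overhang), so bins tile deterministically
  from coordinate 0; chromosome-end windows are N-padded.
- **Decision threshold**: accuracy and FDR default to threshold 0.5,
  configurable; AUROC/AUPR are threshold-free.
- **Determinism**: weight initialisation, epoch shuffling, dropout masks,
  dataset shuffling/splitting and all samplers derive from one integer
  seed. Saving and re-loading a model reproduces predictions
  bit-identically on the same platform.

## Dataset construction

Positives: in-vivo peaks (narrowPeak; summit = start + column 10, interval
midpoint when no summit is recorded) are kept when the *original peak
interval* overlaps any in-vitro peak by ≥ 1 bp, then a 201-bp window is
taken around the summit. Windows that would cross a chromosome edge are
dropped with a warning. Replicate peak lists can be concatenated and
deduplicated at 50% reciprocal overlap; in-vitro peaks are used as-is.

Negatives: rejection sampling. For each positive, windows of the same
length are drawn uniformly from the genome (chromosomes weighted by
length) and accepted when GC fraction matches within ±0.02, repeat
fraction within ±0.05, and the window overlaps no positive; after 5,000
failed draws the closest-GC non-overlapping candidate is used (logged).
Repeat fraction uses an explicit mask when supplied (e.g. a Tandem Repeat
Finder track) and otherwise the soft-masked (lowercase) fraction of the
raw reference slice, which keeps the sampler self-contained on arbitrary
genomes. Train/validation/test fractions default to 0.8/0.1/0.1 and
negatives to 1:1 with positives; both are configurable.

## From kernels to motifs

For each kernel, activations (post-ReLU convolution outputs) are computed
over the positive sequences; each sequence with any activation > 0
contributes the kernel-width subsequence at its maximum (leftmost on
ties). Those best hits give a position frequency matrix (non-ACGT letters
excluded per column); kernels with fewer than 10 hits are skipped. Flank
columns with information content ≤ 0.9 bits (IC = 2 + Σ p log₂ p) are
trimmed from each side inward; motifs narrower than 5 columns after
trimming are discarded. PWMs are log₂((f + 0.01)/(0.25 + 0.01)) — uniform
background, pseudocount 0.01, both configurable. The 0.9 threshold is
interpreted in bits (the logo/JASPAR convention).

**Similarity**: for two PWMs, all ungapped offsets and both orientations
are scanned; `cor` is the best Pearson correlation of the flattened
aligned columns and `ncor` the best correlation × (aligned width /
max width). Zero-variance alignments score 0. The reported offset/strand
belong to the ncor-maximising alignment, which is the quantity clustering
gates on.

**Clustering**: agglomeration on distance 1 − ncor with median linkage
over cross-pair values; a merge happens only while some cluster pair has
median cor ≥ 0.6 *and* median ncor ≥ 0.6. The **cluster centre is the
medoid member** — the member PWM with the highest median ncor to its
co-members. An aligned frequency average across members is also attached
(`average_pfm`), but it is deliberately *not* the centre: G-rich kernel
motifs differ chiefly in where their loops sit, and averaging across
incompatible loop phases converges on a featureless all-G matrix that
represents none of the members; the medoid keeps a real, realisable motif
as the cluster's face. Exact reproduction of external tree-merging
clustering tools is out of scope; this construction reproduces the
median-linkage / dual-gate semantics of their published parameters.

## Motif analysis

- **Best hit score**: max over positions and strands of summed log-odds;
  ambiguous bases contribute the background score 0.
- **Variable importance**: a bagging ensemble of 500 sqrt-feature decision
  trees on the motif-score table; importance = mean drop in out-of-bag
  accuracy when one motif's column is permuted, averaged over trees.
- **Consensus and G-stretches**: per-column argmax (ties by fixed order
  A<C<G<T); GG+ stretches are maximal G-runs of length ≥ 2 in the
  consensus.
- **Canonical G4 matcher**: regex `G{3,}(N1–7 G{3,})×3` with greedy runs,
  leftmost non-overlapping matches, plus the C-rich complement pattern
  reported as the minus strand.
- **Enrichment profiles**: fraction of anchors whose motif hit
  (score ≥ 80% of the motif's maximum achievable score, configurable)
  covers each offset in ±flank around the anchor summit/midpoint; hits are
  counted per covered base. Anchors too close to a chromosome edge are
  dropped and counted.
- **Embedding**: classical (Torgerson) metric MDS on 1 − correlation,
  top-2 eigenspace, sign fixed by making each axis's largest-magnitude
  loading positive. Hand-written because the eigendecomposition form is
  deterministic, unlike iterative stress minimisers.

## Synthetic data: what it emulates and what it does not

`generate_dataset` plants one realisation of
`G{3,4}N{1,7}G{3,4}N{1,7}G{3,4}N{1,7}G{3,4}` (uniform over run lengths and
loop letters) at the window centre of every positive; negatives are i.i.d.
background at the configured GC (default 0.41, human-like). Accessibility
is truncated-normal at 0 with class means 0.8 (positives) / 0.2
(negatives) and sd 0.15. In *interaction* mode the positive label requires
motif AND high accessibility, and the negative class mixes motif/low,
no-motif/high and no-motif/low in equal parts — the regime in which the
accessibility input is provably informative and the sequence-only ablation
must fall behind. `generate_toy_genome` writes a complete file bundle
(FASTA, summit-bearing narrowPeak, in-vitro BED including decoy
in-vitro-only sites, accessibility bedGraph, ground-truth BED) with
byte-identical output per seed; defaults are 2 chromosomes × 150 kb.

What passing on these fixtures does **not** show: real G4 ChIP-seq peaks
have biased loop-length distributions, flanking sequence context, repeat
structure and assay noise that the generator does not model; negatives in
real genomes are not i.i.d.; and real accessibility is a continuous track
correlated with many confounders. Synthetic results demonstrate that the
machinery is correct and that the architecture can exploit both inputs —
not that a given AUROC will transfer to any particular cell line.

## Problem sizes in the shipped checks

The test-suite and `scripts/acceptance.py` train reduced models — 128
kernels/20 epochs on 4,000 sequences for discrimination and motif
recovery, 64 kernels/10 epochs for the three-seed ablation pair, 32
kernels for the permuted-label null — and use a 2-Mb, 1,000-positive toy
genome for the matched-negative check. These sizes were chosen so the full
suite runs in about a minute on one CPU while leaving every measured
property far from its decision boundary; the full 900-kernel architecture
changes capacity, not any of the mechanisms under test.

## Known limitations

- The accessibility input is a single scalar per window; base-resolution
  accessibility shape is not used.
- Scan windows anchor at bin starts rather than centring on bins; scores
  near bin edges describe mostly-rightward context.
- Motif clustering is greedy agglomeration with a dual gate, not a full
  tree-merging reimplementation of external matrix-clustering tools;
  cluster counts may differ from those tools on the same input.
- The permutation-importance ensemble uses bagged sqrt-feature trees
  (exposing bootstrap indices for true OOB evaluation) rather than a
  stock random-forest class.
- Training is CPU-bound NumPy; the full 900-kernel model on hundreds of
  thousands of windows is feasible but slow (hours, not seconds).
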
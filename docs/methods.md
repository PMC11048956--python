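# Methods

This note documents the models, procedures and design choices behind
`resplice`, in the order the pipeline runs them.

## Dataset construction

Splice sites are read off forward-strand exon chains in a GFF3 annotation
(1-based inclusive coordinates): for every transcript with ≥ 2 exons, the
intron between consecutive exons contributes one donor at its first base
and one acceptor at its penultimate base (the first base of the terminal
AG). Reverse-strand features are skipped — the forward-strand restriction
keeps window orientation unambiguous; reverse-strand sites would require
reverse-complementing windows and are out of scope. All annotated
transcripts contribute; duplicate sites from overlapping isoforms are
collapsed on (contig, type, position). Non-canonical dinucleotides (e.g.
GC-AG introns) are retained and flagged rather than discarded.

Windows take `flank` nt on each side of the site dinucleotide
(default 200 → 402 nt, site at 1-based window positions 201–202). Windows
that overrun a contig or contain N are rejected with a recorded reason —
the encoder is strictly 4-letter, and imputing N would inject signal.

**Negatives** are genome-wide forward-strand occurrences of the canonical
dinucleotide (GT for donor models, AG for acceptor models) that are not
annotated sites of that type and admit a valid window. This
dinucleotide-matched design forces the classifier to learn context, not
the trivial core. Mining is genome-wide rather than restricted to genic
regions — the simplest universe consistent with "non-site sequences that
satisfy the GT-AG rule"; a genic-only variant can be had by passing a
restricted exclusion/genome. Sampling is uniform without replacement,
seeded.

Exact-duplicate window strings are removed (first occurrence kept) before
balancing; the larger class is then subsampled to the smaller, and each
class is split 60/15/25 into train/validation/test with identical
per-class counts, so every partition is balanced within ±1 example. One
seed drives subsampling, splitting and shuffling.

One-hot encoding maps A, T, G, C to the four unit rows in that column
order; labels map splice site → [1, 0], non-site → [0, 1].

## Network

The architecture is a five-stage 1-D residual CNN with efficient channel
attention, built for 402×4 inputs (see `resplice.model` docstrings for the
exact layer order). Three structural choices matter:

* **stride-1 convolutions everywhere**, with downsampling done by
  non-overlapping average pooling (floor semantics) — pooling after
  feature extraction discards less positional information than strided
  convolution;
* **delayed downsampling** — stage 2 pools with window 1 (no-op); pooling
  starts at stage 3 (windows 3, 4, 4), giving per-stage lengths
  402, 402, 134, 33, 8;
* **ECA gates** — global average pooling over positions gives a channel
  descriptor, a bias-free 1-D convolution across channels (kernel
  k = t if odd else t+1, t = ⌊(log₂C + b)/γ⌋ with γ = 2, b = 1, i.e.
  k = 3, 5, 5 for C = 64, 128, 256) and a sigmoid produce per-channel
  gates in (0, 1) multiplying the residual branch output.

Block internals are pinned as: two convolutions per block in
pre-activation order (BN → ReLU → Conv), the ConvBlock pooling between its
two convolutions, the ECA gate after the second convolution and before the
additive merge, and a ConvBlock shortcut of 1×1 convolution followed by
the same pooling (no shortcut BN). Among the layouts consistent with the
block description above, this is the one whose analytic parameter and
FLOP totals jointly land on 2.66 M and 0.34 G; requiring both to match at
once is what pins down the remaining freedom in the layout.

### Cost accounting

`cost_report` is a pure function of the spec: parameters are
K·C_in·C_out + C_out per convolution (bias included), C_in·C_out + C_out
for the dense head, 4 per batch-norm channel (scale, shift and the moving
mean/variance, matching what deep-learning frameworks print as "total
params"), and k per ECA gate. FLOPs count 2 · output_positions · K · C_in
· C_out per convolution plus 2 · C_in · C_out for the dense head
(multiply-accumulate = 2 FLOPs; pooling, BN and activations excluded —
the dominant profiler convention). Counting BN as 2 rather than 4
parameters per channel changes the total by 0.004 M and does not move the
rounded figure. The test suite checks the analytic totals against an
instantiated network on random small specs and on the default spec.

### NumPy implementation

Forward and backward passes for every layer (convolution via im2col,
batch normalization, ReLU, average pooling, ECA, global average pooling,
dense) are implemented in `resplice.nn` with activations of shape
(batch, length, channels). One gradient engine serves training,
input-gradient attribution and Grad-CAM. Gradients were verified against
finite differences (directional derivatives, float64) to ~1e-9 relative
error. Activations and weights are float32; batch-norm inference mode uses
moving statistics (momentum 0.9, ε = 1e-3), which makes the attribution
target function deterministic.

## Training protocol

Categorical cross-entropy; SGD with Nesterov momentum 0.9 (the protocol
fixes Nesterov but leaves the coefficient open; 0.9 is the near-universal
default); initial learning rate 0.01 halved at epoch
boundaries 5, 10, 15 (epochs 1–5 at 0.01, 6–10 at 0.005, …); batch 64;
20 epochs; the epoch with the highest validation **accuracy** supplies the
final weights (accuracy is the scoreboard metric throughout, so it is
also the checkpoint criterion). Each configuration trains
`repeats` = 3 independent runs (fresh seeded initialization and shuffling)
whose results are averaged. Weight init is He-normal for convolutions and
Glorot-uniform for the dense head.

The per-stage grid search enumerates each stage's (N, K, P) grid with the
other stages held fixed — not the Cartesian product across stages — under
a reduced training budget (epochs / max examples), scoring by validation
accuracy with ties broken toward fewer parameters, then first-seen order.
A precomputed score table can stand in for training, which is how the
selection logic is unit-tested at full grid size.

## Evaluation

Accuracy, precision, sensitivity, specificity, F1 (= harmonic mean of
precision and sensitivity) and error rate (= 1 − accuracy) derive from the
confusion matrix with splice site as the positive class and predicted
labels from the softmax argmax (threshold 0.5). A metric with a zero
denominator is reported as undefined, never silently 0. AUC comes from the
ROC curve of the site probability (equal to the Mann–Whitney statistic
with ties counted ½; tested against an O(n²) pairwise oracle). Percentages
print with 2 decimals. Cross-organism evaluation applies an A-trained
model to B's test split after checking window-geometry compatibility, and
tags the report (train=A, test=B).

## Interpretation

**Attribution.** Contribution scores follow the reference-difference
contract: per input, scores sum to f(x) − mean f(reference), f being the
pre-softmax site logit. They are computed as expected gradients: for each
reference r, an integrated gradient (x − r) ⊙ ∫₀¹ ∇f(r + α(x − r)) dα with
an n_steps-point midpoint quadrature, averaged over references. This is an
in-house implementation of the same reference-difference family as
DeepSHAP-style explainers, exact for linear models and within quadrature
error otherwise. Defaults: 100 dinucleotide-shuffled versions of each
input (Altschul–Erickson Eulerian-walk shuffle — preserves mono- and
dinucleotide composition, destroys position) and 64 steps; analyses in the
tests and examples use 8 references × 16 steps, which leaves the
importance *profile* stable while loosening per-sequence completeness (a
violation beyond tolerance raises a diagnostic warning, and the report
stays attached to the result). The completeness tolerance is 5% relative.

**Weighted scores.** Raw scores are L1-normalized per sequence (divided by
the sum of absolute scores, signs kept) so sequences contribute on a
common scale; other normalizations are conceivable, so the choice is
isolated behind one function (`normalize_weighted`) and easy to swap.

**Profiles and tracks.** Position importance is the mean absolute weighted
score of the realized base per position; base-set tracks (e.g. G+C vs
T+A) average realized-base scores over sequences whose base at that
position belongs to the set; IUPAC motif tracks (e.g. CTNA, AG) average
the motif's summed realized scores over occurrences anchored at their
first position, with NaN where a motif never occurs.

**Grad-CAM.** Channel weights are position-averaged gradients of the
class logit w.r.t. the final convolutional layer's feature maps; the ReLU
of the weighted channel sum is linearly interpolated from the final conv
length (8 under the default spec — a deliberate resolution limit) to the
window length and min–max normalized per sequence before dataset
averaging; flat maps are flagged and left zero.

**Conservation.** Per-position nucleotide frequencies and information
content R = 2 − H bits (Shannon, base 2), with the small-sample logo
correction e(n) = 3/(2n ln 2) available but off by default. Cosine
similarity compares importance and conservation profiles; the tests
require the trained model's profile to beat a position-shuffled control.

## Synthetic genome simulator

The simulator emits forward-strand gene models on uniform-background
contigs, planting every feature the interpretation module is meant to
recover: a donor context MAG|GTAAGT and acceptor context YAG|G sampled
from position-weight matrices (GT/AG cores fixed; a configurable fraction
of donors — default 1% — becomes GC-AG to exercise the non-canonical
path), a 12-nt polypyrimidine tract at 85% pyrimidine directly upstream of
the acceptor YAG, a CTNA branch-point motif 20–40 nt upstream of the
acceptor, and a G+C step (exons 0.55, introns 0.35, intergenic 0.45).
Ground truth (all planted sites and gene structures) is emitted alongside
and must round-trip exactly through the dataset module's GFF3 derivation.

Two generator defaults are calibration choices and worth stating
explicitly:

* **Site density.** Intergenic gaps default to a rice-like ~1 donor per
  5 kb. In a maximally gene-dense miniature genome, a large fraction of
  dinucleotide-matched negative windows contain a *true* donor context a
  few dozen nt off-centre; a network whose head is global average pooling
  is largely translation-invariant and cannot reject such decoys from a
  few thousand examples, which caps separability for reasons that say
  nothing about real genomes.
* **Motif sharpness.** The planted consensus is dominant (0.80–0.96 at
  informative positions) rather than natural-frequency. At the fixture's
  sample sizes (~2,400 training windows vs tens of thousands in real
  datasets) a natural-frequency motif is under-determined; the dominant
  consensus makes the fixture separable (validation AUC ≥ 0.95 for the
  width-reduced model) so that pipeline defects are distinguishable from
  sample-size effects.

What the simulator does **not** emulate: codon structure and hexamer
composition of real exons, splice-site strength variation and alternative
splicing, branch-point distance distributions, repeats, chromatin- or
expression-linked biases, reverse-strand genes. Passing the planted-motif
tests therefore demonstrates that the pipeline, architecture, training
loop and attribution machinery work end to end — not that the model would
reach any particular accuracy on a real genome.

The "unrelated organism" variant swaps in disjoint context PWMs
(TTC|GTCGCG donors, GAG|T acceptors), removes the PPT enrichment and
branch motif, and flattens the G+C landscape, so only the invariant GT/AG
cores are shared; transfer accuracy to it is expected at chance, versus
near-parity for a same-parameters organism. This mirrors the
similar-vs-distant species pattern qualitatively.

## Problem sizes and numerical choices

* Fixtures: "tiny" ≈ 400 examples (68 genes), "small" ≈ 4,000 (660
  genes); the tests train the width-reduced spec (stem 8; stages
  8/16/16/32 — same depth, kernels and pooling) for 10 epochs on "small",
  and the full-width settings remain available in configs for larger
  machines.
* Average pooling truncates remainders (floor); 'same' padding keeps the
  stem length at 402.
* Splits: per-class counts are rounded (train, validation) with the test
  partition absorbing the remainder; partitions are disjoint by
  construction.
* Ties in the ROC curve are handled by scikit-learn's curve construction;
  AUC integrates by trapezoid.
* Seeds: every stochastic component (simulator, sampling, splitting,
  initialization, shuffling, attribution references) flows from explicit
  integer seeds; fixed seed ⇒ byte-identical simulator output and
  reproducible training.

## Known limitations

* The NumPy engine is single-threaded except through BLAS; full-width
  20-epoch training on real-genome-scale datasets is out of its intended
  range.
* Batch-norm inference statistics come from training-time moving
  averages; very short runs (1–2 epochs) evaluate with partially
  converged statistics.
* Expected-gradients completeness degrades on sharply nonlinear trained
  models at few quadrature steps; the diagnostic report quantifies it per
  sequence.
* Grad-CAM's positional resolution is bounded by the final conv length
  (8 cells for 402 nt).
* Reverse-strand sites, alternative flank lengths as defaults, and
  RNA-seq-based site discovery are out of scope.
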
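# Methods

## Problem and model

`histmark` predicts, for fixed 200-bp genomic windows, which of seven
histone marks (H3K4me1, H3K4me3, H3K27me3, H3K36me3, H3K9me3, H3K9ac,
H3K27ac) the window carries in a given epigenome. The predictor integrates
two inputs over a 1000-bp region centred on the window:

- **sequence**: one-hot encoded DNA (rows A, C, G, T; ambiguous bases as
  all-zero columns, preserving the binary-matrix property);
- **accessibility**: a per-base openness score equal to the fold enrichment
  of the covering DNase-seq peak, 0 outside peaks, and the per-base maximum
  where peaks overlap (fold enrichment is a peak-level statistic; taking
  the maximum avoids double counting).

The network has two structurally identical branches. Each starts with an
initial convolution (the full-size model uses 128 kernels of width 4 and
length 9 on sequence; the accessibility branch's initial convolution is
one-dimensional), followed by two densely connected convolutional blocks,
each closed by a transition convolution and a max-pooling stage of length
4. A dense block holds three BN→ReLU→conv layers; every layer consumes the
concatenation of the block input and all earlier layer outputs, so early
features reach all later layers directly. The two branch outputs are
flattened, concatenated, and passed through a feedforward head ending in
seven **independent sigmoid** outputs — a window can carry several marks at
once, so no softmax is used. Two ablations drop one branch each (DNA-only,
DNase-only).

Training minimizes binary cross entropy averaged over all (window, mark)
entries, with Adam at its default moments and an initial learning rate of
0.001, and early stopping on an internal holdout split.

## Dataset construction rules

- Windows tile each chromosome at a 200-bp step anchored at coordinate 0
  (the grid origin is a convention; peak files do not fix one).
- A window is a modification site for a mark when it overlaps the *union*
  of that mark's peaks by ≥ 100 bp.
- An epigenome is usable when every mark has ≥ 50,000 sites (strict
  less-than cutoff for exclusion).
- The example set for one epigenome is the union of all marks' sites; for
  any one mark, the negatives are the other marks' sites. This one-vs-rest
  design is deliberately stringent: sites of different marks share
  properties (GC content, gene proximity) that random genome draws do not.
- 1000-bp regions that run past a chromosome edge are kept and padded
  (N bases / zero openness) rather than dropped, so every site has an
  example; all coordinates are 0-based half-open throughout.
- Openness scores are used raw; a `log1p` flag exists but is off by
  default.
- Fold assignment is window-level. Adjacent-window leakage is a known
  hazard of this protocol; a chromosome-aware split can be emulated by
  passing per-chromosome row indices, but window-level assignment is the
  default protocol implemented and tested here.

## Evaluation

Per mark: auROC as the rank statistic (probability a random positive
outranks a random negative, ties ½ — identical to the trapezoid ROC area
but with a simpler independent oracle) and auPRC as average precision
(precision summed at each recall step; the interpolation convention is
declared because it changes the value). Degenerate marks (no positives or
no negatives) are reported as NaN rather than scored.

Paired method comparisons use the one-sided exact binomial sign test,
P(X ≥ wins) under Binomial(n, ½), with ties dropped and n reduced — at
n = 15 epigenomes this yields the closed-form tails 3.052E-05 (15 wins),
4.883E-04 (14), 3.693E-03 (13), 5.924E-02 (11), 0.500 (8), 0.304 (9).
Variant-score comparisons use the one-sided Wilcoxon rank-sum test:
inclusive exact tail for tie-free samples with min size ≤ 10 and combined
size ≤ 20, otherwise a tie-corrected normal approximation without
continuity correction (so identical samples score exactly 0.5).

Cross-epigenome ("collective") scoring averages at two levels, both
unweighted: the five cross-validation fold models within each known
epigenome, then the per-epigenome means across epigenomes. The input pairs
the region's sequence with the *novel* epigenome's accessibility track.

## Kernel motifs

For each first-layer DNA kernel, every input sequence is scanned over all
valid length-9 windows; the extreme activation value (EAV) is the maximum
activation, and windows activating at ≥ α·EAV (α = 0.9) are collected.
The position frequency matrix is the elementwise mean of the collected
one-hot windows. The EAV reference is configurable: per sequence, or the
maximum over the whole scanned sample. The default is the sample-global
scope used across the kernel-visualization literature, because the
per-sequence rule guarantees that every sequence with a positive EAV
contributes at least its own best window — for a kernel whose motif
occurs in a fraction f of the sample, the resulting PFM is at best ~f
signal, which measurably caps recovery (flattened Pearson r ≈ 0.3–0.5 at
f = 1/7 on the benchmark) regardless of how well the kernel has learned
the motif. Sequences (or samples) with EAV ≤ 0 contribute nothing — with
a non-positive maximum the threshold rule would admit arbitrarily weak
windows. Windows containing an N are skipped so columns stay stochastic;
kernels with fewer than `min_activations` (default 10) windows are
dropped. Motifs are exported in
MEME minimal format for downstream comparison (e.g. TomTom against
JASPAR); that comparison step, including its q ≤ 0.05 threshold, is
outside this package.

## Variant scoring

A SNP is scored on the 1000-bp sequence centred at its position:
p_ref from the reference sequence, p_alt after substituting the single
base, both over the same openness vector (a substitution does not edit the
accessibility measurement), and Δp = |p_alt − p_ref| for the mark of
interest. The genome base must equal the stated reference allele; indels
are rejected. Control sets match each positive SNP to an unused same-
chromosome candidate nearest to a target distance (500/1000/1500/2000/2500
bp) within ±250 bp, without replacement in positive order; unmatched
positives are dropped from both sets so the sets stay equal-sized and
aligned.

## Synthetic benchmark

The generator emits a complete miniature study: an i.i.d. background
genome at GC 0.41 (human-like), 220 disjoint grid-aligned 200-bp sites per
mark (spaced three grid windows apart so matched control variants fall in
background), each carrying a sample from that mark's 4×9 planted PFM
(consensus probability 0.94, ≈ 1.6 bits/column) written at the window
centre, a 200-bp peak per site, a DNase peak of fold enrichment 5.0 over
every site regardless of mark, and ref/alt variant pairs: positives
substitute the central motif column with its least likely base, controls
substitute a background base ≈ 500 bp away. Because accessibility is
identical at all sites, the DNase-only ablation cannot distinguish among
marks (mean auROC ≈ 0.5 by construction) while the sequence branch can —
the synthetic analogue of accessibility data being shared across marks
within an epigenome.

What the generator does **not** emulate: repeat structure, CpG islands,
nucleosome positioning, correlated peak shapes, read-level noise, or
multi-mark sites (an overlap option exercises the multi-label path in unit
tests, but the benchmark default keeps loci disjoint so one-vs-rest truth
is unambiguous). Passing the benchmark therefore demonstrates that the
implementation learns planted sequence signal under the stated protocol,
not that it reaches any particular performance on real epigenomes.

## Numerical and scale choices

- The network, backpropagation, and Adam are implemented directly on numpy
  float32 arrays; convolutions are evaluated as one GEMM per kernel offset
  over a channels-first layout. Batch-norm running statistics are frozen
  in evaluation mode, so eval-mode forwards are deterministic and
  checkpoints reproduce predictions bitwise.
- Probabilities are clipped to [1e-7, 1 − 1e-7]; the loss gradient is
  taken through the logit, so saturated outputs still receive gradient.
- Pooling is ceil-mode (the trailing remainder is padded with −inf), which
  makes pooling of length 4 well defined for running lengths not divisible
  by 4 (1000 → 250 → 63).
- Transition convolutions between dense blocks use kernel length 1
  (DenseNet-style); only the initial-layer shape is fixed by the
  architecture's published annotation, and all widths are recorded in
  `NetworkSpec` so a run is reproducible from its manifest.
- The benchmark runs a reduced model — 16 initial kernels, dense growth 2,
  one hidden head layer of 64 — with batch 16, at most 12 epochs, patience
  2, holdout fraction 0.1, and 5 folds; the ablations use 2 folds and at
  most 5 epochs. Narrow dense blocks matter at this scale: with wide
  blocks (growth 8) a 16-kernel model under-fits several marks in the same
  step budget, while growth 2 concentrates the capacity and reaches
  out-of-fold auROC ≥ 0.9 per mark. Batch size, epoch budget, and patience
  are not architecture constants and are exposed in `TrainConfig`.
- Seeds propagate end to end: genome generation, site placement, fold
  assignment, parameter initialization, batch order, and motif-sample
  selection all derive from the run seed, so identical commands reproduce
  identical outputs.

## Known limitations

- In this architecture the dense blocks convolve at full base resolution
  before any pooling, so complete motif detection can be composed at the
  second convolutional layer from first-layer *fragment* detectors. At the
  benchmark scale the trained first-layer kernels are therefore mostly
  composite patterns rather than clean single-motif matrices: extraction
  is exact on a planted kernel (the unit oracle recovers a one-hot PFM
  bit-for-bit), but the best trained-kernel correlation with a planted PFM
  is typically 0.4–0.9 per mark, with only one or two crisp (> 0.85)
  kernels per training run, and this persists across widths 16–48,
  initialization schemes, longer training, and both EAV scopes. Kernel
  PFMs should be read as a qualitative window into the first layer, not as
  a complete per-mark motif catalogue.
- The i.i.d. background makes the planted-motif task easier than real
  genomic sequence; reported benchmark numbers are not comparable to
  real-data performance.
- The full-size architecture (128 kernels, growth 128) is defined and
  tested for construction and forward passes, but the shipped benchmarks
  train only the reduced model.
- gapped-peak input, BAM/BigWig tracks, blacklist filtering, and VCF INFO
  parsing are out of scope; peaks are BED3/narrowPeak text.
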
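# Methods

## Data model and preprocessing

A cohort is a set of CNV calls — (sample, chromosome, interval, dosage
del/dup) — plus a per-sample table carrying the case/control label and
optional sex.  Internally every interval is 0-based half-open, so
`length = stop − start`; CNV TSV input declared 1-based inclusive is
shifted on read, BED gene annotations are taken as-is.  Preprocessing
drops rows with missing required fields or malformed intervals (counted
and logged), removes calls shorter than 1 kb (strictly smaller; a 1000 bp
call survives) and all chrY calls.  Samples whose calls are all filtered
away stay in the sample table: burden denominators count individuals, not
calls.  Cohort summaries report case/control ratios both at full
precision and as 2-decimal *truncated* strings, matching the printed
style of published dataset tables (47,119/24,858 = 1.8955 → "1.89").
Genome liftover is out of scope; inputs are assumed on one assembly.

## Features

One feature per gene × dosage: the summed overlap (kb) of a sample's
CNVs of that dosage with the gene.  Overlaps from multiple calls add up
and may exceed the gene length — summation is monotone in burden and we
impose no cap by default.  Columns are scaled to [0, 1] by their maximum
(`unit_interval`) because the decoder and classifier end in sigmoids;
binary overlap indicators are available as an alternative encoding.
CaseOV/ControlOV count *distinct* individuals with ≥ 1 bp of overlap
(threshold configurable).  Features overlapped by nobody are dropped;
features overlapped by strictly more controls than cases stay in the
training matrix (the model sees all data) but are excluded from the
final ranking.

## The autoencoder

Architecture follows the square-root rule: hidden widths are repeated
⌈√(previous)⌉, at most three layers, stopping once widths stop strictly
decreasing; the latent dimension is ⌈√(last hidden)⌉ with a floor of 2.
ReLU activations, optional dropout (default 0.1) on encoder hidden
layers, sigmoid decoder output.  The loss is per-sample summed squared
reconstruction error (averaged over the batch) plus the closed-form
Gaussian KL; binary cross-entropy reconstruction is available for
binarized features.  Optimization is Adam at learning rate 1e-3 with
multiplicative decay 1 (constant rate), batch size 128, an 80/20
train/validation split (stratified by label when labels exist), at most
10,000 epochs with early stopping (default patience 50) on validation
loss, returning the best-validation parameters.  Every source of
randomness — split, init, reparameterization draws, dropout — flows from
one seed; runs are bit-reproducible.

Three numerical choices matter for making the narrow latent usable, and
all three address posterior collapse, which otherwise occurs reliably at
these widths (the latent is 2–3 dimensional by construction):

- the log-variance head bias is initialized at −3 (posterior σ ≈ 0.22),
  so reparameterization noise does not drown the latent mean before the
  decoder has learned to read it;
- the KL weight anneals linearly from 0 to 1 over the first 50 epochs;
- a free-bits floor (0.25 nats per latent dimension) masks the KL
  gradient below the floor, so the posterior cannot be squeezed back
  onto the prior late in training.  The reported objective is always the
  unweighted bound.

Without these, the encoder receives no gradient, the latent mean
collapses to ~0, and the downstream classifier and attribution operate
on noise.

## Semi-supervised training and the gene score

Phase 1 pretrains the VAE without labels on the pooled features of all
available cohorts.  Phase 2 sets the decoder aside and trains a sigmoid
classifier head on the latent *mean* (deterministic; no sampling) with
binary cross-entropy — jointly with the encoder by default, or with the
encoder frozen, which is logistic regression on the latent codes.  In
frozen mode the latent means are standardized internally before the head
fit and the affine transform is folded back into the returned head
(exact for a linear readout); without this the head cannot reach
convergence within any reasonable epoch budget when the latent scale is
small.

During joint fine-tuning a proximal L1 soft-threshold (strength 1.0
relative to the Adam step) is applied to the input→hidden weight matrix
after each step.  This is our realization of restricting network
connections to reduce effective parameters: input features whose
gradient support is sporadic — genes overlapped by one or two
individuals — are driven to exactly zero weight, while features with
consistent support across batches survive.  It is the single most
important control on attribution noise: without it, rare
single-carrier features retain their random initialization (or acquire
spurious weight from isolated case carriers under Adam's per-coordinate
normalization) and contaminate the score ranking.  Decoupled weight
decay is available but off by default; in our experiments it degraded
attribution.

The gene score is the matrix product of all encoder weights, the
mu-head and the classifier head — an I×1 signed vector, computed with
biases and nonlinearities omitted.  It is exactly the input Jacobian of
the pre-sigmoid case logit for a linearized network (a property the
tests verify to 1e-8), i.e. a first-order attribution.  Only the mean
head enters the product, since classification uses the latent mean.
Ranking uses the signed score descending (case-enrichment positive),
ties broken by Fisher p then lexicographically; a magnitude mode exists.

## Statistics

*Fisher burden test.* 2×2 of overlapped vs not-overlapped distinct
individuals per arm; one-sided "greater" by default (the pipeline
reports case-enriched features), two-sided (sum of point probabilities ≤
observed) available.  Implemented on the exact hypergeometric tail; the
test suite checks it against brute-force enumeration (margins ≤ 30,
agreement to 1e-10) and against an independent library implementation.

*Permutation null.* Case/control labels are permuted preserving arm
sizes; the statistic is the overlapped-case count (an odds-ratio variant
with Haldane correction is available).  Randomized mode uses the add-one
estimator (1 + #{perm ≥ obs})/(n_perm + 1), so p is never exactly 0;
exhaustive mode enumerates all label assignments and returns the plain
exceedance fraction.  Default 999 permutations; the published analyses'
100,000 is a configuration value.

*Sex segregation.* Within each sex, the percentage of overlapped cases
over overlapped controls; the headline number is log2(male ratio /
female ratio).  The accompanying chi-square uses the 2×2 of
overlapped-sample counts {male, female} × {case, control} without
continuity correction — the construction is not uniquely determined by
the published table, so this choice is stated prominently.  Any empty
stratum marks the row undefined rather than raising.

*Multiple testing.* Benjamini–Hochberg q-values accompany every ranked
table.

*Enrichment.* Fold enrichment of a gene set among the top-n ranked genes
is (k/n) / (|set|/|universe|) with an exact hypergeometric upper-tail
p; n defaults to 40 and the universe defaults to the annotation's genes
surviving prefiltering (both configurable — published analyses used an
external transcriptome atlas as universe).  Stratified variants filter
the ranked list by biotype (coding/lncRNA) and dosage first.  Mouse
nervous-system-phenotype homolog sets are plain input gene lists (the
homolog mapping is resolved upstream).  Phenotype ratios report, per
gene and phenotype term, the fraction of gene-overlapped samples
annotated with the term.

## Synthetic cohorts

The simulator emulates a burden study's structure: non-overlapping genes
placed uniformly on one chromosome (~25 % flagged lncRNA), Poisson
background CNVs per sample with log-normal lengths clipped at 1 kb (so
the standard length filter passes them), dosage dup with probability
0.5, and planted risk features — gene × dosage pairs that receive a
fully-covering CNV with probability `case_prob` in cases and
`control_prob` in controls, optionally multiplied per sex.  The
reference benchmark is 300 + 300 samples, 500 genes on 50 Mb,
background rate 2, and 10 planted deletion features at 0.30 vs 0.05,
seed 11.

What the simulator does *not* emulate: real CNV length/frequency
spectra, recurrent multi-gene syndromic CNVs (planted features are
mutually independent given the label), linkage between neighboring
genes, platform batch effects and ascertainment bias.  Passing the
recovery benchmark therefore shows that the implementation extracts a
planted burden signal under clean conditions, not that it matches the
published cohort results, which depend on restricted-access data.

A separate no-signal configuration backs the calibration checks.  Exact
tests are discrete: a Kolmogorov–Smirnov uniformity check is only
informative when contingency counts are large enough that p-value atoms
are small, so the null configuration uses a denser, longer background
(about 50–100 overlapped samples per arm per gene) than the planted
benchmark.  With small counts the same test would reject uniformity for
any exact test, conservatively correct though it is.

The pretraining ablation mirrors the published with/without-pretraining
contrast on synthetic data: the unsupervised phase pools the target
cohort with two auxiliary cohorts emulating related disorders (same gene
annotation and risk genes, different individuals), and the supervised
phase uses the frozen two-step scheme so the comparison isolates the
value of the learned representation.  Under the package defaults the
pretrained representation beats a random-initialization encoder by
roughly 15–25 accuracy points on held-out samples.

## Problem sizes

The shipped benchmark and acceptance runs use 600-sample cohorts with
~500 genes, 150-epoch training phases, 999 permutations and five
training seeds — sizes chosen so the complete suite and the acceptance
script each finish in about a minute on a single CPU while leaving the
statistical conclusions stable across seeds.

## Known limitations

- The weight-product score ignores activations and biases; it is a
  linearization, and scores for features that act only through strongly
  rectified paths can be misattributed.  The ranking is therefore always
  reported next to the exact burden statistics.
- The square-root architecture rule produces very narrow latents; the
  anti-collapse machinery above is required, and representation quality
  is sensitive to the latent width for data with many independent risk
  features.
- The sex-segregation chi-square construction and the enrichment
  universe are documented assumptions, not uniquely determined by the
  published tables.
- Permutation p-values for many features use independent permutation
  streams per feature; this makes them independent but not jointly
  exchangeable with a single shared null.
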
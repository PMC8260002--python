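# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the design decisions behind `semrdm`. It states no empirical
number that the test suite or `scripts/acceptance.py` does not itself compute.

## Encoding model

Responses are modeled per voxel as a linear function of delay-embedded scene
features, `R = X W + ε`, where `X` (S×4K) concatenates copies of the S×K
scene-vector series lagged by 3, 4, 5 and 6 samples (TR = 1 s). The lag bank
is the only hemodynamic model: there is no parametric HRF convolution, and the
pre-stimulus boundary is zero-filled — defensible because responses are
z-scored, so zero is the mean, and because real protocols discard an onset
dummy period anyway. Train and test segments come from separate scans, so each
is embedded (and zero-padded) separately.

`W` solves the L2-penalized normal equations; the implementation goes through
the SVD of `X`, which lets one decomposition serve every penalty on the grid.
The unit test suite pins this path to an explicit
`solve(X'X + λI, X'R)` oracle at 1e-8.

**Penalty selection.** One λ per model (not per voxel): the training rows are
split at random into 80% fit / 20% validation, 10 times; a λ's score is the
resample-mean of the voxel-mean validation Pearson r, and ties go to the
smaller λ. The default grid is 17 log-spaced values 10⁰…10⁸. Per-model
selection follows the convention that a single optimal parameter is obtained
for each model; with the voxel-mean criterion the order of averaging (over
voxels, then resamples, or the reverse) is immaterial.

**Accuracy and significance.** Prediction accuracy is the per-voxel Pearson r
between predicted and measured held-out responses (a correlation, not R²).
Per-voxel p-values come from the Student-t transform
`t = r·sqrt((n−2)/(1−r²))`, two-sided, corrected across all voxels with
Benjamini–Hochberg FDR at q = 0.05. Zero-variance predictions or responses get
r = 0 with a logged warning rather than NaN. `r_threshold(n, α)` inverts the
same transform; at n = 1200 and α = 10⁻⁴ (0.05 Bonferroni-corrected over 148
regions, as conventionally rounded) it gives 0.112, i.e. 0.11 at two decimals.

**Preprocessing.** `detrend_standardize` subtracts a running median (120-s
window, coerced to the nearest odd sample count, reflect padding) and z-scores
each voxel with the sample (ddof = 1) standard deviation. A voxel left with
zero variance is an error, named by index.

## Scene features

The **scene vector** of a 1-s scene is a two-level average: token vectors are
averaged within each annotator description, then the per-description means are
averaged. A pooled mean over all tokens would weight verbose descriptions more
and is deliberately not used. Out-of-vocabulary tokens are dropped silently; a
description that loses every token contributes nothing; a scene with no usable
token raises an error (a zero-vector fallback exists behind a flag, default
off).

Control spaces: **untrained** vectors are i.i.d. standard normal with the
template's vocabulary and dimensionality (the distribution is a documented
assumption — only "random vectors" is conventionally specified);
**dimension-shuffled** vectors permute each word's entries independently,
preserving per-word multisets and norms while destroying relational structure;
**binary occurrence** features mark, for the top-n most frequent description
words (ties broken lexicographically), whether the word occurs in any
description of the scene. Five independent control instances are the
conventional evaluation unit and the pipeline default.

## Brain-derived and word-vector-derived RDMs

Fitted 4K×N weights are averaged across the four delay blocks to K×N. Voxel
selection is `all`, `top_m` by test accuracy (ties to the lower voxel index),
or a single region. Task-word vectors are projected through the collapsed
weights and the RDM is the matrix of correlation distances (1 − Pearson r)
between projected rows; applied to raw embedding rows the same operation gives
the word-vector-derived RDM. For binary-occurrence models the collapsed weight
rows *are* the word representations (identity projection over the binary
vocabulary), and task words missing from that vocabulary simply drop out of
the comparison (the intersection is taken, with a warning). Averaging across
participants or instances is an elementwise mean of distances.

## Arrangement engine (inverse MDS)

Geometry lives in arena-diameter units: the arena is the unit-diameter disc,
so the largest possible screen distance is 1. From a set of partial
arrangements the estimator alternates, to 1e-6 or 100 sweeps:

1. per-trial scale `s_t = Σ d·D / Σ d²` over the trial's pairs — least squares
   through the origin, because zero dissimilarity must map to zero distance;
2. global estimate `D(i,j) = Σ_t w_t s_t d_t / Σ_t w_t` with evidence weight
   `w_t(i,j) = d_t(i,j)²` (squared normalized screen distance: widely
   separated pairs are placed with better relative precision).

Initialization is the first trial at scale 1. Cumulative evidence combines
multiplicatively, `E = 1 − ∏_t (1 − w_t)`, which keeps E in [0, 1]; simple
summation would not. Pairs never co-arranged are flagged missing (NaN) and
excluded from correlations. The exact evidence and aggregation formulas of the
original inverse-MDS method are not published in a reusable form; this
reconstruction is the package's own, and the recovery experiments in the test
suite are its arbiter (a noiseless simulated subject on planar truth is
recovered with Spearman ≥ 0.99; 5% positional noise over 60 words still gives
median recovery ≥ 0.9 over 20 sessions).

Session control: trial 1 arranges the full word set, so every pair has an
estimate from the start; subsequent trials greedily assemble the subset with
the largest evidence deficit, seeded by the minimum-evidence pair (ties by
label order). The session stops when every pair's evidence exceeds 0.75 or
after `max_trials` (default 25, standing in for the 1-hour wall clock;
observed human sessions average about 19 trials). A geometric aside: for ≥ 3
words the largest attainable minimum pairwise distance in the disc is √3/2,
so single-trial evidence never *exceeds* 0.75 — at least two trials are always
needed, which matches the adaptive design's intent.

The simulated subject embeds the subset's true sub-RDM by classical
(Torgerson) 2-D scaling, rescales it to the arena, applies a random rotation,
adds isotropic Gaussian jitter of `position_noise × arena radius`, and pulls
strays back to the rim. It is deterministic under its seed.

## Permutation statistics

RDMs are compared by Spearman correlation (Kendall available) over strictly
upper triangles, excluding missing pairs pairwise. The permutation null
relabels the items of one matrix — rows and columns together, preserving
symmetry — which is the default `relabel` scheme; a literal `rows_only` scheme
is available for replication of the row-shuffle description, taking the upper
triangle of the now-asymmetric matrix as written. With P! ≤ n_perm the null is
enumerated exhaustively (p = exact exceedance fraction, identity included);
otherwise p uses the add-one estimator (1 + #exceedances)/(1 + n_perm), which
is never exactly zero. Brain–behavior correlations are tested one-sided
positive (a directional hypothesis); correlation differences two-sided, with
independent relabelings per pair in each repetition. Wilcoxon signed-rank is
exact for ≤ 25 informative pairs, normal-approximate beyond.

## Synthetic ground truth: what it emulates, and what it does not

The generator plants everything the real study measures but does not deposit:

- **Embedding truth** — word vectors `√c·centroid + √(1−c)·noise` with one
  centroid per category, so expected within-category correlation is exactly
  `c` (default 0.6) and between-category 0. Six categories; the 60-noun task
  vocabulary (6×10) occupies the head of each category block, padded to
  `vocab_per_category` (default 100, i.e. 600 words) with filler words. The
  task set being a small sample of the description vocabulary matters: it
  keeps per-word occurrence rates realistic (a task word appears in tens of
  scenes out of thousands) and gives the binary model only partial task-word
  coverage, as real occurrence models have.
- **Scene streams** — a sticky Markov topic (a random pool of 10 vocabulary
  words, persisting with probability 0.9 per second) drives token sampling
  (70% from the pool, 30% uniform), so consecutive scene vectors correlate as
  movie scenes do. Topic pools are sampled uniformly, *not* along semantic
  categories: on screen, a sea is not usually accompanied by a mountain, and
  wiring categories into co-occurrence would build the behavioral structure
  into every occurrence-sensitive control. The stream's feature series is by
  construction identical to `scene_vector` applied to its descriptions.
- **Brains** — exactly `round(tuned_fraction·N)` voxels (default half) get
  dense Gaussian tuning of scale 1/√K; the rest are pure noise. Region labels
  partition voxels into contiguous near-equal groups (default 148).
- **Responses** — the forward model replicates the planted K×N weights across
  delay blocks with fixed gains (0.4, 0.8, 0.8, 0.4), a crude hemodynamic
  envelope, and adds i.i.d. Gaussian noise (default sd 2.0, chosen so that
  trained-model test accuracies land near 0.1, the order observed with real
  recordings). There is no temporal autocorrelation in the noise, no
  physiological confound, and no 3-D geometry — all documented
  simplifications.
- **Behavior** — simulated subjects as above, default positional noise 5% of
  the arena radius, arranging the 60 task nouns against the truth RDM of the
  planted embedding.

Passing recovery tests on this generator shows the *pipeline* is correct and
well-calibrated; it does not show that real cortical tuning follows the
planted model, which is a test harness, not a claim about the brain.

**The word-identity channel.** One genuine phenomenon the simulation exposes:
scenes containing word *w* evoke *w*'s true semantic response, so any feature
space that can index "scenes containing *w*" — untrained, shuffled, or binary
features alike — partially reconstructs *w*'s true brain representation even
with all relational structure destroyed. Control models therefore retain a
small but real brain–behavior RDM correlation (growing with the ratio of
feature dimension to vocabulary size and with averaging across control
instances), and at the default conditions the dimension-shuffled control's
correlation is small (ρ ≈ 0.1–0.2 versus ≈ 0.8 for the trained model) yet can
reach permutation significance. The corresponding suite check expects a
non-significant control and is left failing deliberately rather than tuned
away: the channel is informative about what occurrence-driven models can and
cannot show.

## Problem sizes

The pipeline default (`ExperimentConfig()`) matches the study's protocol
scale: 7200 training + 1200 test samples at TR = 1 s (12 once-shown 610-s
training clips and 2 repeat-averaged test clips minus 10-s dummies), K = 50,
N = 2000 voxels in 148 regions. Simulation-heavy tests and the acceptance
script run reduced, documented sizes chosen as the package's own desk-scale
defaults — replicate-brain contrasts at S = 900+300, N = 150, K = 20, and the
end-to-end experiment at S = 3000+800, N = 800, K = 50 — while keeping the
default noise level, resampling schedule, λ grid and permutation counts.

## Known limitations

- No noise-ceiling estimation or parametric RSA inference.
- The untrained-vector distribution (standard normal) is an assumption.
- The evidence formula is a reconstruction (above), validated by recovery.
- Binary features use a global frequency vocabulary; no per-movie-set split.
- No NIfTI/volumetric I/O and no cortical surface rendering: responses are
  matrices with region labels.
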
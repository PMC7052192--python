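# Methods

This note documents the models, the synthetic data they are validated on,
and the numerical and design choices a user should know before trusting or
extending the results.

## Temporal grid and designs

All series live on the TR grid (default TR = 2 s); bin `t` covers
`[t·tr, (t+1)·tr)` and a trial occupies every bin whose start lies in
`[onset, onset + duration)`. Runs carry 6 s of task-free imaging at both
ends and 2-s feedback displays between trials (feedback is deliberately
*not* represented in any feature matrix; it acts as unmodeled variance).

Training runs present tasks in pseudorandom order by cycling seeded
permutations of the task list, with trial durations drawn uniformly from
the configured range and rounded to TR multiples. Test runs tile a fixed
repeat block — one seeded permutation of all tasks with per-task durations
drawn once — across the available runs; each test run records how many
trailing samples the reshape step discards (the 6-s end rest, a trailing
feedback sample on every third test run, and any remainder needed to make
the retained sample count an exact multiple of the block length). With the
full-study geometry (103 tasks, 12 training + 6 test runs of 556 s,
`test_block_s = 824`) this yields 3336 training samples and 4 repeats of
412 test samples, with discards of 3 samples per run plus 1 extra on runs
3 and 6.

Repeat blocks may span run boundaries, so consecutive repeats in the
retained timeline carry hemodynamic spill-over from one another. For this
reason, test-time features (and, for decoding, test responses) are
delay-embedded **on the physical test runs first** and then repeat-averaged
with exactly the same discard/split rule as the measurements; because the
model is linear, averaging inputs equals averaging predictions, and the
predictions inherit the same carry-over structure the averaged measurement
has. Embedding an isolated repeat block instead loses the carry-over and
measurably depresses accuracy at small block lengths.

## Preprocessing

Per run and per voxel: a running-median baseline over a 240-s window
(121 samples at TR = 2 s, forced odd, reflected edges; runs shorter than
the window fall back to a run-length window with a logged warning) is
subtracted, then the voxel is z-scored within the run. Zero-variance voxels
are flagged and excluded from modeling. Two consequences worth knowing:

* The running median is not an idempotent operator on noisy data — a second
  pass moves each sample by roughly the median sampling error
  (≈ 1.25/√window per unit SD). Only the z-scoring component is exactly
  idempotent; the composed normalization is a near-fixed-point, and the
  test-suite checks it as such.
* With tasks occupying most bins, the median tracks each voxel's *typical
  task level*, not an absolute baseline; detrending therefore absorbs a
  per-voxel constant into the weights. The encoding fit includes an
  unpenalized per-voxel intercept (features and responses centered over the
  training samples) so that this offset does not leak into the task
  weights as a rank-one bias. Weight maps remain identifiable up to the
  per-voxel scaling introduced by z-scoring, which is why recovery against
  ground truth is assessed on task-differential (across-task-centered)
  maps for the pipeline path, and on raw maps only for fits without
  normalization.

Drift is removable by the 240-s median filter only when it is slower than
the window; the generator's drift components therefore default to periods
of 480 s and above.

## Model fitting

Ridge solutions are computed through a thin SVD of the (optionally
centered) design, which makes the entire 18-value regularization path
(`100·2^k, k = 0..17`) available from a single factorization; singular
values below `s_max · max(T, N) · eps` are treated as zero, so `λ = 0`
reproduces the pseudoinverse solution. Cross-validation folds are
contiguous time blocks (serial correlation makes shuffled folds
optimistic); the selected λ maximizes mean held-out Pearson accuracy across
voxels, ties going to the smaller value. The group-level λ used for pooled
weight analyses is chosen by 50 repetitions of a random 80/20 split,
averaged over repetitions and subjects.

Note that the grid floor of 100 is comparable to the one-hot design's
Gram eigenvalues at desk scale, so even noise-free fits are substantially
shrunk; this is the intended behavior for noisy data, and the noise-free
forward-model consistency of the implementation is checked separately at
`λ = 0` (mean r > 0.99).

Decoding swaps the roles of features and responses. One asymmetry is
physical: the BOLD response *lags* its cause, so the encoder shifts
features forward in time (response at `t` explained by features at
`t − 2, 4, 6 s`), while the decoder reads the feature at `t` from responses
at `t + 2, 4, 6 s` (backward shifts of the response matrix, zero-padded
within runs). With past-shifted decoder inputs the current bin's task would
be literally invisible to the decoder, and novel-task decoding degrades to
cluster level.

## Representational analyses

The RSM is the Pearson correlation of delay-averaged task weight maps over
each subject's FDR-significant voxels, concatenated across subjects along
the voxel axis (no anatomical alignment is assumed — concatenation is the
group operation). Clustering is single linkage on `1 − r` with
deterministic tie-breaking by lowest node index; heights are therefore
non-decreasing and the k-cluster cut removes the k−1 highest merges. Group
PCA centers the task-by-voxel matrix over tasks (no variance scaling, since
weights share units); component signs are pinned so the largest-magnitude
task loading is positive; components explaining more than 5% variance are
flagged as meaningful; RGB embeddings map each of the top three components
affinely by its 1st–99th percentile range to [0, 1].

## Cognitive transform function and novel tasks

The CTF row of a task is the Pearson correlation of its delay-averaged
weight map (over that subject's significant voxels) with every term map
registered to the same voxels. Per-subject CTFs are averaged
leave-one-subject-out, so the features used for a subject's generalization
analyses are independent of that subject's data.

For novel-task analyses the tasks are split into five balanced groups
(sizes differ by at most one; 103 tasks give 21/21/21/20/20). Training
excludes target-task bins plus a 6-s window after each occurrence
(truncated at run boundaries); testing uses exactly that union. Predictions
and decoded factor vectors at time points covered by several folds are
averaged. Task likelihood averages the per-time-point correlations over
the target's test-mask bins with equal weights (task bins and post-task
window bins count the same). One-vs-one accuracy counts strictly-lower
competitors as wins and ties as 0.5; the per-task sign test excludes ties.

Shuffle nulls permute all elements of the relevant matrix (test
cognitive-factor features for encoding, the CTF for decoding) and recompute
the mean statistic; 1000 repetitions by default. A permutation hook allows
tests to inject the identity permutation. The per-task accuracy under the
CTF-shuffle null is rank-uniform by exchangeability, so its extreme
percentiles are dominated by discreteness; calibration statements about
individual tasks are therefore made against the null distribution of the
*mean* accuracy, which is the quantity the shuffle procedure reports.

## Synthetic-data generator

The generator is first-class, tested code; its defaults define the study
conditions used throughout the test-suite.

Task-space structure is planted in a latent factor space of dimension
`F = n_clusters + max(2, n_tasks // 4)`: task `k` is
`cluster_sep · e_c(k) + z_k`, with `e_c` its cluster axis and `z_k` a
unit-norm random mixture of the shared private factor axes; term `j` is the
factor axis `j mod F` plus `term_noise` on its own noise axis. Two
properties are deliberate:

* Every task lies in the span of the factors. Zero-shot generalization is
  only possible when a held-out task's response direction is expressible
  through directions seen in training; giving each task an orthogonal
  private axis would make novel tasks provably undecodable, which is a
  statement about the world, not about the method.
* Each subject's voxel realization multiplies the latents by a random
  orthonormal basis with zero-mean rows, so every pairwise Pearson
  correlation between maps equals the cosine of the latents *exactly* and
  is identical across subjects. Exactness claims in the tests (equal CTFs
  across subjects at zero term noise, exact planted-partition recovery on
  noise-free truth) rest on this construction.

BOLD is simulated through the same three-delay FIR forward model the
encoder assumes, with delay gains (1.0, 0.9, 0.6), plus per-voxel
sinusoidal drift (three components at 1×, 2×, 3× the base period, random
phases, amplitude ∝ 1/m) and i.i.d. Gaussian noise. Defaults: σ = 1,
drift amplitude 1, drift period 480 s, cluster separation 3 — a regime in
which encoding accuracy sits near r ≈ 0.8–0.9 at 300–2000 voxels.

What the generator does **not** emulate: realistic hemodynamic response
shapes beyond the 3-delay FIR, physiological (non-white, non-Gaussian)
noise, spatial smoothness of voxel maps, anatomical correspondence across
subjects, behavioral variability in button presses (presses are Poisson
events on designated response tasks), and any semantic content of the
terms. Passing tests therefore demonstrate correctness of the pipeline
under the stated generative assumptions, not performance on real fMRI.

## Problem sizes

The default configurations are desk-scale by design: 6 subjects, 24 tasks,
6 clusters, 60 terms, 2000 voxels, 4 training + 2 test runs of 360 s. The
test-suite uses smaller cohorts (300–1000 voxels, 12–48 tasks) and two
purpose-built conditions: a 48-task, σ = 0.7, cluster-separation-2 cohort
for zero-shot decoding statistics (lower separation keeps within-cluster
factor vectors discriminable — margins scale like 1/(1 + sep²) — and 8–12-s
trials keep task bins dominant over the 6-s post-task window), and a
1-training-run, σ = 3 cohort where pooling by dendrogram nodes gives the
hierarchical model its clearest advantage over the task-type model. The
full-study geometry (103 tasks, 12 + 6 runs, 556 s) is exercised for design
arithmetic and procedure constants; `pipeline.PAPER_SCALE_CONFIG` exposes
it for larger runs.

## Known limitations

* Single λ per subject and model (selected on mean accuracy across voxels);
  no banded or per-voxel regularization.
* The CTF uses each subject's FDR-significant voxels; with very few
  significant voxels the term correlations become unstable (an error is
  raised when none survive).
* Likelihood averaging weights all test-mask bins equally; post-task window
  bins dilute the target signal when trials are short.
* `cut_clusters` relies on single linkage's non-decreasing merge heights;
  trees built by other linkage rules would need height-based cutting.
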
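# Methods

## Scope and assumptions

`epinet` models the network of brain voxels anticorrelated with an
epileptogenic-zone (EZ) seed in resting-state BOLD data and relates its
summary statistics to surgical outcome. The pipeline starts from
co-registered volumes: motion correction, MNI normalisation and EEG
source localisation are explicitly outside its scope — the EZ arrives as
a voxel mask, and pre/post-operative scans must share grid and affine
exactly (checked, never resampled). Voxel indexing is 0-based; all
world-space quantities come only from the 4×4 affine.

## Preprocessing

* **Gaussian smoothing.** Each volume is convolved with an isotropic
  *in millimetres* Gaussian, σ = FWHM / (2√(2 ln 2)) converted per axis
  to voxel units, so the anisotropic acquisition voxel
  (4 × 3.75 × 3.75 mm) still receives an isotropic smooth in world
  space. Default FWHM 8 mm. Boundary handling is reflect padding —
  chosen to avoid edge darkening on small synthetic grids — with the
  kernel truncated at ±4σ (truncation error < 1e−4). Tests use a direct
  triple-sum convolution as the oracle under the same conventions.
* **Grand-mean scaling.** The image is multiplied by
  target / mean(in-brain voxels × timepoints), default target 100.
  Grand-mean (rather than per-volume) scaling was chosen because
  Pearson correlation is invariant under a single positive scalar, so
  the choice cannot perturb any downstream connectivity number — a
  property asserted in tests. The operation is idempotent and rejects a
  global mean indistinguishable from zero at float precision.
* **EEG filters.** The band-pass (default 1–100 Hz) is a 4th-order
  recursive Butterworth applied forward–backward (zero phase, so
  discharge timing is preserved); the notch (default 60 Hz) is a
  second-order IIR notch with quality factor 30, also zero-phase. Only
  the band edges are prescribed upstream; these realisations meet
  ≥ 20 dB attenuation at low/4, at 2×high and at the notch center while
  staying within 1 dB in-band, which the tests verify on pure tones.
  EEG travels as delimited text; nothing past filtering is in scope.

## Network mapping

The seed series is the unweighted spatial mean of the seed voxels
(simplest reading; a first-principal-component summary would weight
voxels by variance and is not the default). Every in-brain voxel with
nonzero temporal variance gets a Pearson r against that series;
zero-variance voxels are excluded and counted, never imputed.

The negatively correlated network is the set of defined voxels with
r **strictly** below the threshold, default −0.4; ties at the threshold
are excluded. The positive network uses r strictly above its threshold,
defaulting to the signed mean of all defined r values in the patient's
map. Seed voxels are removed from both networks so the seed cannot
trivially join its own positive network. An empty network is a warning,
not an error, because small or noisy scans legitimately produce one.

The control analysis grows a contiguous face-connected ROI of exactly
*n* voxels (default 907, matching the average EZ seed size) from a
uniformly chosen start voxel inside a supplied region, absorbing a
random frontier voxel at each step; it is deterministic under its RNG
seed and errors informatively when the region (or its connected
component) cannot supply *n* voxels.

## Network metrics

* **Intraconnectivity** — mean pairwise Pearson correlation between
  distinct member voxels, signed (no absolute value: the interpretation
  of high intraconnectivity as synchrony requires sign preservation),
  self-pairs excluded (including the diagonal would inflate the value
  by (1 − mean)/N). Computed via the closed form
  (‖Σ zᵢ‖² − N)/(N(N−1)); equality with the brute-force all-pairs
  average to 1e−10 is an acceptance-tested invariant, as is the
  positive-semidefiniteness bound −1/(N−1) ≤ value ≤ 1, asserted on
  every computation. Fewer than two usable voxels yields an explicit
  missing value.
* **Spread** — median Euclidean distance in mm of member voxel centers
  from the *seed-mask* centroid (not the network centroid). Voxel
  centers and world mm via the affine, because index-space distances
  would be biased by the anisotropic voxel. Even counts use the
  midpoint of the two middle order statistics.
* **Post-operative connectivity** — the identical computation on the
  post-operative series over the voxel set frozen from the
  pre-operative network; voxels that became constant (e.g. resection
  cavity) are excluded and counted.

## Cohort statistics

Group comparisons use the pooled-variance Student t-test (Welch by
flag); degenerate complete separation returns the smallest
representable positive p rather than zero. Spearman ρ uses midranks for
ties; the Bonferroni family size defaults to the number of outcomes
tested in the run and is never inferred silently from the table.
Missing data are handled by pairwise deletion and every result carries
its effective n; pairs with fewer than 3 complete cases are returned
flagged, not dropped.

The ROC treats higher network intraconnectivity as predicting seizure
freedom (configurable). AUC is the concordance probability with ties
counted ½ (equal to the trapezoidal area); the 95% CI uses DeLong's
variance, truncated to [0, 1], with a seeded percentile bootstrap
available by flag. Operating thresholds: the Youden-J maximiser with
ties broken toward higher specificity, the sensitivity maximiser
subject to specificity > 0, and the specificity maximiser subject to
sensitivity > 0. Printed percentages round half away from zero.

## Synthetic data

The scan generator plants three pairwise-disjoint regions (seed,
positive network, anticorrelated network — axis-aligned boxes by
default for trivially computable centroids, spheres optional) on a
background of white Gaussian noise plus a positive offset (default 100)
that keeps grand-mean scaling well-defined. Planted voxels follow a
one-factor model x_v(t) = w·s(t) + √(1−w²)·ε_v(t) with unit-variance
white latent signal s and idiosyncratic noise ε, so two planted voxels
with loadings w_u, w_v have expected correlation w_u·w_v and the
anti-network's expected intraconnectivity is exactly w_anti². The
latent signal is white by default to keep those closed forms exact; an
AR(1) coefficient is available for realism. Defaults mirror the study
acquisition (TR 3 s, 100 volumes ≙ one 5-minute run, 4 × 3.75 × 3.75 mm
voxels, w_anti = −0.7); recovery tests use T = 300 as specified for
those properties, where the −0.4 cut sits several Fisher-z standard
errors from −0.7 and detection is near-exact.

The cohort generator draws connectivity per outcome group from normal
distributions and ties one memory score linearly to connectivity with
additive noise. Group means default to 0.37 (seizure free) vs 0.21
(not), SD 0.08 — a 2-SD separation placed inside the connectivity range
where the analysis's reported operating thresholds live — with the
12/7 split of the demographic table. For equal-variance normals the
expected AUC is Φ(d/√2), the closed form the simulation tests check.

What the generator does **not** emulate: hemodynamic response
convolution, physiological confounds (cardiac/respiratory),
autocorrelated noise, scanner drift, motion, or spatial correlation of
the background. Passing recovery tests therefore demonstrate
correctness of the computations under the stated model, not robustness
to real-scanner artefacts.

## Numerical and design choices

* Strict inequalities at both network thresholds; ties excluded.
* Zero-variance voxels: excluded and counted at every stage.
* Intraconnectivity values are clipped to [−1/(N−1), 1] only after the
  invariant assertion passes (guarding 1e−16-scale float overshoot).
* Determinism: every stochastic component (scan, cohort, control ROI,
  bootstrap) takes an explicit RNG seed; per-patient reports contain
  SHA-256 input hashes and no timestamps, so identical config + inputs
  reproduce byte-identical reports.
* Problem sizes in the test suite (20³ grids, T ≤ 300, 200 simulated
  cohorts, 10⁴ permutations) were chosen as the smallest at which the
  closed-form expectations are sharp; they run in seconds on a laptop.

## Known limitations

* The seed summary discards within-seed heterogeneity; a principal
  component option exists but is not default.
* DeLong's CI degenerates (zero width) at AUC = 1 on small samples; the
  bootstrap option is preferable near the boundary.
* The positive-network mean-r threshold includes all defined voxels
  (signed average), so on synthetic scans with mostly-noise background
  the positive network is large and weakly coherent; this mirrors the
  definition rather than a detection claim.
* No atlas labelling, graph-theoretic measures, survival modelling or
  multivariate prediction — deliberately out of scope.
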
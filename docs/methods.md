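# Methods

This note documents the models, conventions and design choices behind
`ampdyn`, in the order the pipeline runs.

## Preprocessing

The chain assumes spatially standardized 4D images (slice timing,
realignment, coregistration and nonlinear normalization are upstream and out
of scope). Stage order is fixed and recorded in the provenance sidecar:
discard → exclusion check → nuisance regression → scrubbing → band-pass →
smoothing.

- **Volume discard.** The first 10 volumes (configurable) are dropped from
  image and motion trace alike, modelling scanner equilibration; a
  180-volume protocol retains 170.
- **Motion exclusion.** A subject fails if any translation axis deviates
  more than 1.5 mm, or any rotation axis more than 1.5°, from the *first
  retained frame*. The reference frame is a convention of this package (the
  range definition is not standardized across toolchains); values exactly at
  the limit pass, since exclusion requires strictly "more than". A relative
  guard of 1e−9 keeps unit round-trips (deg → rad → deg) at the limit from
  flipping the verdict.
- **Nuisance regression.** Per voxel, OLS residuals against [intercept,
  linear trend, 24 motion regressors, WM mean, CSF mean], with the voxel's
  temporal mean added back. The Friston-24 expansion is [p(t), p(t−1),
  p(t)², p(t−1)²] for the six rigid-body parameters, with the lagged value
  at the first timepoint defined as 0. The global signal is never included.
  Intercept and trend are included even though plain detrending is sometimes
  treated as a separate stage; a drifting baseline otherwise leaks into the
  lowest pass-band bins. Collinear columns are dropped with a logged
  warning rather than failing the subject.
- **Scrubbing.** Framewise displacement follows the Jenkinson formulation:
  for consecutive rigid transforms, FD = sqrt(R²/5 · tr(AᵀA) + bᵀb) with
  [A|b] = T_i T_{i−1}^{−1} − I and R = 80 mm — the RMS displacement of
  points uniformly distributed in an 80 mm ball (the method's standard
  constant; the test suite checks the closed form against Monte-Carlo ball
  sampling). Frames with FD > 0.5 mm are flagged together with 2 preceding
  and 1 following frame; the after-count of 1 is the common toolbox default
  and is exposed in `PrepConfig`. Flagged values are replaced per voxel by a
  cubic spline fitted through unflagged timepoints (at least 4 required);
  unflagged values are bit-identical to the input. Rotations are stored in
  radians on disk; degree thresholds are converted internally.
- **Band-pass.** An ideal (hard) frequency-domain filter: DFT bins with
  frequency inside [0.01, 0.08] Hz inclusive are kept, all others zeroed,
  and the temporal mean re-added. A hard filter matches the convention of
  the ALFF literature and makes analytic tests exact; it is idempotent by
  construction. Bin selection uses an absolute guard of 1e−12 Hz so edge
  bins are classified stably.
- **Smoothing.** Per-volume Gaussian convolution, σ = FWHM/(2√(2 ln 2)) per
  axis in voxel units, reflect boundary handling (preserves constants and,
  away from edges, unit mass). FWHM 0 is the identity.

## Amplitude metrics

Static ALFF removes the temporal mean, takes the DFT, forms the single-sided
amplitude spectrum a_k = 2|X_k|/N (no doubling of the DC or Nyquist terms,
which the band never includes), and averages a_k over in-band bins —
"averaged square-root power". ALFF is positive and 1-homogeneous in the
signal. Maps are z-scored within the analysis mask with the *sample*
standard deviation (ddof = 1); outside-mask voxels are 0.

Dynamic ALFF uses rectangular (untapered) sliding windows of 22 TR with step
1 TR by default (36 and 50 TR as robustness alternates); W = ⌊(T − w)/s⌋ + 1
windows, each analysed on its own DFT bin grid, and the per-voxel sample
variance (W − 1 denominator) across window-ALFF values is reported. The
variance choice (rather than SD or coefficient of variation) and the sample
denominator are this package's conventions. dALFF variance maps are z-scored
before statistics exactly like static maps, so that both metrics enter group
models on a common scale.

Metrics are computed on fully preprocessed (band-passed, smoothed) data; the
in-band average then restricts an already band-limited spectrum, which is
harmless and keeps the stage contract simple.

## Group statistics

Voxel-wise OLS of the map on [intercept, group, age, gender (0/1),
education] gives the group-coefficient t with df = n − 5. Cluster-level
family-wise error is controlled by permutation rather than random-field
theory: RFT needs smoothness estimates and parametric assumptions that are
hard to validate on desk-scale synthetic grids, while the permutation null
is exact under group exchangeability and directly testable. Suprathreshold
voxels are |t| > t_crit at two-sided p ≤ 0.001 (two-sided because effects in
both directions are of interest); clusters are 26-connected components; the
null is the maximum cluster extent over label permutations, with covariates
staying attached to their subjects (label-only shuffling; a Freedman–Lane
scheme is a possible refinement, not implemented). Corrected p is the
proportion of null maxima at least as large, floored at 1/n_perm so no
reported p is exactly 0.

## Pattern analysis

Features are in-mask voxel values, one column per voxel in lexicographic
coordinate order. LOOCV trains on n − 1 subjects and scores the held-out
subject 100 or 0; the mean is the reported accuracy. The SVM is a linear
soft-margin machine with C = 1; a decision value of exactly 0 predicts the
positive (patient) class. Features are not re-scaled per fold — maps are
already z-scored — and per-fold primal weights w = Σ y_i α_i x_i are
back-projected to voxels, with positive weight meaning elevation favours
the patient class; only voxels whose weight sign agrees across *all* folds
enter the consistency mask. AUC uses the rank (Mann–Whitney) formulation
with tie averaging on pooled cross-validated decision values.

Permutation inference reruns the full LOOCV per label shuffle; p is the
proportion of null statistics ≥ the observed one, floored at 1/n_perm.
Region-wise analyses apply *one shared shuffle per permutation* to every
region and take the per-permutation maximum statistic across regions as the
null — the max-statistic construction that makes each region's corrected p
valid family-wise (corrected p ≥ the region's own-null p, monotonicity
checked in the tests). Prognosis prediction swaps the classifier for linear
ε-SVR (ε = 0.1, the common library default; the analysis fixes only kernel
and C) with target shuffling, and reports the Pearson correlation between
pooled leave-one-out predictions and the true recovery rates plus RMSE.

### SVM solver

The permutation × LOOCV design solves on the order of 10⁵–10⁶ tiny SVM
problems per simulation study. `ampdyn._svm` implements the standard SMO
algorithm (maximal-violating-pair working-set selection, tolerance 1e−3,
intercept from free support vectors — the libsvm formulation) on a
precomputed linear kernel, JIT-compiled with numba; ε-SVR is reduced to the
same solver by the usual 2n-variable box expansion. A single fit costs
microseconds. The test suite verifies agreement of decision values,
predictions and LOOCV accuracies with scikit-learn's libsvm bindings on
batteries of random problems, and the LOOCV loop against a hand-written
hold-one-out loop around scikit-learn.

A methodological note: on balanced null data, LOOCV accuracy sits slightly
*below* the nominal 50 % chance level (each training fold has 19 of the
held-out subject's class versus 20 of the other, tilting the classifier
toward the wrong class). At the package's null-cohort test conditions
(n = 20/20, 100-voxel ROI) the permutation-null mean is ≈ 48.7 %, within 2
points of chance; the acceptance test estimates it by pooling five
independent null cohorts to keep the Monte-Carlo error of the estimate well
below the tolerance.

## Synthetic cohorts

Each voxel's signal is baseline + A_v (1 + m_v s(t)) sin(2π f_v t + φ_v) +
ε_t: carriers drawn uniformly inside the 0.01–0.08 Hz band (so static
effects survive the band-pass), a slow sinusoidal envelope s(t) with period
240 s ≫ any window length (so dALFF variance responds to the modulation
depth m_v), and white noise. Patients' carrier amplitude is multiplied by a
configured ratio inside static-effect blocks; their modulation depth is
raised inside dynamic-effect blocks. Head motion is a bounded (reflected)
Gaussian random walk, translations and rotations separately, with bounds
inside the exclusion limits. Subjects get a global amplitude scale (sd 0.2)
plus, inside the prognosis pattern, a regional scale (sd 0.3) — the regional
component is what survives within-subject z-scoring and carries the
prognosis signal into standardized maps.

Covariates (age ~ N(52, 8²), gender Bernoulli(½) coded 0/1, education ~
N(10, 3²)) are drawn independently of group. Preoperative JOA scores are
integers in [6, 14]; the recovery rate is built as 0.70 + 0.156·z + noise
(matching the recovery distribution of the motivating surgical population,
mean 70 %, sd 15.6 %), truncated at the formula's ceiling of 1, where z is
the z-scored projection of the subject's amplitude field onto the prognosis
weight map; the postoperative JOA is then the rounded integer realisation,
so the tabulated recovery rate is the JOA-formula value after quantisation.
Negative recovery (worsening) is allowed. Everything is deterministic in
(spec seed, subject seed) via seed sequences; regeneration is bit-identical.

The atlas generator k-means-partitions an ellipsoidal "brain" mask into
compact labelled regions with a minimum-size guarantee — structurally a
parcellation, with no anatomical claim.

Two map-level simulators (`planted_map_cohort`, `prognosis_map_cohort`)
generate per-subject *amplitude maps* directly — i.i.d. Gaussian voxels with
an additive group shift (so the shift in sd units is the per-voxel Cohen's
d), or with a latent severity score expressed in a pattern mask and a noisy
target. They emulate the post-metric stage of the pipeline for simulation
studies (power, family-wise error, chance level) where regenerating full
time series per replicate would add nothing but runtime.

### What the generator does not emulate

Hemodynamic response shape, physiological (cardiac/respiratory) noise,
scanner drift fields, susceptibility artifacts, spatial autocorrelation of
the noise (map-level simulators use i.i.d. voxels; cluster-extent nulls on
real, smooth data are heavier-tailed), realistic motion-artifact coupling
between trace and image, and anatomy. Passing tests therefore demonstrate
the *statistical machinery* — calibration of the metrics against analytic
signals, error control under exchangeability, power against planted effects
— not performance on real BOLD data.

## Simulation sizes in the test suite

Chosen once as desk-scale study conditions: cluster power at the 24³ grid
with n = 20/20, d = 2 and 100 permutations over 50 replicates; cluster
family-wise error on a 16×16×12 grid over 200 null replicates; region-wise
power and error on a 12×12×10 ellipsoid mask with 8 regions over 25
replicates each; prognosis recovery with 40 patients, a 100-voxel pattern
and target noise at 20 % of signal sd over 25 replicates; permutation counts
in the heavy loops use the procedures' minimum of 100 (p floor 0.01, below
the 0.05 significance level).

## Known limitations

- The exclusion-range reference frame and the scrub-after count are package
  conventions where the underlying protocol descriptions are ambiguous;
  both are configurable.
- Permutation cluster correction is a deliberate, documented divergence
  from SPM-style random-field FWE; extents calibrated under one smoothing
  regime do not transfer to another.
- The SMO solver targets small dense problems (n ≲ a few hundred); it is
  not a general replacement for libsvm/liblinear at scale.
- Region-wise analyses assume the atlas is in the same grid as the maps; no
  resampling is provided.
- No fractional ALFF, regional homogeneity or functional connectivity
  metrics; no DICOM/BIDS ingestion; no postoperative imaging models.
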
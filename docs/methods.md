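# Methods

## Scope

`boldmse` implements a complexity analysis of spontaneous BOLD activity:
per-voxel multiscale entropy (MSE) maps from resting-state fMRI time
series, followed by covariate-adjusted group inference with cluster-level
multiple-comparison control, cross-validated ROI definition, post-hoc
pairwise contrasts, and rank correlations between regional entropy and
clinical scores. Because subject-level neuroimaging data cannot be
redistributed, the package ships a synthetic cohort generator that
emulates the four-group (NC / EMCI / LMCI / AD) study design, so every
stage is exercised end to end by simulation.

Spatial preprocessing (slice-timing correction, realignment, template
normalization, smoothing, tissue segmentation) is out of scope: volumes
are assumed to arrive on a common grid, and gray-matter volume enters
only as a supplied per-ROI number.

## Entropy estimator

**Coarse-graining.** For scale factor `l`, consecutive non-overlapping
windows of length `l` are averaged, giving a series of length
`floor(N/l)`; trailing remainder samples are discarded. Scale 1 is the
original series.

**Sample entropy.** `SE(m, r, N) = -ln(A/B)` where `B` counts ordered
pairs of distinct length-`m` templates within Chebyshev distance `r` and
`A` counts the subset still matching at length `m + 1`. Conventions,
fixed here because the estimator's literature leaves them open:

- distance is the max-norm with an **inclusive** boundary (a difference
  exactly equal to `r` matches) — deterministic tie-breaking, immaterial
  for continuous data;
- template starts range over `i = 1 .. N − m` for **both** match
  lengths, so `A ≤ B` by construction;
- mirrored ordered pairs are both counted (the ratio is unaffected; the
  counts are defined this way so a brute-force oracle can be compared
  exactly);
- self-matches are excluded;
- the radius is `r ×` the **population** SD (divide by `N`) of the
  original scale-1 series and is *not* recomputed after coarse-graining.
  Since the pipeline standardizes voxels to unit SD, the absolute radius
  equals the fractional `r`;
- zero `A` or `B` makes SE undefined; undefined values propagate as NaN
  (never 0) and are counted per scale in the run log.

A scale is computed only when `floor(N/l) > m + 1`; with 130 retained
time points and scales 1–6 every scale is valid (scale 6 uses 21 points).

**Parameters.** The estimator grid covers six (m, r) pairs —
(2, 0.15), (2, 0.25), (2, 0.30), (2, 0.35), (1, 0.25), (1, 0.35) — with
(m = 2, r = 0.35), scales 1–6, as the default reported configuration.

**Analytic oracle.** For i.i.d. Gaussian noise the per-coordinate match
probability is `P(|X − Y| ≤ rσ) = erf(r/2)` (X − Y is Normal(0, 2σ²)),
so large-N sample entropy tends to `−ln(erf(r/2))` independent of `m`.
This closed form anchors the estimator tests: at N = 100 000 the
implementation agrees within 0.02 for r ∈ {0.15, 0.25, 0.30, 0.35} and
m ∈ {1, 2}. A literal triple-loop brute-force counter (implemented
independently in the tests and in `scripts/acceptance.py`) must agree
*exactly* — counts and value — on short random series.

## Temporal preprocessing

Per subject, in order: drop the first 10 volumes (scanner
equilibration), per-voxel linear detrend (OLS on intercept + time),
nuisance regression (intercept + global signal, six motion parameters,
CSF and WM signals), temporal band-pass, standardization to zero mean
and unit population SD. Standardization is last so every analyzable
voxel enters the entropy estimator with SD exactly 1.

The filter is a zero-phase forward–backward Butterworth (order 2 per
pass) on the 0.01–0.2 Hz band. At TR = 3 s the Nyquist frequency is
1/6 ≈ 0.167 Hz, below the nominal 0.2 Hz upper edge; the upper edge is
clipped to 0.99 × Nyquist (logged once per band), making the filter
effectively a 0.01 Hz high-pass. Zero-phase filtering avoids lag
distortion of the entropy estimates.

Zero-variance or non-finite voxels are flagged non-analyzable, excluded
from entropy mapping, carried as NaN in every downstream map, and
counted in the run log.

## Group inference

**Voxelwise ANOVA.** The omnibus group test per voxel is the
general-linear-model partial F comparing
`[1, age, sex, education, group dummies]` against
`[1, age, sex, education]`, with p from `F(g − 1, n − g − c)`. Sex is a
single binary covariate; age and education enter linearly. The
linear-algebra path (orthonormal design bases, one matrix product per
map) is cross-checked in the tests against statsmodels' `compare_f_test`.

**Cluster correction.** Supra-threshold voxels (p < 0.001) form
face-connected (6-connectivity) clusters. Cluster-level control uses
label permutation rather than parametric Gaussian-random-field theory:
under Freedman–Lane residual permutation (reduced-model residuals are
permuted and added back to the reduced fit, keeping covariates fixed),
the maximum cluster size is recorded for each of `n_perm` relabelings,
and an observed cluster survives when
`(1 + #{null max ≥ size}) / (n_perm + 1) < 0.05`. This substitution is
deliberate: permutation gives exact-level control at desk scale while
preserving the two-threshold (voxel p / cluster p) structure, and needs
no smoothness estimation. 6-connectivity is the conservative choice.

**Fivefold ROI selection.** Subjects are split into five group-stratified
folds (per-group base allocation plus greedy remainder assignment to the
smallest folds, so 124 subjects give sizes {24, 25} with all four groups
in every fold). For each fold, ANOVA + cluster correction on the other
four folds defines 8-mm spheres at surviving-cluster peaks; the held-out
fold supplies unbiased ROI values. Reports are emitted both per fold and
pooled across folds, labeled as such.

**ROI spheres.** Sphere membership uses voxel-center Euclidean distance
in the affine's mm space, inclusive boundary; peak coordinates are
interpreted through the image affine with no assumption about storage
orientation. Undefined voxels are excluded from sphere means.

**Post-hoc and correlations.** All six group pairs are tested with
two-sample t tests on covariate-adjusted residuals (consistent with the
omnibus model); raw p is multiplied by 6 and capped at 1 (Bonferroni).
Associations between ROI entropy and MMSE / FAQ / CDR / GMV use Spearman
rank correlation with average ranks for ties; within each (score, scale)
family across ROIs, p-values are adjusted by Benjamini–Hochberg FDR by
default (Bonferroni available via configuration) — the correction scope
is a package choice and is recorded in every run manifest.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
validated; its defaults are frozen, not tuning knobs.

**Design.** Four groups of 30/33/32/29 subjects; 20×24×20 voxel grid at
3 mm isotropic with the mm origin at the grid center; 140 volumes at
TR = 3 s, the first 10 carrying a +100 additive offset so a failure to
drop them is caught by downstream shifts.

**Signal model.** Each voxel is a standardized mixture
`w·pink + (1 − w)·white` of unit-variance spectral-synthesis 1/f noise
(power ∝ 1/f, random phases, zero DC) and i.i.d. Gaussian noise. The
pink weight `w` controls the MSE-curve shape directly: `w = 0` falls
steeply with scale, `w = 1` is nearly flat, and after the band-pass the
group contrast grows with scale — the behavior the inference layer is
meant to detect. An AR(1) mode (coefficient = w) exists for robustness
checks. Background voxels share `w = 0.60` in every group; voxels inside
the planted 8-mm sphere at the mm origin take group weights
NC/EMCI/LMCI/AD = 0.90/0.75/0.60/0.45 plus per-subject jitter
(SD 0.05, clipped to [0, 1]). These values were fixed once, by
simulation, to produce a clearly detectable but not saturating contrast
at the default sample sizes (per-voxel scale-6 effect of roughly one
estimator-noise SD between the extreme groups).

**Confounds.** A slow global drift (ramp plus two slow sinusoids), six
smoothed random-walk pseudo-motion traces, and pink-ish CSF/WM signals
are mixed into all voxels with random per-voxel loadings (SD 0.8); the
same regressors are returned as the subject's confound table, so nuisance
regression can remove them exactly.

**Covariates and scores.** Age, sex and education are drawn independently
of group (covariate adjustment is a no-op on average); a confounded mode
shifts AD ages upward to exercise the adjustment. Each subject's
complexity summary `c` (mean planted weight) drives the clinical scores:
MMSE = 10 + 21·c + N(0, 2) (rounded, clipped to 0–30; group means fall
from ≈29 toward ≈20), FAQ = 26 − 28·c + N(0, 3) (rises with severity),
CDR = 2.3 − 2.25·c + N(0, 0.15) clamped to [0, 3]; per-ROI GMV =
4 + 3·c + N(0, 0.4). Slopes echo the familiar clinical pattern
qualitatively; they are not fit to any dataset.

**Determinism.** All randomness flows from one master seed through named
`SeedSequence` substreams (one per subject, separate streams for
permutations), so identical seeds give byte-identical cohorts.

**What the generator does not emulate** — hemodynamic response shape,
spatial autocorrelation, scanner noise physics, tissue anatomy, realistic
effect sizes (no public effect-size information exists to calibrate
against). Passing tests therefore demonstrate the estimator's and the
inference layer's correctness and calibration under a controlled signal
model, not performance on real fMRI.

## Validation problem sizes

The simulation-based checks run at the following sizes, chosen to give
stable rates at desk scale: type-I calibration on 20 null cohorts of
24 subjects/group (scale-2 analysis, 500 permutations each; the fraction
of cohorts with any surviving cluster must stay ≤ 0.10 at cluster
p < 0.05); planted-effect recovery on 20 cohorts at the default
30/33/32/29 design, analyzed at scale 6, where the effect is largest
(cluster overlap with the planted sphere and NC > EMCI > LMCI > AD
ordering of recovered ROI means in ≥ 90% of seeds, correct Spearman
signs vs MMSE/FAQ/CDR in ≥ 95%). The per-scale ANOVA makes the analysis
scale a free choice; scale 2 (null) and scale 6 (planted) keep the two
experiments independent of one another. `scripts/acceptance.py` reruns
the same experiments at 8 repetitions per condition.

## Numerical notes and limitations

- Entropy kernels are numba-compiled; a single-pass multi-radius counting
  kernel serves the large-N white-noise checks and is verified against
  the scalar path count-for-count.
- OLS residuals everywhere use orthonormal (QR) design bases; designs are
  rank-checked, and degenerate confound sets are rejected naming the
  offending columns.
- The permutation null is discrete: with 500 permutations the smallest
  achievable cluster p is 1/501, and surviving-cluster sets can change at
  quantile-boundary clusters when `n_perm` changes.
- Short series (21 points at scale 6) make single-voxel SE noisy and
  occasionally undefined; ROI averaging and the undefined-value
  bookkeeping absorb this, but single-voxel scale-6 values should not be
  over-interpreted.
- The white-noise analytic limit has a small finite-N bias (≈0.003 at
  N = 10⁵); tolerances in the tests account for it.
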
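# Methods

## Model and procedure

### Temporal intersubject correlation (ISC)

The unit of analysis is a subject × video voxel time course: the masked
4D series sliced at the video's onset, with the first `trim_volumes`
volumes discarded to remove transient onset responses (default 2
volumes; at TR 2.62 s that is 5.24 s).  ISC assumes a stimulus-locked
signal component shared across viewers plus idiosyncratic noise; it
makes no assumption about the shape of the shared component.

Correlation cells pair each subject's time course with a leave-one-out
(LOO) average reference:

* **General scheme.**  Same-video cells (reference: LOO average of all
  other subjects for the same video) carry weight +1/V; different-video
  cells, formed only for ordered pairs of videos *within the same run*,
  carry −1/(V(m−1)), where m is the run size.  The weights sum to zero,
  so the contrast is the mean same-video Fisher z minus the mean
  different-video Fisher z.  Cross-run pairs are never formed.
  Different-video references also use the LOO average (excluding the
  correlating subject) so that a subject's own data never enters any of
  their reference time courses.
* **Prior-knowledge scheme.**  Subjects belong to one of two
  complementary condition lists; each same-video cell's reference is
  the LOO average *within the subject's list*, and the cell is labelled
  by the subject's condition for that video (HC = prior narrative
  knowledge, LC = none).  Weights are ±1/(V/2); the contrast is mean
  HC z minus mean LC z.

Pearson correlations are computed voxelwise; series of unequal length
are truncated to the shorter (no interpolation).  Fisher's transform
z = arctanh(r) is applied with |r| clipped to 1 − 1e−7, which keeps z
finite at |r| = 1 while leaving |r| ≤ 0.999999 unchanged to six
decimals.  Voxels with zero temporal variance yield an undefined
correlation, carried as NaN; they are excluded from group inference at
that voxel and counted, rather than being coerced to 0 (z = 0 is a
meaningful value, "no correlation").

If a subject is missing a video, that subject's cells for the video are
dropped and the subject is removed from everyone else's LOO pool for
that video — pools stay consistent without imputation.

### Group inference

The group statistic is the one-sample t per voxel, m̂/(σ̂/√n).  Under
the null that subject contrasts are sign-symmetric about zero, the null
distribution is built by independently negating each subject's map
(i.i.d. ±1 per subject per permutation); the identity flip is always
included, so the smallest attainable p is 1/n_permutations and p is
never 0.  Because the per-voxel sum of squares is invariant to sign
flips, all permuted t-maps reduce to one matrix product, which is what
makes 200-replicate calibration studies cheap.  Tests are one-sided
(same > different; HC > LC), matching the directional hypotheses.

Cluster-extent FWE correction: the observed and every permuted t-map
are thresholded at the per-voxel permutation-null quantile whose
exceedance probability is `height_alpha` (default 0.001); a voxel is
suprathreshold when its t is at least that value, which is exactly the
condition "permutation voxel-p ≤ height_alpha".  A fixed statistic
threshold can be supplied instead (`height_stat`), since published
pipelines differ on whether the height threshold is parametric or
permutation-based.  Suprathreshold voxels are grouped by 26-neighbour
connectivity (6 and 18 are options); the maximum cluster size per
permutation forms the null, and each observed cluster's FWE p is the
proportion of null maxima at least as large.  An empty cluster table is
a valid outcome.  The max-cluster-size null is integer-valued; on small
grids at strict height thresholds its discreteness makes the procedure
conservative (observed familywise error around 0.01 at a nominal 0.05
in the configurations below), which is the accepted behaviour of
extent-based correction, not a defect.

### Semantic consistency of recall

Only remembered trials enter the analysis.  Within each video ×
condition stratum, each subject's embedding vector is correlated
(Pearson, across the d dimensions — not cosine, and vectors are not
re-normalized) with the leave-one-subject-out centroid of the other
remembered recalls.  Per-subject correlations are Fisher transformed
and averaged into one consistency score per video per condition.
Strata with fewer than two remembered recalls cannot form a LOSO
centroid; they are flagged, excluded, and reported.  A centroid with
zero variance across dimensions leaves that subject's score undefined
(flagged NaN).

The condition test operates at the video level: per-video differences
d_v = score(HC) − score(LC) are summarized by the paired t statistic,
whose null is built by flipping the sign of each d_v.  When 2^V does
not exceed the permutation budget the test enumerates all sign patterns
and is exact; the Fisher-z scale is used throughout, consistent with
transforming before averaging.  Videos missing either condition are
dropped with a warning.

### Gray-matter mask

Per-subject gray-matter probability maps are averaged voxelwise,
smoothed with a Gaussian kernel (sigma = FWHM/(√(8 ln 2)·voxel size),
default FWHM 8 mm at 3 mm voxels), and thresholded strictly above 0.3.
An empty mask is an error.

## Synthetic cohorts

The BOLD simulator draws, per video, a latent time course g_v shared by
all viewers: white noise passed through a moving-average window
(`smooth_width`, default 5 volumes) and standardized to unit variance.
A moving average rather than an HRF-convolved event stream is
deliberate: ISC is invariant to the latent's spectrum, so the simulator
avoids hemodynamic assumptions entirely.  Subject s's signal at voxel x
during video v is

    g_v(t) · (base + boost · 1[x ∈ effect_region and cond(s, v) = HC]) + ε,

with ε i.i.d. Gaussian (`noise_sd`).  Defaults base = 1, boost = 0,
noise_sd = 1 give a same-video ISC of roughly 0.6–0.9 depending on pool
size — the regime of strongly synchronized association cortex.  The
counterbalancing generator produces exactly two complementary condition
lists split as evenly as possible over subjects (19 subjects → 9 and
10), mirroring the two-list fMRI design; richer multi-order behavioral
counterbalancing is out of scope.

The embedding simulator draws a per-video centroid
(N(0, centroid_scale²·I), dim default 512) and scatters each subject's
vector around it with isotropic condition-specific noise (σ_HC default
0.5, σ_LC default 1.0 — the planted "prior knowledge tightens recall"
effect; equal sigmas give the null).  Isotropic Gaussian noise is the
simplest model under which the LOSO Pearson statistic is monotone in
the dispersion.  Remembered flags are Bernoulli per condition (defaults
0.84 HC / 0.69 LC, the recall-rate regime of a large online cohort).

What the simulator does *not* emulate: hemodynamic convolution and
undershoot, temporal autocorrelation of scanner noise, motion and
physiological artifacts, spatial smoothness of real BOLD fields,
between-video duration variability, and the lexical structure of real
recall text.  Passing tests therefore demonstrate that the estimators
and permutation procedures are correct and calibrated under the model's
assumptions — not that real acquisitions meet those assumptions.
Notably, real cluster inference depends on spatial noise smoothness,
which is absent here (noise is voxelwise independent), so cluster-size
nulls on real data will be larger.

## Numerical choices

* Pearson denominators of exactly zero → NaN (undefined), propagated
  and excluded from inference; |r| is clipped into [−1, 1] after the
  fast einsum path to absorb rounding at the boundary.
* Fisher clipping ε = 1e−7 (see above).
* Zero-variance voxels inside the t computation: t set to ±∞ when the
  mean is nonzero (all subjects agree), 0 when the mean is zero.
* Sign-flip tests: identity always in the null; scalar tests switch to
  exhaustive enumeration when 2^n ≤ n_permutations (n ≤ 30 guard).
* Onsets are 0-based volume indices; video onsets are assumed
  volume-locked.  Unequal-length series truncate to the shorter.
* Cluster connectivity default 26; exposed as an option.

## Validation scales

Calibration and recovery studies (test suite and
`scripts/acceptance.py`) run at desk scale: null calibration with 12
subjects on 8×8×8 grids (1000 permutations, 200 replicates per test);
planted-effect recovery with a 3×3×3 effect region, base = boost = 1,
noise 1 (50 replicates); semantic power at 100 subjects × 20 videos ×
512 dimensions (50 replicates).  These sizes estimate rejection rates
with Monte-Carlo standard errors around 0.015 while the full suite
completes in well under a minute of compute.

## Known limitations

* The encoder adapter boundary is intentional: the package consumes
  embedding vectors and never runs a sentence encoder; scoring recall
  text as remembered/forgotten is likewise upstream.
* Only one-sample (within-subject contrast) designs are supported; no
  two-sample tests, TFCE, or parametric random-field correction.
* The spatial-pattern variant (ISPS) returns per-subject scalars for an
  ROI; it does not produce whole-brain searchlight maps.
* Preprocessing (realignment, normalization, smoothing of EPI data) is
  assumed done upstream; time courses are used raw, without detrending.
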
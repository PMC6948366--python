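# Methods

`dbsdiff` implements, at desk scale, the analysis workflow used to compare
diffusion MRI acquired before and after deep-brain-stimulation (DBS)
electrode implantation: scalar diffusion metrics, image-quality metrics,
artifact-aware region statistics, Bayesian crossing-fiber modeling with
probabilistic tractography, and two tract-retention statistics.  Because no
patient data ships with the package, a synthetic phantom generator stands in
for the cohort; every number the pipeline reports is computed from volumes
the generator produced under a recorded seed.

## The synthetic two-session subject

A subject is a voxel grid (default 24³ at 2 mm isotropic) holding an
ellipsoidal "brain" of gray matter (GM) with a small CSF blob, white-matter
(WM) fiber bundles defined as tubes around polyline centerlines, integer ROI
labels, and a spherical susceptibility-artifact region.  Voxel coordinates
are 0-based; world coordinates are `index × voxel size` with no oblique
affine, so all masks and labels share one grid and atlas registration stays
out of the test path.

The signal model per voxel and volume is the single-shell ball-and-stick
form

    S(g, b) = S0_t · [ (1 − Σ fᵢ) e^{−b·d} + Σᵢ fᵢ e^{−b·d·(g·vᵢ)²} ],

with at most two sticks per voxel, tissue diffusivities d_WM = 1.2·10⁻³,
d_GM = 0.9·10⁻³, d_CSF = 3.0·10⁻³ mm²/s (plausible literature-range values,
declared as `PhantomSpec` defaults rather than claimed from any
measurement), and
per-tissue proton-density/T2 weights S0_GM : S0_WM : S0_CSF = 1.0 : 0.9 :
1.6.  The tissue weights give the b = 0 image genuine contrast; without
them a b0 volume of this phantom would be a featureless uniform ball and
rigid registration would be ill-posed (we verified this directly — with a
single global S0 the rotation component of motion is unidentifiable).  The
brain ellipsoid semi-axes are deliberately anisotropic (0.46/0.42/0.37 of
the grid extent) for the same reason.

Noise is Rician — `|S + ε₁ + i·ε₂|` with independent N(0, σ²) components —
the correct model for magnitude MR data.  Air voxels therefore carry
Rayleigh noise with mean σ·√(π/2), which the tests verify.

The default acquisition mirrors a clinical single-shell DTI protocol:
32 gradient directions from a deterministic electrostatic-repulsion scheme
at b = 800 s/mm² plus one b0 volume, 2 mm isotropic voxels.

### Encoding the pre/post contrast

The two sessions differ in exactly three knobs:

* noise: σ_pre = 5, σ_post = 40 (at S0 = 1000 this yields session SNRs of
  roughly 150 and 19 — a strong, desk-scale version of the order-of-
  magnitude SNR drop seen between a 3 T anesthetized scan and a 1.5 T awake
  scan with an implanted pulse generator);
* motion: the post session applies a random rigid transform per volume
  (≤1 mm, ≤1° by default; the b0 reference stays fixed), the pre session
  none;
* artifact: a spherical dropout region is active in the post session only.

### Two artifact semantics, deliberately

`apply_artifact` multiplies the *final* magnitude signal inside the mask by
the attenuation factor — the masking operation one would apply to an
already-reconstructed image.  Note that this operation alone cannot degrade
any downstream estimate except at attenuation exactly 0: the tensor fit and
the ball-and-stick sampler both estimate a free per-voxel S0 and noise
level, so they are invariant under per-voxel rescaling of the data.  Real
susceptibility dropout destroys *signal* while thermal noise is unchanged,
collapsing the local SNR.  The simulator therefore also accepts a
`dropout_mask`: attenuation is applied to the noiseless signal *before*
Rician noise, and this is the path the pipeline and the dose-response tests
use.  The attenuation factor is a free parameter (its real-world value is
not quantified anywhere we could anchor it); the default is 0.1.

Motion is applied by resampling the simulated volumes, which physically
corresponds to the diffusion gradient co-rotating with the head.  At the
default amplitudes (≤1–2°) the resulting gradient-table error is well below
the tensor-fit noise floor; the correction stage still rotates b-vectors by
the estimated rotation, as is standard.

## Motion correction

Each non-b0 volume is aligned to the b0 reference with a 6-parameter rigid
transform (the phantom's motion is rigid and eddy-current physics is out of
scope, so the extra degrees of freedom of an affine would only add
variance).  The similarity metric is normalized cross-correlation between
the volume and the *candidate-warped reference*.  Two details matter and
were chosen after measuring alternatives on the phantom:

* Warping the reference rather than the moving volume keeps the moving data
  un-interpolated.  Metrics evaluated on a resampled moving image acquire a
  spurious optimum at transforms that minimize interpolation smoothing
  (integer-voxel shifts, the identity), large enough here to swallow a 5°
  rotation.
* Histogram-based information metrics (32-bin NMI, correlation ratio) were
  too flat at 24³ resolution to resolve rotations; NCC on the warped
  reference resolves 5° to better than 0.1° on this phantom.  The b0-to-DWI
  intensity mapping of each tissue class is monotone, so correlation
  remains a valid cross-contrast criterion at this image scale.

The optimizer is a 5³ coarse grid over translations (±4 mm) followed by
Nelder–Mead on all six parameters with an explicit initial simplex
(0.75 mm / 1°).  A volume whose optimization fails to converge is passed
through unresampled, recorded as identity and flagged.  Translations are
reported in millimetres (the unit is stated because published motion
summaries of this kind sometimes omit it), rotations in degrees; session
summaries are means of absolute per-volume values, and the post/pre ratio
is reported with a NaN-plus-warning convention when the reference session
shows zero motion.

## Tensor scalars

The diffusion tensor is estimated by weighted log-linear least squares
(weights = squared signal): deterministic, iteration-free, exact on
noiseless single-tensor data (verified to 10⁻⁹ relative).  Signal values
≤ 0 are floored at machine-epsilon × the voxel's b0 before the log.
Negative eigenvalues are clamped to zero and the voxel flagged; clamped and
invalid voxels are excluded from ROI statistics.  FA, MD and RD follow the
standard eigenvalue formulas; FA is clipped to [0, 1].

The known Rician noise bias — lower SNR inflates FA in isotropic tissue —
is reproduced by the generator + estimator pair and asserted as a
monotonicity property over the σ grid {0, 20, 40, 80}.

## Quality metrics

SNR = Mean_GM / SD_AIR and CNR = (Mean_GM − Mean_WM) / SD_AIR, computed per
volume (sample SD with n − 1 over the air mask) and averaged across all
volumes including b0 (an `exclude_b0` flag is provided; the published
definition does not separate the cases, so the inclusive reading is the
default and is documented).  CNR may legitimately be negative.

## ROI statistics

ROIs intersecting the artifact mask in ≥1 voxel are "affected".  For each
(ROI, scalar) pair the pre and post voxel values — paired by voxel index,
valid voxels only — enter a two-sample Kolmogorov–Smirnov test at
α = 0.05.  KS rejection routes to a paired Wilcoxon signed-rank test (zero
differences dropped; all-zero differences reported as p = 1 and flagged
degenerate); otherwise a paired t-test with a 95% CI for the mean
difference (post − pre).  Exactly one branch p-value is populated per ROI.
`p > α` is reported as "similar" to mirror the convention of the study
design being reproduced; this is similarity-by-nonrejection, not an
equivalence test, and is labelled as such.  No multiple-testing correction
is applied by default (faithful to the original analysis across its 127
structures); Benjamini–Hochberg is available behind a flag.

The voxel-pairing requirement restricts the statistics to equal-grid
sessions.  For real data the pairing would come from registration; the
artifact requires the common grid and says so.

## Crossing-fiber model and tractography

The ball-and-stick posterior (≤2 sticks) is sampled with
Metropolis-within-Gibbs, all voxels advancing as vectorized chains:
Gaussian random-walk proposals per parameter block — two orientation blocks
in spherical angles with the sin θ area correction, two fraction blocks, a
diffusivity block with a Gamma(shape 2, mean 1.5·10⁻³ mm²/s) prior, an S0
block — plus a conjugate inverse-gamma Gibbs update of the noise variance.
Stick fractions carry automatic-relevance (1/f) shrinkage priors; a stick
counts toward the voxel's fiber support only if its posterior mean fraction
exceeds 0.05.  Without the shrinkage prior an isotropic voxel at SNR 40
retains a spurious stick roughly half the time; with it, fewer than 10%.
Proposal scales adapt toward 35% acceptance during burn-in (default 400
iterations, then 60 samples at thinning 2, i.e. ≥50 retained samples per
voxel); voxels whose post-burn-in acceptance leaves [0.05, 0.95] are
flagged.  The noise SD has a floor of 10⁻³·S0 so noiseless test fixtures
remain samplable.

Tracking follows the referenced implementation's conventions where the
published description is silent: the curvature threshold is the minimum
cosine between successive steps (0.2 ≈ 78.5°); propagation is bidirectional
(two half-tracts per sample, either half reaching the target is a success);
orientation lookup is nearest-voxel (position floored to an index, no
orientation interpolation); the loopcheck records the first entry direction
per half-resolution cell and terminates a streamline re-entering a cell
against that direction.  At each step one posterior sample is drawn and a
stick chosen with probability proportional to its f (ties therefore break
uniformly at random); the drawn direction is sign-aligned with the previous
one.  Defaults are 5000 samples per seed voxel, 0.5 mm steps and loopcheck
on; the desk-scale study configuration reduces samples to 500 per voxel.

A consequence of f-proportional stick choice worth knowing: a voxel where
two bundles cross acts as a stochastic attrition zone, because each step
has roughly an f₂/(f₁+f₂) chance of drawing the transverse stick and dying
on the curvature check.  The default study phantom therefore keeps its
three tracts disjoint; crossing geometry remains available and tested at
the phantom and model levels.

Streamline RNG is organized per chunk of seed samples with per-chunk
spawned seeds, so runs are reproducible and tightening only the curvature
threshold on a fixed seed can never increase success counts (the property
tests assert this).

## Connectivity statistics

The *index of connection probability* is the mean per-seed-voxel count of
successful samples (the raw count, not divided by samples-per-voxel: the
published magnitudes, e.g. 204.8, are counts) and the *streamline density*
is the percentage of seed voxels with ≥1 successful streamline, with the
numerator restricted to seed voxels (the table footnote's reading; the
loose reading "any nonzero map voxel" would not yield a percentage of the
seed).  Percent change is 100·(pre − post)/pre, undefined (NaN with a
warning) at pre = 0, rounded half-away-from-zero to one decimal in reports.
The voxel-wise pre/post comparison is a two-tailed Welch t-test on the
visitation values inside the target ROI, voxels treated as independent
observations (spatial autocorrelation is ignored, as in the analysis being
reproduced; the caveat stands).

## Pipeline and reproducibility

`run_study` chains the stages and derives every stage seed as
`sha256(master_seed : stage_name)` mod 2³¹, so stages are independently
re-runnable and a rerun with the same master seed is bit-identical (tested
on the emitted CSVs).  A failing stage aborts with the stage name; outputs
written before the failure are preserved.  The manifest records package and
dependency versions, all stage seeds, key parameters and aggregated
warnings (clamped voxels, non-converged registrations, flagged chains).

Problem sizes in the shipped configurations — 24³ grid, 33 volumes,
500 tracking samples per seed voxel, 520 MCMC iterations per voxel — are
the package's desk-scale defaults; they were chosen so a complete study
runs in minutes on a single core while every qualitative contrast of
interest (noise-driven FA inflation, artifact-driven tract loss, motion
recovery) is comfortably resolved above Monte-Carlo noise.

## What the phantom does and does not show

Passing tests demonstrate that the estimators and statistics behave
correctly on data whose ground truth is known, and that the qualitative
phenomenology — upward FA bias at low SNR, collapse of tract
reconstruction through a dropout region, affected-ROI statistics departing
more than unaffected ones — emerges from the modeled physics.  They do not
certify performance on real scans: the phantom has piecewise-constant
tissue, no susceptibility geometry beyond a sphere, no eddy currents, no
slice-wise artifacts, no partial-volume gradients at tissue boundaries, no
cardiac or slow drift, and its motion is volume-wise rigid.  Absolute
published patient values (SNR 324.56 vs 8.26, the per-structure
percentages, the absolute index/density magnitudes) depend on real anatomy
and scanner hardware and are not reproduction targets; the arithmetic that
produced them (the metric definitions and the percent-change computation on
the printed values) is.
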
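# Methods

## Generative model of the synthetic data

Each naturalistic condition `c` has a single shared signal `s(t)`: white
Gaussian noise spectrally masked to the analysis passband (0.008–0.09 Hz by
default) and standardized. Masking guarantees the planted signal is
invariant under the pipeline's own band-pass step, so preprocessing cannot
destroy (or manufacture) the quantity being estimated. A voxel `v` of
subject `i` inside a parcel of network `n` follows

    y(t) = a(n, c) * sigma_shared * s(t)
         + sigma_subject * g_i(t)
         + sigma_voxel * e_vi(t)
         + nuisance terms

with couplings `a >= 0` per (network, condition). `g_i` is shared across all
of a subject's gray-matter voxels but independent across subjects: it
creates realistic within-subject correlations between regions while
contributing nothing to inter-subject correlation. An implementation that
accidentally correlates data within subject (e.g., by using the grand
average rather than the leave-one-out average) is caught by this term.
Gray-matter voxels outside any parcel carry no stimulus-locked signal.

Defaults emulate the target study design: ~30 subjects per condition
(28–32 in the study), 160 frames at TR = 2 s (≈5–7 min runs), seven
conditions spanning the four types (+Lang+ToM ×3, −Lang+ToM ×3,
+Lang−ToM ×1, rest), a 5-parcel language network and 6-parcel ToM network,
couplings 0.35/0.10 (language, ±Lang) and 0.30/0.10 (ToM, ±ToM), rest = 0
everywhere. `sigma_subject = 0.5` and `sigma_voxel = 1.0` make voxel noise
the dominant source, with region-mean effective noise
`sigma_subject^2 + sigma_voxel^2 / m` for an `m`-voxel fROI.

Nuisance contamination is injected with known sources at half the shared
signal's amplitude: a random quadratic drift, a motion-locked artifact
linear in the motion-parameter derivatives (the leading-order form of
motion contamination, and removable by motion regression), and WM/CSF
compartment signals that dominate their compartments and leak weakly into
gray matter. All sources are stored as ground truth so nuisance removal is
verifiable (residual correlation with every injected source < 0.05).

What the generator does **not** emulate: scanner physics, spatial
misalignment, hemodynamic nonlinearity, empirically realistic BOLD noise
spectra (subject and voxel noise are white before filtering), or
heterogeneous fROI sizes. Passing tests therefore demonstrate the
correctness and statistical behavior of the *pipeline*, not claims about
any particular real dataset.

## The leave-one-out ISC expectation

For `y_i = a*s + n_i` with independent noise, the correlation of subject
`i` with the average of the other `N−1` subjects converges (large T) to

    r(a, sigma_s, sigma_n, N) =
        a^2 s^2 / sqrt( (a^2 s^2 + n^2) * (a^2 s^2 + n^2/(N−1)) )

(`s^2 = sigma_s^2`, `n^2 = sigma_n^2`). At `a = s = n = 1, N = 30` this is
0.6952, verified in-suite by direct Monte-Carlo at T = 1e5. The expectation
is strictly increasing in `a` (for `n > 0`) and in `N`; the empirical mean
inherits both monotonicities.

## Preprocessing choices

* Filter realization: zero-phase forward–backward 2nd-order Butterworth
  (an FFT-mask alternative is available via `method="fft"`); both meet the
  ≤1 dB passband / ≥20 dB stopband contract, and provenance records which
  was used.
* Outlier frames are *regressed out* with spike columns, never deleted —
  deletion would desynchronize subjects, which ISC cannot tolerate.
* Framewise displacement: sum of absolute differences of the three
  translations plus the three rotations converted to arc length on a 50 mm
  sphere (the conventional constant).
* Noise-ROI components: top-5 temporal PCs per compartment after per-voxel
  mean removal only (no variance normalization), plus the compartment mean
  signals as separate columns.
* Polynomial detrending (order 2) is included in the nuisance design: the
  band-pass alone leaves an in-band tail of slow drifts at these run
  lengths.
* The 200 s high-pass (cosine drift columns) lives only in the localizer
  GLM path; naturalistic runs get the 0.008–0.09 Hz band-pass.

## fROI definition

Canonical HRF: double-gamma with 6 s peak, 16 s undershoot, 6:1 amplitude
ratio, unit-sum normalized (so a sustained boxcar plateaus at 1). Top-10%
rule with ceiling rounding and a 1-voxel minimum guarantees a non-empty,
size-matched fROI in every subject; ties at the threshold break by
ascending voxel index for cross-platform determinism. The suprathreshold QC
count uses the positive tail only (the localizer contrasts are directional)
with the p < 0.001 threshold converted to a t quantile at the GLM's
residual df; subjects with fewer than 100 such voxels across a network's
parcels are excluded (boundary: 99 fails, 100 passes). Voxels claimed by
fROIs of two or more networks within a subject are removed from all of
them. Anatomically defined ROI sets (e.g., early auditory/visual cortex)
bypass fROI definition and use the parcels directly.

## ISC conventions

Time courses start `ceil(6 s / TR)` frames after stimulus onset (excluding
the initial hemodynamic rise) and end at stimulus offset, excluding the
trailing fixation. Each subject's fROI-mean series is z-scored; the
reference is the unweighted mean of the *other* subjects' z-scored series
(not re-standardized — Pearson r is invariant to that choice). Correlations
are clipped to |r| ≤ 1 − 1e−7 before arctanh so r = ±1 maps to a finite
z ≈ ±8.4. Conditions completed by different subject subsets are handled
within-condition; the long table carries per-condition N. Network-level
summaries average Fisher-z across a network's fROIs within subject.

## Surrogate null and its known anti-conservatism

Per participant, 1000 surrogates are built by randomizing the Fourier
phases of that participant's series (amplitude spectrum — hence
autocorrelation — preserved exactly; DC and Nyquist bins keep their phase
so the surrogate is real with the original mean) and correlated against the
*veridical* leave-one-out average; the Fisher-z values' sample mean and sd
parameterize a Gaussian. Per-participant Gaussians are combined as
`mu = mean(mu_i)`, `sigma = sqrt(sum sigma_i^2)/N`, and the observed group
mean is z-scored against this and converted to a one-tailed p. Surrogate
seeds derive deterministically from a master seed and the (fROI, condition,
subject) labels.

The combination assumes the N per-participant ISCs are independent under
the null. They are not: each leave-one-out value is approximately an
average of pairwise correlations, and any two participants share N−2
reference members plus each other, giving `Cov(r_i, r_j) > 0`. For white
data the true variance of the group mean is ≈2× the combined value (sd
ratio √2, from the pairwise-overlap count); for band-limited data,
fourth-moment terms raise it further (measured ≈1.8–2.0× in sd at N = 10,
T = 150 in-band frames). Consequences, quantified by the suite's
calibration audit and `scripts/acceptance.py`:

* the zero-coupling rejection rate at nominal α = 0.05 is ≈0.17 rather
  than 0.05, and the null z-score sd is ≈2 rather than 1;
* the resting-state reality check is non-significant in ≈3/4 of
  replicates rather than ≥95%.

This is an intrinsic property of analytically combined per-participant
nulls for leave-one-out ISCs, kept as specified because the analytic
combination *is* the procedure under study; the audit numbers document its
size. Planted effects in this package are large relative to the inflation,
so the dissociation analyses are unaffected in practice. A fully calibrated
alternative would randomize all participants jointly and build the null of
the group mean directly; that variant is out of scope here.

## Mixed-effects models

The solver fits `y = X b + sum_k Z_k u_k + e` with independent
(uncorrelated) effects per random term: intercepts for participant, fROI,
and condition (the last two crossed), and by-participant slopes for each
coded fixed effect. Estimation is REML, profiled over the residual
variance, optimized over log variance ratios with L-BFGS-B (two starts);
all linear algebra runs through the Woodbury identity on precomputed
cross-products, so a fit costs O(q^3) in the total random-effect dimension
regardless of row count. Fixed-effect tests use Satterthwaite df computed
by the delta method from numerical gradients/Hessians of the REML deviance
in the variance parameters; components estimated at the zero boundary are
held fixed, and the df is clamped to [1, n − p]. Against R lmerTest on an
interior-case dataset (all components positive), estimates and SEs agree to
~1e−4/1e−3 relative and Satterthwaite df to a few percent.

Design choices:

* Two-level factors are coded −1/2, +1/2 (sum-to-zero), so a main-effect
  beta is the difference of level means and the interaction beta a
  difference-of-differences, symmetric in factor ordering up to sign.
* Random slopes are uncorrelated with the intercepts (lme4 `||` style).
  With correlated structures the maximal model frequently hits singular
  fits at these sample sizes; the uncorrelated parameterization keeps the
  same variance structure on the diagonal while remaining estimable.
* Non-convergence ladder: drop the interaction slope, then the
  condition-type slope, then the network slope, then the condition
  intercept, then the fROI intercept; the structure actually fitted is
  recorded on every result.
* Baseline (intercept) tests are one-tailed (ISC > 0), matching the
  one-tailed surrogate test; factor contrasts are two-tailed. Families of
  baseline tests are BH-FDR corrected.
* A constant response yields a flagged degenerate result (OLS estimates,
  `converged=False`, NaN statistics), never an exception.

## Problem sizes

Replicated studies (calibration, dissociation recovery, resting state) run
on a reduced configuration — 12×12×6 voxel grid, 3 parcels × 12 voxels per
network, N = 10–20 — chosen so that hundreds of independent end-to-end
replicates are practical on a single CPU while every stage (simulation,
nuisance regression, filtering, ISC, surrogates, mixed models) still runs
in full. Single showcase runs use the default 20×20×10 grid. The
consistency check uses T = 2000 frames so the large-T expectation applies
within ±0.02.

## Known limitations

* The surrogate-null combination's anti-conservatism, quantified above.
* One-sample (baseline) tests across participants inherit a milder version
  of the same dependence problem: between-participant variance of
  leave-one-out values underestimates the variance of their mean.
* The generator's noise is white pre-filtering; real BOLD noise spectra are
  not emulated, and surrogate sigma estimates on real data would differ.
* Uncorrelated random effects: intercept–slope covariances are not
  estimated.
* No pairwise-ISC variants, ISFC, time-resolved ISC, subject-level
  inference, or Bayesian models.
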
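# Methods

This note documents the models, estimators and numerical conventions the
package implements, the design choices made where several conventions are
defensible, and what the synthetic-data generators do and do not emulate.

## Functional connectivity

Regional BOLD series (default 150 timepoints at TR = 2 s) are linearly
detrended and band-pass filtered by frequency-domain masking: rFFT bins with
low ≤ f ≤ high (defaults 0.01 and 0.1 Hz) are kept, everything else
including DC is zeroed.  The ideal (brick-wall) filter was chosen over an
IIR design because it preserves in-band sinusoids to ≥ 99% amplitude and
suppresses out-of-band content below 1% — the behaviour the downstream
correlation analysis assumes — and because it is exactly invertible and
deterministic.  Its known cost (ringing at band edges for broadband
transients) is immaterial for stationary resting-state series.

Connectivity is Fisher-transformed Pearson correlation, z = atanh r, with r
clipped to |r| ≤ 1 − 10⁻⁷ so z stays finite (z_max ≈ 8.38) while preserving
ordering.  Mean FC of a region is the arithmetic mean of its off-diagonal z
values across **all** other regions, including the contralateral ones;
bilateral FC is the z of the left/right pair, with pairing derived from
`_L`/`_R` label suffixes.  Group matrices are elementwise means on the z
scale.  Hemisphere assignment on grids uses the sign of the first world
coordinate under the volume's affine (0-based voxel indexing).

Seed maps correlate every voxel with the **mean** signal over the seed mask
(the first principal component is a defensible alternative; the mean is the
common small-animal convention and is what the generators plant).  The group
seed map is a one-sample t across subjects' z-maps against 0 with df = n − 1
— the standard second-level construction consistent with a T-score display.
Per-region group comparisons run independent two-sample t-tests and correct
the per-region p-values with the Holm-Šidák step-down.

Motion-covariate residualisation is available in principle ahead of the
filter but is off by default; realignment and spatial preprocessing are out
of scope, and the package assumes co-registered, preprocessed inputs.

## Diffusion tensor imaging

The single-shell signal model S = S₀ exp(−b ĝᵀ D ĝ) is inverted per voxel by
log-linear least squares (design row [1, −b gx², −b gy², −b gz², −2b gx gy,
−2b gx gz, −2b gy gz] against ln S).  The log-linear fit is deterministic and
exact on noiseless data, and is adequate at a single b = 800 s mm⁻² shell;
weighted or nonlinear fits matter mostly at high b or very low SNR.
Non-positive samples are clamped to the smallest positive observed signal
and flagged; negative eigenvalues are clamped to zero and flagged, which
keeps FA ∈ [0, 1] without discarding voxels.  Eigenvalues are sorted
λ₁ ≥ λ₂ ≥ λ₃.

FA uses the standard definition √(3/2)·‖λ − MD‖/‖λ‖; a tensor whose norm is
at numerical zero (‖λ‖ ≤ 10⁻¹⁴, i.e. eleven orders below physiological
diffusivities) is reported as isotropic (FA = 0) rather than amplifying
round-off.  At SNR 30 (Gaussian noise) the median FA bias at true FA 0.8 is
below 0.02.

The voxel-wise group test is a pooled-variance two-tailed t with
df = nA + nB − 2; `critical_t(p, nA, nB)` returns the |T| display bound for
an uncorrected p.  For 7 vs 6 subjects this gives T = 2.20 at p = 0.05 and
T = 3.50 at p = 0.005 (T = 3.3 corresponds to p ≈ 0.0071 two-tailed at
df = 11).  Structure volume is reduced to voxel count × voxel volume over a
supplied mask; manual delineation tooling is out of scope.

## EM morphometry

Micrographs follow the backscatter-SEM convention: myelin dark on a light
background, origin top-left, row-major, pixel size in nm (7 nm/px default).
Segmentation thresholds the dark phase with Otsu's parameter-free method
(a fixed threshold can be supplied), labels connected myelin components,
and fills holes: filled component = outer region, holes = inner lumen.
Diameters are circular-equivalent, 2√(A/π), so d, D, thickness (D − d)/2 and
g = d/D are area-based and rotation-tolerant to one quantisation step.

Exclusion gates: components touching the image border, components without a
lumen (solid debris), inner diameter below 0.2 µm, and g outside
(0.2, 0.98).  All exclusions are flagged per record and reported, never
silently dropped.  Binned profiles bin on the **inner** diameter d (the
quantity usually called "axonal diameter"), default 0.1 µm bins over
[0.3, 1.5] µm, and compare genotypes with a type-II genotype × bin ANOVA
plus per-bin t-tests under Holm-Šidák.

Quantisation bound: on noiseless synthetic annuli with D ≥ 20 px the 1-px
anti-aliased edge yields mean |g error| < 0.02 (measured ≈ 0.0006); the
g-ratio is exactly invariant under pixel-size rescaling because both
diameters scale linearly.

## MEA and patch-clamp analysis

Noise s.d. is estimated as MAD/0.6745 — the robust Gaussian-consistent
estimator, insensitive to the spikes themselves (≤ 5% bias at 1% spike
samples of 8σ).  The trace is conditioned with a zero-phase 2nd-order
Butterworth high-pass at 100 Hz before detection (the recording chain's
"100 Hz" filter is interpreted as high-pass conditioning: spike energy
lives near 1 kHz, and a low-pass at 100 Hz would abolish spikes; the step
can be disabled).  Detection is negative-only at −5.5 × s.d.; each
sub-threshold excursion yields one spike timed at its most negative sample,
and excursions within the 1 ms dead time merge into the deeper minimum.
Detection is invariant under global trace rescaling because the threshold
scales with the estimated s.d.

A burst is a **maximal** run of at least 5 consecutive spikes whose
inter-spike intervals are all **strictly** below 50 ms; maximality makes
bursts disjoint, which is the only reading under which burst counts and
rates are well defined.  Spike rates are reported in Hz and burst rates per
minute; slice-level values average electrodes whose spike rate reaches a
configurable activity floor (default 0.01 Hz).  Rate distributions are
compared with the two-sample KS test on the empirical CDFs.

EPSC trains (5 pulses at 20 Hz) are normalised to the first pulse;
EPSC₅/EPSC₁ < 1 indicates short-term depression, > 1 facilitation.

## Behavioural indices

PPI% = 100 − 100·(mean prepulse+pulse startle at one intensity)/(mean
pulse-alone startle), the denominator taken from the block-2 pulse-alone
trials only; blocks 1 and 3 are stored but unused by the formula.  Prepulse
intensities are coded in dB above background {0, 3, 7, 11, 19}; the 0 dB
condition is scored like any other (its expected PPI is 0).  Negative PPI
(facilitation) is legal, and the index is invariant under rescaling of all
amplitudes.

Spontaneous alternation collapses immediate re-entries, then scores every
sliding triplet of visits as alternating iff its three arms are distinct:
score = 100 × alternations/(visits − 2).  For a uniform random walk without
self-transitions the third visit differs from the first with probability
1/2, so the score converges to 50%.  The touchscreen criterion is inclusive
(≥ 80% on 3 consecutive sessions) and returns the closing session of the
first qualifying run.  Preference, slip and marble indices are the plain
percentage formulas with validation of their domains.

Trial-resolved scores feed the mixed-design ANOVA below; subject averages
across trials feed a two-sample t-test.

## Statistics

Scalar tests delegate to scipy (pooled t by default, Welch optional;
Mann-Whitney exact for tie-free samples up to n = 20, asymptotic with tie
correction beyond; asymptotic two-sample KS).  Degenerate zero-variance
comparisons use the p = 1 (equal means) / p = 0 (unequal) convention with a
flag rather than NaN.

Holm-Šidák: sort the m raw p ascending; the i-th gets candidate
1 − (1 − p₍ᵢ₎)^(m−i+1); a running maximum enforces monotonicity and values
are capped at 1; rejection proceeds while adjusted p < α.  The single-step
Šidák adjustment 1 − (1 − p)^m serves the post-hoc comparisons.

The two-way ANOVA for crossed factors uses type-II sums of squares
(statsmodels), stable under the unbalanced cell counts that arise when axon
numbers differ per genotype.  The repeated-measures (mixed) ANOVA is the
classical univariate decomposition: the between-group effect is tested
against subjects-within-groups (df = N_subjects − n_groups, e.g. (1, 29)
for 15 + 16 subjects), the within effect and interaction against the
subject × within residual.  No sphericity correction is applied by default,
matching the uncorrected-df convention of common analysis software; the
implementation is cross-checked against an independent mixed-ANOVA
implementation in the test suite.  Post-hoc between-group comparisons at
each within level use the pooled error term
(SS_between-error + SS_within-error)/(df_b + df_w) with single-step Šidák
over the m planned comparisons — the convention of common GUI statistics
packages; a per-level error term is the main defensible alternative and
would differ only under strong variance heterogeneity across levels.

## Synthetic data: what it does and does not emulate

Generators are deterministic given their seed and carry their planted truth.

* **ROI signals**: white noise → ideal band-pass → per-row standardisation →
  Cholesky mixing plants the target correlation exactly in expectation;
  optional white-noise admixture. Emulated: band-limited spectra, homotopic
  structure, group effects, 150 × TR 2 s geometry. Not emulated: scanner
  drift, motion, physiological (cardiac/respiratory) aliasing, spatial
  autocorrelation — so passing recovery tests validates the estimator
  chain, not robustness to those artefacts.
* **DWI**: exact tensor-model signals; Gaussian noise of s.d. S₀/SNR by
  default so the log-linear fit stays unbiased in recovery tests (Rician
  available).  Eigenframes with λ₂ ≠ λ₃ have an arbitrary in-plane
  orientation, which no rotation-invariant scalar sees.
* **EM**: annuli with a 1-px linear coverage ramp (anti-aliasing) at both
  radii, optional Gaussian noise and a non-overlap check. Not emulated:
  elliptical/crenellated axons, inner mitochondria, touching myelin
  sheaths — the main failure modes of real segmentation.
* **MEA**: Gaussian baseline plus a 1 ms biphasic dominant-negative
  template (unit peak, representable at 10 kHz); per-spike amplitudes may
  vary. Not emulated: LFP, electrode drift, overlapping units.
* **Behaviour**: trial tables whose expected index equals the planted truth;
  startle uses a truncated-at-zero normal around the planted means.

## Problem sizes and tolerances

Recovery suites use 100 subjects (FC convergence), 100 reseeded simulations
(power and detection rates), a 32³ voxel volume (DTI), 500 axons (EM) and
10⁴ null simulations (type-I calibration) — sizes at which every Monte-Carlo
band quoted above is comfortably resolved while the whole suite runs in
under a minute.  Key numerical constants: Fisher clip 1 − 10⁻⁷; FA zero-norm
floor 10⁻¹⁴; spike dead time 1 ms; burst rule ≥ 5 spikes, ISI < 50 ms
strict; Holm-Šidák cap at 1.  Known limitations: no spatial preprocessing
(realignment/normalisation/smoothing), no tractography or skeletonisation,
no spike sorting, no video tracking; inputs are assumed co-registered and
artefact-free.
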
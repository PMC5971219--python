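# Methods

`babydcm` implements a complete in-silico pipeline for estimating effective
connectivity from infant fNIRS recordings with dynamic causal modelling
(DCM), together with the photon-transport and preprocessing machinery the
method needs and a synthetic "twin" harness (simultaneous fNIRS + BOLD from
one neural ground truth) for validating it end to end. This note records
the models, the defaults and why they were chosen, the numerical choices,
and what the synthetic validation does and does not demonstrate.

## Geometry

The head is a three-layer tetrahedral slab: scalp/skull + extra-cerebral
tissue, CSF, and brain, with the scalp face at z = 0 and depth increasing
with +z (coordinates in mm). A structured grid is split into six Kuhn
tetrahedra per cell with a shared main diagonal, which keeps the mesh
conforming and positively oriented at any resolution. Default layer
thicknesses are 5 mm (scalp/skull) and 2 mm (CSF) — plausible infant-scale
values, configurable. A slab rather than a curved head is deliberate: it
admits a closed-form photon-transport oracle; curvature effects are out of
scope.

The probe fixture reproduces the study array topology — 4 sources and
4 detectors forming exactly 9 channels at 2 cm separation — with planar
coordinates chosen by this package (the published array figure is not
numerically specified). Channels are enumerated by detector id then source
id over all pairs at the nominal separation, which makes the channel list
independent of optode insertion order.

## Photon transport

Channel sensitivity functions (photon measurement density functions,
PMDFs) follow the standard adjoint recipe: solve the continuous-wave
diffusion approximation

    (-div kappa grad + mua) phi = q,    phi + 2 A kappa n.grad phi = 0 on the boundary,

with kappa = 1/(3(mua + mus')), by linear finite elements (consistent mass,
exact P1 stiffness, Robin boundary mass with coefficient 1/(2A)); form the
product of the forward field (source) and adjoint field (detector), weight
by lumped nodal volumes, and normalize by the unperturbed measurement
amplitude (Rytov), so entries approximate d(-ln I)/d(mua). The mus in the
kappa formula is interpreted as the *reduced* scattering coefficient, the
standard diffusion-approximation usage. A collimated optode is modelled as
an isotropic point source buried one reduced scattering length below its
scalp projection, with the load distributed barycentrically; detector
measurements interpolate the field with the same weights as the adjoint
load, which makes source-detector reciprocity exact up to solver precision.

Baseline tissue coefficients at 770/850 nm ship as replaceable
literature-style defaults for neonatal tissue (scalp/skull mua
0.017/0.019, mus' 0.74/0.64; CSF 0.004/0.004, 0.30/0.30; brain
0.018/0.021, 0.55/0.50 mm^-1); the refractive-mismatch term defaults to
A = 2.82 (tissue-air, n ~ 1.4). Systems are factored directly (SuperLU)
below 50k nodes and solved by conjugate gradients (relative residual
1e-10) above.

Numerical caveats, verified in the tests:

- The solver is checked against the extrapolated-boundary semi-infinite
  closed form on a homogeneous slab. At ~14k nodes (1.35 mm grid) the
  nodal error is below 10% throughout the measurement zone (lateral offset
  5–10 mm from the source, depth 2–12 mm, 10 mm clear of the walls). The
  error grows toward the source axis (point-load resolution) and with
  distance (grid dispersion in the effective decay rate), which is why the
  zone is quoted laterally.
- Linear FEM with consistent mass has no discrete maximum principle:
  small negative fluence undershoots (order 1e-5 of the peak at 2.5 mm
  resolution) occur far from the source. PMDF rows are non-negative up to
  the same vanishing undershoot.
- PMDF entries condensed onto single elements agree with brute-force
  absorption perturbation (re-solve) to < 5% at 2.5 mm resolution; the
  exact discrete derivative uses the consistent element mass and agrees to
  ~1e-5, the difference being the lumped nodal weighting of the PMDF
  definition.

Cortical source regions are 4 mm spheres; their sensitivity is the sum of
PMDF entries over the region's brain-labelled nodes.

## fNIRS preprocessing

Raw intensities convert to optical density (-ln I/I0 against a baseline
window) and to chromophore changes by the modified Beer-Lambert law with
DPF = 5.13 at both wavelengths (one value is standard for this infant age)
and bundled extinction coefficients at 770/850 nm from a standard
compilation (HbO 6.38e-4 / 1.097e-3, HbR 1.311e-3 / 7.81e-4 in
uM^-1 mm^-1, replaceable). Temporal filtering is a 5th-order Butterworth
high-pass at 0.008 Hz plus band-stops over 0.06–0.16 Hz (Mayer waves) and
0.8–1.8 Hz (cardiac), applied forward-backward (zero phase; the two-pass
scheme doubles the effective order). Motion artifacts are flagged where
the centred 1 s moving SD of the haemoglobin series exceeds 3 uM; flagged
segments can be dilated (e.g. 3 s forward) so the slow decay tail of a
spike — which moves the moving-SD much less than its onset — is included.
Correction fits a cubic smoothing spline per flagged segment, subtracts
it, and re-levels the segment to the preceding clean mean; unflagged
samples are untouched.

Trial averaging extracts per-condition epochs over [-2, +22] s (9 s block
plus rest), baselines each to its pre-onset mean, and averages. The
averager also returns (i) matching averaged stimulus functions (optionally
with a lead-in window of input history), (ii) the window start samples it
actually used, and (iii) the per-epoch residuals about each condition
mean. The residuals matter: their average periodogram, scaled by
1/(n_epochs - 1), is a model-free estimate of the noise spectrum of the
trial average with n-1 degrees of freedom per frequency bin (a split-half
odd/even estimate is also provided).

## The generative model

Neural dynamics are the standard bilinear DCM state equation
dz/dt = (A + sum_j u_j B_j) z + C u over three regions (IFG, STS, TPJ) and
two inputs (V = voice, NV = non-voice). Each region's activity drives a
balloon model (vasoactive signal, inflow, venous volume v,
deoxyhaemoglobin q) with defaults kappa_s = 0.64 1/s, gamma = 0.32 1/s,
tau = 2 s, alpha = 0.32, E0 = 0.32 — the standard published forms and
values, configurable; the study itself inherits them from the cited
literature. Chromophore changes in the cortical regions follow
dHbT = HbT0 (v-1), dQc = HbR0 (q-1), dHc = dHbT - dQc with baselines
HbT0 = 100 uM, HbR0 = 40 uM; only products of these baselines with the
optical gain are identifiable, and that product is absorbed by the free
scaling k below.

The fNIRS observation stacks, per wavelength,

    y(lambda) = eps_H(lambda) W_H(lambda) S(lambda) dHc
              + eps_Q(lambda) W_Q(lambda) S(lambda) dQc,   S = k * S0,

with S0 the channels-by-regions optical sensitivity from photon transport,
W_H = W_Q = 1 by default (no pial-vein correction), and k a free scaling
with the informed log-normal prior log k ~ N(0, 1/16), accommodating
source strength and detection efficiency. A standard BOLD observation
y = V0 (k1 (1-q) + k2 (1-q/v) + k3 (1-v)), V0 = 0.04, k1 = 7 E0, k2 = 2,
k3 = 2 E0 - 0.2, provides the fMRI twin.

Integration is fixed-step RK4 (dt <= 0.1 s; inputs piecewise constant per
output sample; states recorded at 10 Hz), compiled with numba. Rest is an
exact fixed point; step-halving changes outputs by < 1e-4 relative.
Instabilities (|z| > 1e3 or non-positive balloon states) flag the run.

## Inversion

Variational Laplace: a Gaussian posterior over the free parameters is
optimized by Gauss-Newton ascent on F = accuracy - complexity,
complexity = KL(posterior || prior). Jacobians are finite differences
(relative step 1e-4), central by default; the recovery harness uses
forward differences, which halves the model evaluations per iteration at
negligible cost in step quality for these smooth models. A Levenberg
schedule accepts a step only if F increases (so the accepted-step trace is
non-decreasing by construction) and raises damping otherwise; convergence
is declared at dF < 0.01 nats or 64 iterations; runs start at the prior
mean (deterministic — no random initialization). Observation noise is
Gaussian with one log-precision per output row (channel-wavelength for
fNIRS, region for BOLD) under a weak N(4, 1) hyperprior; per-row precision
lets a motion-damaged channel be down-weighted instead of polluting a
shared estimate. The accuracy term includes the (small) hyperprior
penalty, so F = accuracy - complexity recomposes exactly. On a conjugate
linear-Gaussian problem with fixed noise the scheme reproduces the
closed-form posterior to 1e-6 and the exact log evidence to 1e-3 nats (the
bound is tight for linear models).

Priors (established DCM-style defaults; the study prints none): A
off-diagonals N(0, n/64); self-connections parameterized as log-scalings
of a -0.5 1/s decay with N(0, 1/256); B and C N(0, 1); haemodynamic
transit/stiffness log-scalings N(0, 1/64) per region; log k N(0, 1/16).
Structural zeros are excluded from the parameter vector entirely.

Two design choices make the trial-averaged fit statistically honest:

- **Session-consistent forward model.** The generative prediction
  integrates the *full session* design and applies the *identical*
  epoch-averaging and baselining operator as the data (the kernel
  accumulates epoch averages in place, so memory and cost stay modest).
  An earlier design that integrated isolated epochs under averaged inputs
  left a 1–2% carryover mismatch — negligible for plotting, but large
  against the ~1% noise floor of a 12-trial average, and it biased the
  driving-input estimates.
- **Spectral prewhitening.** Physiological oscillations survive trial
  averaging as band-limited correlated residues that a white-noise
  likelihood treats as informative signal, shrinking the posterior
  intervals unrealistically. Before inversion, data and predictions are
  both multiplied (zero-phase, per channel and condition) by
  1/sqrt(noise spectrum), the spectrum being the epoch-residual estimate
  above smoothed over 5 frequency bins and floored at 10% of its median.
  This is generalized least squares against the measured noise
  covariance; because the weighting is data-derived it is shared by all
  models compared on the same recording, leaving model comparison fair.
  (A projection alternative — removing a low-order cosine subspace — was
  rejected: it also removes the smooth between-condition response
  differences that carry the modulatory-effect evidence.)

Data and predictions are jointly rescaled to unit data SD per recording so
noise log-precisions land in their hyperprior's range; the common scale
cancels in model comparison.

## Model space, selection, averaging, agreement

All 13 models share: inputs V and NV driving STS; bidirectional intrinsic
connections STS–TPJ and STS–IFG plus three self-connections; modulation
only on inter-regional connections. The enumeration is model 1 without
modulation, models 2–5 with V on [STS→TPJ, TPJ→STS, STS→IFG, IFG→STS],
models 6–9 with NV on the same ordered connections (model 8 = NV on
STS→IFG), and models 10–13 with both. The published constraints fix the
shared structure, the count, the census (91 intrinsic parameters, 26
inputs, 8 + 8 modulations) and model 8's identity; the remaining ordering
is this package's documented choice.

Model selection is fixed-effects (single subject): p(m) proportional to
exp(F_m), ties to the lowest index. Bayesian model averaging forms
Gaussian-mixture moments over all 13 models, with parameters absent from a
model entering as point mass at zero. Cross-method agreement uses Pearson
correlation of the 13 log evidences, robust regression (IRLS with Tukey
bisquare, c = 4.685, MAD scale — statsmodels' RLM — with F and R^2 on the
weighted fit), and a seeded case-resampling bootstrap (percentile CI on
the slope; degenerate resamples redrawn and counted).

## Synthetic data and the recovery harness

The generator emulates the study recording: a seeded block design of
12 + 12 trials (9 s blocks, rest 13 s plus up to 4 s uniform jitter,
session 690 s at 10 Hz; the block order and jitter form a fixed protocol
under `design_seed`, so the clean series depends only on the truth, not on
the noise seed). The ground truth is the model-8 structure with
inter-regional couplings 0.2–0.4 Hz, self-decay -0.5 1/s,
C(V→STS) = C(NV→STS) = 0.3, B(NV, STS→IFG) = 0.4 — stable and
identifiable; the study prints no values. The observation model is built
end to end: slab mesh, FEM sensitivity, 4 mm regions at distinct locations
under the probe, normalized so the true k = 1.

Noise, per channel: white Gaussian with SD set by SNR = 5 (clean-signal SD
on the best channel divided by white SD); Mayer-band (0.1 Hz +-10%) and
cardiac-band (1.2 Hz +-10%) sinusoids at twice the white SD with random
phases; motion spikes as exponential-decay steps (1 s decay) at Poisson
times (0.5/min), 5–15 uM haemoglobin-equivalent, coherent across the two
wavelengths of a channel. The BOLD twin gets white noise at the same SNR.
Clean series and each noise realization are stored separately (their sum
is the recording, exactly).

The harness (per seeded run): simulate; detect artifacts on MBLL oxy-Hb
(3 uM / 1 s rule, segments dilated 3 s forward / 0.5 s back) and
spline-correct the OD channels; trial-average; invert all 13 models per
modality; BMS, BMA, coverage of the true nonzero A/B/C values by 90%
credible intervals, and cross-modality agreement statistics. The
Butterworth bank is deliberately *not* applied in this path: the
generative prediction is unfiltered, the Mayer notch overlaps the
evoked-response band, and averaging 12 jittered trials plus prewhitening
handles the physiological noise; filtering remains the right tool for the
GLM/activation stage and is validated separately. Run problem sizes — 20
runs, 13 models per modality, one modality fully and a subset of runs with
the BOLD twin as well — keep the full validation at desk scale on one CPU.

### What passing the harness shows — and what it does not

Passing shows the estimator is *internally* calibrated and selective: when
data truly come from a bilinear DCM observed through the stated optics
with stationary additive noise, the pipeline recovers the generating
parameters with honest uncertainty and identifies the generating model.
It does not show robustness to real-data deviations the generator omits:
head curvature and segmentation error in the sensitivity matrix,
non-stationary or non-sinusoidal physiology, serial correlation of white
noise, habituation/attention effects on the neural parameters, wrong
balloon constants, or model classes outside the 13 considered.
Cross-method agreement measured on a real simultaneous fMRI-fNIRS
recording depends on that recording; here the harness computes the same
statistics (log-evidence correlation, class-wise robust regressions of
the per-model coupling estimates) on synthetic twins, where the two
modalities share the neural truth by construction, so the agreement is an
upper bound on what real data can show.

## Known limitations

- Slab geometry only; no curved-head or template meshes.
- CW diffusion approximation; the low-scattering CSF layer is handled by
  the diffusion equation, not radiative transfer.
- Fixed-effects, single-subject inference; no hierarchical/group BMS, no
  Bayesian model reduction, no stochastic DCM.
- Finite-difference Jacobians; adequate at this parameter count (16–18),
  quadratic in it.
- The artifact threshold ("3 uM") is applied on the oxy-Hb series; the
  exact spline variant of the cited correction method has unpublished
  tunables, and this implementation's smoothing choice is documented in
  the code.
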
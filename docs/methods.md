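# Methods

This note documents the statistical machinery, the numerical conventions,
and the design choices made where more than one defensible option existed.

## Wavelet transform

The transform is a continuous complex Morlet analysis parameterized
directly by timescale σ (months):

    W(t, σ) = (dt/σ) Σ_u x(u) · conj(ψ((u − t)/σ)),
    ψ(η) = π^(−1/4) exp(2πiη) exp(−η²/2).

Two conventions matter downstream and are fixed here:

- **Timescale = period.** The kernel's central frequency is 1 in η, so for
  x(t) = cos(2πt/P) the time-averaged response magnitude peaks at σ = P,
  and band limits quoted in months are directly interpretable as periods.
  The 1/σ prefactor (rather than 1/√σ) makes the frequency response of a
  fixed-amplitude sinusoid flat across σ, so the peak is not biased upward.
- **Phase sign.** Using conj(ψ), the phase at σ = P advances by +2π per P
  months; a response that lags its driver therefore has a negative
  cross-spectral phase, matching the reporting convention below.

Edges: the kernel is truncated at |η| = 4 and applied by linear (not
circular) convolution, so no periodicity is imposed on the data. A validity
mask flags coefficients within `coi_factor · σ` of either end of the
record; `coi_factor` defaults to 1.0 — a deliberately lenient cone, since
the analyses aggregate over sites and times and the longest band (16–60
months) must retain some valid points on an 11-year record. All band
statistics use only valid points. Timescales whose validity column is
empty are excluded from band statistics entirely (and their normalization
falls back to all-times power so it stays well defined).

The default timescale grid is log-uniform with ratio 1.05 from 2 months
(the Nyquist limit of monthly data) to min(72, T) months, which covers the
2–8, 8–16 and 16–60 month analysis bands with smooth resolution.

## Cleaning

Per site, in fixed order: optional Box–Cox (off by default; series are
shifted minimally positive if needed), ordinary least-squares linear
detrend, then scaling to zero mean and unit sample variance. Missing values
are a hard error naming the site and month; linear interpolation exists as
a separate, explicit call so gaps are never filled silently. Constant or
exactly-linear series raise a zero-variance error rather than producing
0/0 fields.

## Mean fields and the random-phasor null

With across-locations normalization (each timescale's coefficients divided
by the square root of the across-site mean power at that timescale, so
mean |w̃|² = 1), the wavelet mean field is the plain across-site average;
|WMF|² is the synchrony measure, and both |WMF| and |WMF|² are exported
since either may be plotted. The wavelet phasor mean field uses unit
phasors only, making it invariant to any per-site positive rescaling.

The WPMF null is the magnitude of the mean of N independent uniform-phase
unit phasors. Its distribution is the same at every (time, timescale) cell,
so a single global threshold per α is used — the (1−α) empirical quantile
over `n_rand = 1000` seeded draws (asymptotically threshold² ≈ −ln α / N).
Significance contours are pointwise; no field-wise multiplicity correction
is applied, and the pipeline instead reports a tests-versus-rejections
summary so readers can judge the weight of evidence.

## Spatial coherence and surrogate testing

Coherence at timescale σ is ⟨conj(w̃x) · w̃y⟩ over sites and valid times,
with both variables across-locations normalized (magnitude ≤ 1 by
Cauchy–Schwarz). Band aggregation is the unweighted mean over the
log-spaced grid timescales inside [lo, hi] — on a log-uniform grid this is
an average over log-timescale, the natural scale for octave-like bands.
Phase φ = arg/π ∈ (−1, 1]; values numerically at −π are mapped to +1 (the
anti-phase representative).

The null hypothesis is "no cross-variable relation, with each variable's
own spectral and cross-site structure intact". The driver is surrogated
(the response held fixed): per site, discrete-Fourier phases are
randomized conjugate-symmetrically with the *same* phase sequence across
sites, preserving each site's periodogram exactly and the driver's own
synchrony. The amplitude-adjusted variant (AAFT) additionally preserves
each site's marginal value distribution via rank remapping and is offered
for skewed variables. Which side is surrogated is exposed by argument
order; p-values use the add-one rule p = (1 + #{|coh*| ≥ |coh|})/(n_surr+1)
so p is never 0.

Two evaluation routes compute the surrogate distribution. The slow
reference constructs every surrogate series and re-transforms it in the
time domain. The fast route exploits linearity: a Fourier surrogate is a
linear combination of complex-exponential basis series, so after
transforming the T basis series once, every surrogate band coherence is a
single inner product with the random phase vector. In both routes the
statistic keeps the normalization constants of the observed driver —
Fourier surrogates preserve the periodogram, so these constants are
surrogate-invariant up to edge-truncation effects — which makes the fast
route an exact reformulation of the slow one (they agree to ~1e-15 on
shared draws) rather than an approximation. Re-normalizing each surrogate
individually is available as a slow-route option; it perturbs p-values
slightly (edge-truncated power fluctuates per surrogate) without changing
calibration, which is verified empirically: the test's measured type-I
error at α = 0.05 over 200 independent AR(1) datasets is inside the 95%
binomial interval.

## Wavelet linear models and synchrony attribution

At each band timescale the response coefficients are regressed on the
predictor coefficients by complex least squares, pooled over sites and
valid times, with no intercept (the fields are zero-mean by construction).
Coefficients vary freely across the band — phase and gain need not be
constant over a multi-octave span — and band quantities aggregate
afterwards; a constant-per-band fit is available as an option. Collinear
nonzero predictors (condition number of the unit-scaled design > 1e8)
raise an error naming the timescale; zero-power predictors get a zero
coefficient via the pseudoinverse, so padding a model with an inert
predictor changes nothing.

Writing M_j for the mean field of β_j w̃x_j, model synchrony decomposes
exactly as S_mod = Σ_j ⟨|M_j|²⟩ + Σ_{j<k} ⟨2 Re(M_j conj M_k)⟩: nonnegative
per-driver contributions plus signed interaction terms (positive =
synergistic, negative = antagonistic). The fraction explained is
S_mod/S_obs with S_obs the band-time mean of |WMF_y|²; overfit values above
1 are reported raw with a warning rather than clipped.

Two band-phase estimators are computed per predictor. The default
("crossprod") is the cross-spectral phase arg⟨conj(w̃x_j) · w̃y⟩ over the
band — the directly interpretable response-versus-driver offset. The
"coefficient" variant is the predictor-power-weighted argument of β_j(σ),
the phase of the predictor's fitted component, which remains meaningful in
multi-predictor models where correlated predictors contaminate the raw
cross product. Both agree on constructed single-driver lags (a 1-month lag
at the 12-month timescale gives φ = −2/12 = −1/6) and both are exported.

Model diagnostics report a per-timescale R² analog
(1 − Σ|resid|²/Σ|w̃y|²), the fraction of band cells where the residual
phasor mean field exceeds the random-phasor threshold (≈ α under a
well-specified model), and — when predictor series are supplied — surrogate
coherence tests of each predictor against the residual field.

## The cascade pipeline

Raw tables are aggregated as in the field protocols: wrack cover is the
across-transect mean per site-month, shorebird abundance the total over
the configured shorebird species list (unknown species are excluded with a
warning, never silently), wave intensity the monthly mean of daily maximum
significant wave heights. Waves are then first-differenced — wrack
production responds to *changes* in wave energy, since waves that have
already stripped kelp leave less to remove — and Δwaves(t) is indexed at
the later month, so positive values mean wave action increasing into the
current month. Because differencing shortens the wave series by one month,
every variable is trimmed to months 2..T before cleaning, keeping one
common index.

Driver screening runs the surrogate coherence test per (driver, band);
drivers with p < 0.1 enter the band's model, and when both the local and
regional kelp series pass, only the one with the smaller p is kept (on an
exact tie the regional scale is kept, deterministically). Rejections at
0.05 are tallied into the report's multiple-testing summary. Shorebird
models use wrack and air temperature (the temperature term absorbs the
migration-driven seasonal cycle in bird abundance) in all three bands,
with a caution flag on bands where the wrack–bird coherence itself is not
significant, rather than refusing to fit there.

Phase labels follow fixed thresholds: in-phase is the open interval
−0.25 < φ < 0.25, anti-phase φ < −0.75 or φ > 0.75, otherwise negative φ
means the response lags the driver and positive φ that it leads. Boundary
values (|φ| exactly 0.25 or 0.75) fall to the lag/lead categories, reading
the in-/anti-phase definitions as strict inequalities.

All stage seeds derive from one master seed via `SeedSequence` spawning, so
a report is reproducible byte-for-byte; the JSON report stores every scalar
at full float precision together with the configuration that produced it.

## Synthetic data

The generator emulates the structure the analysis assumes, not any
particular dataset. Each driver is seasonal_amp·cos(2πt/12 + phase) (phase
site-invariant by default — regionally coherent seasonality — with an
optional per-site jitter) plus √ρ·common AR(1) + √(1−ρ)·independent AR(1)
with unit-variance innovations, so the across-site correlation of the
nonseasonal part is exactly ρ. Defaults are 5 sites, 132 months, ρ = 0.8,
AR coefficient 0.7 (the simplest process with power at 16–60 months),
gains a = 1.0 (regional kelp→wrack, lag 1 month), b = 0.8 (Δwaves→wrack),
c = 0.6 (width→wrack), d = 1.5 (wrack→birds, lag 1 month), e = 0.5
(temperature→birds), and noise SD 0.5 on wrack and birds. The local kelp
analog is μ·regional + √(1−μ²)·independent with μ = 0.5, so it correlates
with wrack only through its shared component — the screening stage should
(and does) prefer the regional analog. Nonnegative variables are shifted up
by three standard deviations and truncated at zero with the truncation
rate logged (≪ 1% at default noise), leaving the linear ground truth
essentially intact. The generator records gains, lags and the implied band
phases (a lag of ℓ months at the 12-month timescale is φ = −2ℓ/12).

What the generator does *not* emulate: observational error structure,
heavy-tailed or zero-inflated marginals (beyond optional AAFT testing),
spatial transport/advection, distance-dependent coupling, and monitoring
gaps. Passing tests therefore demonstrate correctness of the statistical
machinery under the stated model, not robustness to every feature of field
data.

## Problem sizes and tolerances

The test suite and the acceptance script use scaled-down Monte Carlo sizes
chosen as the package's defaults for routine verification: 500 surrogates
for calibration runs and 200 for paired route comparisons (analyses of
real data should use the 10,000-surrogate default), 100–200 replicates for
null calibrations, 20 seeds for phase recovery, and T = 528 months for
coefficient recovery. Exact algebraic identities are asserted at 1e-8 or
tighter; transform-versus-oracle agreement at 1e-8; Monte Carlo quantities
at tolerances derived from their sampling error (binomial intervals,
order-statistic error of the quantile estimator).

## Known limitations

- Coherence p-values assume the driver and response spectra arise
  independently under the null; under a true driver–response link the test
  is conservative.
- Pointwise WPMF contours carry no field-wise error control.
- `sync_explained` can exceed 1 for overfit models (many predictors, short
  records); it is reported raw.
- The fast surrogate route applies to plain Fourier surrogates only; AAFT
  requires the slow route.
- Single-site wavelet power significance, unevenly sampled records, and
  distance-resolved ("geography of synchrony") statistics are out of scope.
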
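# Methods

This note documents the models, numerical choices and known limitations of
`nirscoupling`. Everything quantitative stated here is computed by the test
suite or `scripts/acceptance.py`; nothing is quoted from external data.

## Signal model of the synthetic generator

Real resting-state bNIRS recordings of the rodent cortex are not publicly
deposited, so the pipeline is exercised on a parametric stand-in. Each
band-limited oscillation is a sum of `n_components = 32` sinusoids with
frequencies drawn uniformly in the analysis band (default 0.02–0.06 Hz),
uniform phases and Rayleigh-distributed amplitudes — a narrowband,
approximately Gaussian process whose periodogram concentrates ≥ 95 % of its
power in the band. A recording mixes a *shared* oscillation S(t) with
trace-private oscillations U(t):

    hbo2  ∝ ρ·S(t)             + (1−ρ)·U_h(t)
    hhb   ∝ ρ·(−S(t))          + (1−ρ)·U_hb(t)     (anti-phase convention)
    oxcco ∝ ρ·S(t + lag)       + (1−ρ)·U_c(t)

each mixture renormalised to its target RMS, plus white noise. The coupling
fraction ρ ∈ [0,1] is the generator's ground truth: band coherence is
monotone in ρ (verified by Monte-Carlo), ρ = 1 gives perfectly coupled
traces, ρ = 0 independent oscillators. The phase lag is applied as a
frequency-independent phase offset of the shared sinusoids, so band
semblance approximates cos(lag) by construction.

Default amplitudes follow bNIRS convention: haemoglobin oscillation RMS
1 µM, oxCCO 0.1 µM. Because oxCCO is an order of magnitude smaller, the
additive noise SD (`noise_sd`, in µM for the haemoglobin traces) is scaled
by `oxcco_amplitude/amplitude` for the oxCCO trace so all traces share one
SNR; an absolute noise floor would otherwise drown the metabolic signal and
make every coupling metric degenerate in noise rather than in ρ.

`hhb_gain` sets the HHb oscillation RMS relative to HbO₂. Its default 1.0
makes HHb an exact mirror of HbO₂ (hbo2 + hhb ≡ 0 for ρ = 1 without noise),
which is the cleanest construction for testing the anti-phase contract — but
it makes HbT pure noise. Cohort simulations therefore use `hhb_gain = 0.6`:
with a smaller HHb oscillation, HbT = HbO₂ + HHb retains a coupled residual
(coefficient ∝ ρ(1 − 0.6)), reproducing the empirically typical pattern in
which oxCCO–HbT coherence and semblance are positive but weaker than the
other pairs. This is a deliberate modelling choice, not a fitted value.

**What the generator does not emulate:** cardiac and respiratory bands,
1/f background, motion artefacts, vasomotion waveform asymmetry,
non-stationary coupling episodes, or any haemodynamic biophysics
(no balloon/Windkessel model). Passing tests demonstrate that the analysis
recovers known coupling structure from band-limited signals; they do not
validate the physiological interpretation of real recordings.

### Study conditions for the three-cohort simulation

Fixed once, before any acceptance measurement: young ρ = 0.9 (n = 18),
placebo ρ = 0.55 (n = 17), nimodipine ρ = 0.8 (n = 24); per-recording ρ
jitter SD 0.05 (truncated to [0,1]) to create between-animal variance;
noise_sd 0.3 µM; phase lag 0.3 rad; hhb_gain 0.6; fs 0.5 Hz; 1800 s.

## Spectral resolution

The modified Beer–Lambert model ΔA(λ,t) = Σᵢ εᵢ(λ)·Δcᵢ(t)·d·DPF(λ) is
solved for the three chromophore concentration changes by ordinary least
squares per time point over the full wavelength grid, with the
wavelength-dependent DPF folded into the design matrix. Wavelength grids
must match exactly (`regrid_extinction` interpolates, never silently).
Rank of the design is validated at model construction; collinear columns
are named in the error. Residual spectra are retained for QC.

The packaged extinction table is **synthetic**: smooth analytic curves with
the qualitative shapes of published NIR spectra (HbO₂ rising over
780–900 nm, HHb falling, an oxidised-minus-reduced CCO band near 830 nm),
full rank with condition number ≈ 8.5. It supports simulation and
forward/inverse round-trip testing; quantifying real spectra requires a
measured ε table supplied via `load_extinction_table`. DPF defaults to a
wavelength-flat 4.0; since only relative concentration changes are resolved
and the downstream coupling metrics are amplitude-invariant, DPF
mis-specification rescales traces without biasing coherence or semblance.
Baselines are the caller's responsibility (ΔA inputs are already changes);
the generator produces zero-mean oscillations.

## Preprocessing

Wavelet denoising: symlet-8 discrete wavelet decomposition, soft universal
threshold σ·√(2 ln n) with σ estimated as MAD/0.6745 of the finest detail
level. The decomposition depth follows a band-protection rule — the deepest
level whose coarsest detail band still lies above `band_high`
(level 2 at fs = 0.5 Hz and 0.06 Hz, details covering 0.0625–0.25 Hz) — so
the slow-wave band is carried entirely by the approximation coefficients and
is not attenuated. Measured on noise-free 0.04 Hz oscillations the denoiser
changes RMS by < 2 % and band power by < 5 %, and it is idempotent to < 1 %.
Composites HbDiff/HbT are derived *after* denoising; a recompute-and-check
invariant guards the identities at every pipeline stage. Optional linear
detrend is off by default and logged when applied.

## Wavelet coherence and semblance

- **Transform:** analytic complex Morlet, ω₀ = 6 (frequency ≈ 1/scale;
  exact Fourier factor 4π/(ω₀+√(2+ω₀²))), computed in the Fourier domain,
  12 voices per octave, frequencies log-spaced from fs/2 down to half the
  band's lower edge. The series is demeaned and symmetrically zero-padded to
  the next power of two; padding is recorded in metadata.
- **Cone of influence:** Morlet e-folding time √2·s. `coi[t]` stores the
  lowest reliable frequency at time t; band averages exclude out-of-cone
  cells by default (a 30-min record keeps a wide in-cone interior at
  0.02 Hz). The `include` policy is available for sensitivity analysis.
- **Smoothing:** time — Gaussian with SD equal to the scale (in seconds,
  configurable as a multiple of scale), matched to the Morlet e-folding
  envelope; scale — 0.6-octave boxcar. With both widths set to 0 the
  coherence estimator degenerates to exactly 1 for any pair
  (|ab*|² = |a|²|b|²); this limit is kept reachable and is asserted in tests
  to prove the default smoothing is active.
- **Coherence:** smoothed cross-spectrum normalised by smoothed
  auto-spectra, each pre-weighted by 1/scale; clipped to [0,1]. At cells
  whose auto-power is at rounding-noise level (a narrowband signal far from
  its tone) the ratio is numerically undefined and is reported as 0; such
  cells never occur inside the band for in-band signals.
- **Semblance:** cos of the *unsmoothed* cross-wavelet phase. Plain cosine
  (exponent 1) is used for the headline metric; the smoothed-phase channel
  is available on coherence maps. Semblance is symmetric in its arguments
  (cosine is even) and exactly ±1 for identical/sign-flipped signals.
- **Band average:** unweighted arithmetic mean over all in-band, in-cone
  (frequency, time) cells, jointly over both axes. Uniform weighting over
  log-spaced frequencies mildly emphasises the low-frequency end in linear-Hz
  terms; this joint-cell mean is the documented convention.
- Measured properties (test suite): semblance of 0.04 Hz sinusoid pairs
  matches cos(Δφ) within 0.01 at lags {0, π/4, π/2, 3π/4, π}; independent
  white-noise pairs (n = 900) give band coherence < 0.5 in > 95 % of seeded
  runs (mean ≈ 0.34); band coherence is monotone in ρ.

## Group statistics

Mean ± sample SD (n−1) per group, pair and metric; independent two-sample
t-tests per pair and metric for young-vs-placebo and placebo-vs-nimodipine.
Welch's correction is the default (robust to the unequal cohort sizes and
variances); the pooled-variance test is available for strict comparability
with analyses that used it. Two-sided p-values; no multiplicity correction
by default across the 16 tests, optional Holm adjustment behind a flag.
One recording is one analysis unit. The rendered report formats mean ± SD to
two decimals and prints p < 0.001 as "<0.001".

## Pipeline and reproducibility

Every generator is a pure function of its scenario (including the seed);
cohort recordings use consecutive seeds from a base seed, with jitter drawn
from a separately keyed RNG so that enabling jitter does not change the
underlying oscillations. `run_study` derives per-group base seeds from the
global seed, writes every artefact with the configuration hash, and refuses
to merge result tables computed under different configurations. Re-running
a study with the same configuration reproduces all outputs bit-for-bit.

Problem sizes in tests and the acceptance script — 200 null runs, 50 seeds
per ρ level, 200 covariance replicates, 3 cohort replicates — were chosen to
keep Monte-Carlo standard errors well below the tested margins while the
whole suite completes in a few minutes on one core. The ρ-recovery check
reuses one seed list across ρ levels (common random numbers), pairing the
draws so level differences are not swamped by between-seed variance.

## Known limitations

- No statistical significance testing of coherence against surrogate data;
  group contrasts operate on band means only.
- No fourth spectral component (e.g. a scattering slope) in the
  Beer–Lambert fit; analyses comparing against systems that fit one may see
  small oxCCO cross-talk differences.
- The denoising automation (band-protection depth rule) is this package's
  own criterion; other "automated" denoisers may choose levels per
  recording.
- Semblance weights all cells equally regardless of spectral power; the
  amplitude-weighted ("dot-product") variant is not the headline metric.
- The cli_io configuration rejects any analysis band reaching the Nyquist
  frequency (band_high < fs/2), which at 0.5 Hz sampling caps usable bands
  at 0.25 Hz.
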
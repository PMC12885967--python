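# nirscoupling

Resting-state **metabolic–haemodynamic coupling** analysis for broadband
near-infrared spectroscopy (bNIRS).

Cerebral small vessel disease degrades the mechanisms that match blood
delivery to neuronal metabolic demand. bNIRS can observe both sides of that
balance non-invasively: the 780–900 nm attenuation spectrum resolves not only
oxy- and deoxy-haemoglobin (HbO₂, HHb) but also the oxidation state of
cytochrome-c-oxidase (oxCCO), a direct marker of mitochondrial oxidative
metabolism. In the resting state all of these signals carry spontaneous
slow-wave oscillations; in the 0.02–0.06 Hz band (attributed to neurogenic
origin) the degree to which the metabolic oscillation (oxCCO) tracks the
haemodynamic ones (HbO₂, HHb, HbT = HbO₂+HHb, HbDiff = HbO₂−HHb) quantifies
how well supply follows demand.

This package implements that analysis end to end, for researchers working
with bNIRS recordings or evaluating the method on simulated data:

- **`synthetic`** — seeded generator of coupled slow-wave chromophore traces
  (30 min at 0.5 Hz by default) with controllable coupling fraction ρ, phase
  lag, anti-phase HHb, and between-animal jitter; plus the Beer–Lambert
  forward model to broadband attenuation spectra.
- **`spectral`** — modified Beer–Lambert inversion
  `ΔA(λ,t) = Σᵢ εᵢ(λ)·Δcᵢ(t)·d·DPF(λ)` solved per time point by ordinary
  least squares over the full 780–900 nm grid.
- **`preprocess`** — automated wavelet denoising (soft universal threshold,
  level chosen to protect the analysis band) and the composite signals
  HbDiff and HbT.
- **`coupling`** — complex Morlet (ω₀ = 6) continuous wavelet transform;
  **wavelet coherence** `R²(s,t) = |S(s⁻¹WₓW*ᵧ)|² / (S(s⁻¹|Wₓ|²)·S(s⁻¹|Wᵧ|²))`
  with scale-dependent time smoothing and octave-band scale smoothing;
  **wavelet semblance** `cos(arg(WₓW*ᵧ))`; cone-of-influence handling and
  band averaging over 0.02–0.06 Hz.
- **`groupstats`** — per-group mean ± SD and independent two-sample t-tests
  (Welch by default) across young / placebo / nimodipine cohorts.

## Worked example

```python
from nirscoupling import (CouplingScenario, generate_chromophore_series,
                          make_signal_set, couple_recording)

scenario = CouplingScenario(coupling=0.9, noise_sd=0.3, hhb_gain=0.6,
                            phase_lag=0.3, seed=3)
rec = generate_chromophore_series(scenario)   # 900 samples at 0.5 Hz
sset = make_signal_set(rec)                   # denoise + HbDiff/HbT
for pair, s in couple_recording(sset).items():
    print(f"{pair}: coherence {s.band_coherence:.3f}, "
          f"semblance {s.band_semblance:+.3f}")
```

prints

```
oxCCO-HbO2: coherence 0.954, semblance +0.894
oxCCO-HHb: coherence 0.953, semblance -0.904
oxCCO-HbT: coherence 0.827, semblance +0.767
oxCCO-HbDiff: coherence 0.964, semblance +0.909
```

With 90 % of the oscillation shared (ρ = 0.9), band coherence is high for
every pair; semblance is positive for oxCCO vs HbO₂/HbT/HbDiff (in-phase
supply and demand) and negative for oxCCO vs HHb, which oscillates in
anti-phase with HbO₂. Lower ρ lowers all coherences and pulls semblance
toward 0.

The same pipeline runs from the shell:

```bash
nirscoupling simulate --coupling 0.9 --noise-sd 0.3 --seed 3 --out rec.csv
nirscoupling preprocess --input rec.csv --out pre.csv
nirscoupling couple --input pre.csv --out coupling.csv
nirscoupling run-study --seed 1 --out study/   # full three-cohort study
```

`run-study` simulates three cohorts (young n=18 with intact coupling,
placebo n=17 with impaired coupling, nimodipine n=24 with largely protected
coupling), analyses every recording and writes the tidy results table, the
group summary, both contrasts and a formatted report.

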
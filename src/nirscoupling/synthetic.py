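"""Seeded synthetic stand-ins for resting-state bNIRS recordings.

The generator emulates 30-minute, 0.5 Hz recordings of three chromophore
concentration-change traces (HbO2, HHb, oxCCO) whose slow-wave oscillations in
a configurable band (default 0.02-0.06 Hz) are coupled with controllable
strength and phase lag.  The signal model is a shared/independent mixture of
band-limited sums of sinusoids:

    x(t) = rho * S(t) + (1 - rho) * U_x(t)      (then RMS-normalised)

where S is an oscillation shared by all traces (the metabolic copy phase
shifted by ``phase_lag``), U_x is an oscillation private to each trace, and
rho is the coupling fraction.  HHb mirrors the shared haemodynamic component
in anti-phase, so oxCCO-HHb semblance is negative by construction.  True band
coherence is monotone in rho, which is what makes the generator a usable
ground truth for the coupling metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import numpy as np

from .errors import ConfigurationError
from .spectral import AttenuationSeries, ExtinctionModel

__all__ = [
    "CouplingScenario",
    "ChromophoreSeries",
    "SyntheticCohort",
    "generate_coupled_pair",
    "generate_chromophore_series",
    "generate_cohort",
    "forward_attenuation",
    "GROUP_LABELS",
]

GROUP_LABELS = ("young", "placebo", "nimodipine")


@dataclass(frozen=True)
class CouplingScenario:
    """Parameters of one synthetic recording.

    Attributes
    ----------
    fs : float
        Sampling rate, Hz.
    duration : float
        Record length, s.
    band_low, band_high : float
        Slow-wave oscillation band edges, Hz.
    coupling : float
        Shared-oscillation fraction rho in [0, 1].
    phase_lag : float
        Phase of the metabolic (oxCCO) copy of the shared oscillation relative
        to the haemodynamic copy, radians.
    hhb_antiphase : bool
        If True, HHb carries the shared component with inverted sign.
    noise_sd : float
        Additive white-noise SD in uM on the haemoglobin traces; the oxCCO
        trace receives it scaled by ``oxcco_amplitude / amplitude`` so all
        traces share a common SNR.
    amplitude : float
        Oscillation RMS of the HbO2 trace, uM.
    oxcco_amplitude : float
        Oscillation RMS of the oxCCO trace, uM (bNIRS convention: ~10x smaller
        than the haemoglobin oscillations).
    hhb_gain : float
        HHb oscillation RMS relative to ``amplitude``.  1.0 makes HHb an exact
        mirror of HbO2 (so HbT is flat); values < 1 leave HbT with a coupled
        residual, as in real recordings.
    n_components : int
        Number of sinusoids summed per band-limited oscillation.
    seed : int
        RNG seed; generation is a pure function of the scenario.
    """

    fs: float = 0.5
    duration: float = 1800.0
    band_low: float = 0.02
    band_high: float = 0.06
    coupling: float = 1.0
    phase_lag: float = 0.0
    hhb_antiphase: bool = True
    noise_sd: float = 0.0
    amplitude: float = 1.0
    oxcco_amplitude: float = 0.1
    hhb_gain: float = 1.0
    n_components: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.fs > 0):
            raise ConfigurationError("fs: must be > 0")
        if not (0 < self.band_low < self.band_high < self.fs / 2):
            raise ConfigurationError(
                "band_low/band_high: need 0 < band_low < band_high < fs/2 "
                f"(got [{self.band_low}, {self.band_high}] at fs={self.fs})"
            )
        if not (0.0 <= self.coupling <= 1.0):
            raise ConfigurationError("coupling: must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd: must be >= 0")
        if self.amplitude <= 0 or self.oxcco_amplitude <= 0:
            raise ConfigurationError("amplitude/oxcco_amplitude: must be > 0")
        if self.hhb_gain <= 0:
            raise ConfigurationError("hhb_gain: must be > 0")
        if self.n_components < 1:
            raise ConfigurationError("n_components: must be >= 1")
        if self.n_samples < 64:
            raise ConfigurationError(
                f"duration: duration*fs = {self.n_samples} samples; need >= 64"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass
class ChromophoreSeries:
    """Time-aligned HbO2/HHb/oxCCO concentration-change traces (uM)."""

    t: np.ndarray
    hbo2: np.ndarray
    hhb: np.ndarray
    oxcco: np.ndarray
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("hbo2", "hhb", "oxcco"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.t.shape:
                raise ConfigurationError(f"{name}: length differs from time vector")
            if not np.all(np.isfinite(arr)):
                raise ConfigurationError(f"{name}: non-finite values")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if not np.allclose(dt, 1.0 / self.fs, rtol=1e-9, atol=1e-9):
                raise ConfigurationError("t: not uniformly spaced at 1/fs")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class SyntheticCohort:
    """A group of synthetic recordings sharing acquisition parameters."""

    recordings: list
    group_label: str
    n: int

    def __post_init__(self) -> None:
        if self.group_label not in GROUP_LABELS:
            raise ConfigurationError(
                f"group_label: {self.group_label!r} not in {GROUP_LABELS}"
            )
        if self.n < 2 or len(self.recordings) != self.n:
            raise ConfigurationError("n: cohort needs n >= 2 recordings")
        fs0 = self.recordings[0].fs
        n0 = self.recordings[0].n_samples
        for rec in self.recordings:
            if rec.fs != fs0 or rec.n_samples != n0:
                raise ConfigurationError("recordings: must share fs and duration")


class _SinusoidBank:
    """A band-limited oscillation: sum of sinusoids with random frequencies,
    phases and Rayleigh amplitudes, evaluated with an optional phase offset."""

    def __init__(self, rng: np.random.Generator, scenario: CouplingScenario):
        k = scenario.n_components
        self.freqs = rng.uniform(scenario.band_low, scenario.band_high, k)
        self.phases = rng.uniform(0.0, 2.0 * np.pi, k)
        self.amps = rng.rayleigh(1.0, k)

    def __call__(self, t: np.ndarray, phase_offset: float = 0.0) -> np.ndarray:
        arg = 2.0 * np.pi * self.freqs[:, None] * t[None, :]
        arg += (self.phases + phase_offset)[:, None]
        return (self.amps[:, None] * np.sin(arg)).sum(axis=0)


def _unit_rms(x: np.ndarray) -> np.ndarray:
    rms = np.sqrt(np.mean(x**2))
    if rms == 0.0:
        return x
    return x / rms


def _mix(rho: float, shared: np.ndarray, private: np.ndarray) -> np.ndarray:
    """rho-weighted mixture of unit-RMS shared and private oscillations,
    renormalised to unit RMS."""
    return _unit_rms(rho * _unit_rms(shared) + (1.0 - rho) * _unit_rms(private))


def generate_coupled_pair(scenario: CouplingScenario):
    """Two coupled band-limited series (uM) from one scenario.

    The second series carries the shared oscillation phase shifted by
    ``scenario.phase_lag``.  Regenerating with the same scenario reproduces
    the pair bit-for-bit.
    """
    rng = np.random.default_rng(scenario.seed)
    t = scenario.time
    shared = _SinusoidBank(rng, scenario)
    u1 = _SinusoidBank(rng, scenario)
    u2 = _SinusoidBank(rng, scenario)
    rho = scenario.coupling
    x = scenario.amplitude * _mix(rho, shared(t), u1(t))
    y = scenario.amplitude * _mix(rho, shared(t, scenario.phase_lag), u2(t))
    if scenario.noise_sd > 0:
        x = x + rng.normal(0.0, scenario.noise_sd, t.size)
        y = y + rng.normal(0.0, scenario.noise_sd, t.size)
    return x, y


def generate_chromophore_series(scenario: CouplingScenario) -> ChromophoreSeries:
    """One synthetic recording of HbO2, HHb and oxCCO traces.

    oxCCO shares the coupled oscillation with HbO2 at the scenario's phase
    lag; with ``hhb_antiphase`` the HHb trace carries the shared component
    sign-inverted, so with rho = 1, lag = 0, no noise and hhb_gain = 1,
    hbo2 + hhb == 0 at every sample.
    """
    rng = np.random.default_rng(scenario.seed)
    t = scenario.time
    shared = _SinusoidBank(rng, scenario)
    u_h = _SinusoidBank(rng, scenario)
    u_hb = _SinusoidBank(rng, scenario)
    u_c = _SinusoidBank(rng, scenario)
    rho = scenario.coupling

    s_haemo = shared(t)
    comp_h = _mix(rho, s_haemo, u_h(t))
    hhb_sign = -1.0 if scenario.hhb_antiphase else 1.0
    comp_hb = _mix(rho, hhb_sign * s_haemo, u_hb(t))
    comp_c = _mix(rho, shared(t, scenario.phase_lag), u_c(t))

    a = scenario.amplitude
    hbo2 = a * comp_h
    hhb = scenario.hhb_gain * a * comp_hb
    oxcco = scenario.oxcco_amplitude * comp_c
    if scenario.noise_sd > 0:
        snr_scale = scenario.oxcco_amplitude / scenario.amplitude
        hbo2 = hbo2 + rng.normal(0.0, scenario.noise_sd, t.size)
        hhb = hhb + rng.normal(0.0, scenario.noise_sd * scenario.hhb_gain, t.size)
        oxcco = oxcco + rng.normal(0.0, scenario.noise_sd * snr_scale, t.size)

    return ChromophoreSeries(
        t=t, hbo2=hbo2, hhb=hhb, oxcco=oxcco, fs=scenario.fs,
        meta={"scenario": asdict(scenario), "source": "generate_chromophore_series"},
    )


def generate_cohort(
    scenario: CouplingScenario,
    n: int,
    group_label: str,
    base_seed: int,
    coupling_jitter_sd: float = 0.0,
    amplitude_jitter_sd: float = 0.0,
) -> SyntheticCohort:
    """n recordings with seeds base_seed..base_seed+n-1.

    Per-recording coupling and amplitude may be jittered (truncated Gaussian)
    to create between-animal variance for group statistics.
    """
    if n < 2:
        raise ConfigurationError("n: group statistics need n >= 2 recordings")
    recordings = []
    for i in range(n):
        seed_i = base_seed + i
        rho_i, amp_i = scenario.coupling, scenario.amplitude
        if coupling_jitter_sd > 0 or amplitude_jitter_sd > 0:
            jrng = np.random.default_rng([seed_i, 0x6A17])
            if coupling_jitter_sd > 0:
                rho_i = float(np.clip(rho_i + jrng.normal(0, coupling_jitter_sd), 0.0, 1.0))
            if amplitude_jitter_sd > 0:
                amp_i = float(max(scenario.amplitude * 0.1,
                                  amp_i + jrng.normal(0, amplitude_jitter_sd)))
        sc_i = replace(scenario, seed=seed_i, coupling=rho_i, amplitude=amp_i)
        rec = generate_chromophore_series(sc_i)
        rec.meta["animal_id"] = f"{group_label}_{i:02d}"
        rec.meta["group"] = group_label
        recordings.append(rec)
    return SyntheticCohort(recordings=recordings, group_label=group_label, n=n)


def forward_attenuation(
    series: ChromophoreSeries, model: Optional[ExtinctionModel] = None
) -> AttenuationSeries:
    """Forward modified Beer-Lambert model: dA(lambda, t) = X @ dC(t).

    X is the extinction design matrix (eps * dpf * distance); the result is an
    exact linear map of the three concentration traces, suitable for testing
    the inverse fit.  ``model`` defaults to the packaged synthetic table.
    """
    if model is None:
        from .spectral import load_default_extinction

        model = load_default_extinction()
    C = np.vstack([series.hbo2, series.hhb, series.oxcco])
    dA = model.design_matrix @ C
    return AttenuationSeries(wavelengths=model.wavelengths, t=series.t, dA=dA)
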
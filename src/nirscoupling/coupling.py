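"""Complex-Morlet wavelet coherence and semblance of slow-wave oscillations.

The analytic Morlet wavelet with central angular frequency omega0 (default 6)
maps scale to frequency via the Fourier factor

    f = (omega0 + sqrt(2 + omega0^2)) / (4 pi s)  ~  1/s  for omega0 = 6.

Coherence follows the standard smoothed-cross-spectrum estimator

    R^2(s, t) = |S(s^-1 Wx Wy*)|^2 / ( S(s^-1 |Wx|^2) S(s^-1 |Wy|^2) )

where S smooths in time with a Gaussian whose width scales with s (matched to
the Morlet e-folding time) and in scale with a boxcar spanning a fixed number
of octaves.  Without smoothing the estimator is identically 1 for any pair
(|ab*|^2 = |a|^2 |b|^2), so the smoothing windows are what give coherence its
statistical meaning; the degenerate no-smoothing limit is kept reachable for
testing.

Semblance is the cosine of the (unsmoothed) cross-wavelet phase,

    D(s, t) = cos( arg(Wx Wy*) ),

+1 for in-phase, -1 for anti-phase, ~0 for unrelated signals once averaged.

Headline metrics are the arithmetic means of coherence and semblance over all
(frequency, time) cells inside the analysis band (default 0.02-0.06 Hz) and
inside the cone of influence.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

from .errors import ConfigurationError, DegenerateSignalError, GridMismatchError
from .preprocess import SignalSet

__all__ = [
    "WaveletConfig",
    "WaveletField",
    "CouplingMap",
    "CouplingSummary",
    "cwt_morlet",
    "coherence_map",
    "semblance_map",
    "band_average",
    "couple_recording",
    "PAIR_ORDER",
]

PAIR_ORDER = ("oxCCO-HbO2", "oxCCO-HHb", "oxCCO-HbT", "oxCCO-HbDiff")
_PAIR_SIGNAL = {
    "oxCCO-HbO2": "hbo2",
    "oxCCO-HHb": "hhb",
    "oxCCO-HbT": "hbt",
    "oxCCO-HbDiff": "hbdiff",
}


@dataclass(frozen=True)
class WaveletConfig:
    """Transform and smoothing parameters.

    smoothing_time_scalefactor is the Gaussian time-smoothing SD in units of
    scale (1.0 ~ the Morlet e-folding time scale/sqrt(2) up to a constant);
    smoothing_scale_octaves is the boxcar width of the scale smoother.  Set
    both to 0 to disable smoothing (coherence then degenerates to 1).
    """

    omega0: float = 6.0
    voices_per_octave: int = 12
    smoothing_time_scalefactor: float = 1.0
    smoothing_scale_octaves: float = 0.6
    band_low: float = 0.02
    band_high: float = 0.06
    coi_policy: str = "exclude"
    fmin_factor: float = 0.5  # lowest analysis frequency = fmin_factor * band_low

    def __post_init__(self) -> None:
        if self.omega0 < 5:
            raise ConfigurationError("omega0: must be >= 5 (Morlet admissibility)")
        if self.voices_per_octave < 4:
            raise ConfigurationError("voices_per_octave: must be >= 4")
        if not (0 < self.band_low < self.band_high):
            raise ConfigurationError("band_low/band_high: need 0 < band_low < band_high")
        if self.smoothing_time_scalefactor < 0 or self.smoothing_scale_octaves < 0:
            raise ConfigurationError("smoothing widths must be >= 0")
        if self.coi_policy not in ("exclude", "include"):
            raise ConfigurationError("coi_policy: must be 'exclude' or 'include'")
        if not (0 < self.fmin_factor <= 1):
            raise ConfigurationError("fmin_factor: must lie in (0, 1]")

    @property
    def fourier_factor(self) -> float:
        """Scale-to-period conversion: period = fourier_factor * scale."""
        return 4.0 * math.pi / (self.omega0 + math.sqrt(2.0 + self.omega0**2))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class WaveletField:
    """Complex CWT coefficients over (frequency, time).

    ``freqs`` is strictly decreasing (small scale first).  ``coi`` holds, per
    time point, the lowest reliable frequency: a cell (f, t) lies inside the
    cone of influence iff f >= coi[t].
    """

    freqs: np.ndarray
    t: np.ndarray
    W: np.ndarray
    coi: np.ndarray
    scales: np.ndarray
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.W.shape != (self.freqs.size, self.t.size):
            raise ConfigurationError("W: shape inconsistent with freqs x t")
        if self.coi.shape != self.t.shape:
            raise ConfigurationError("coi: length differs from t")
        if np.any(np.diff(self.freqs) >= 0):
            raise ConfigurationError("freqs: must be strictly decreasing")
        if not np.all(np.isfinite(self.W)):
            raise ConfigurationError("W: non-finite coefficients")


@dataclass
class CouplingMap:
    """Coherence / semblance / phase over the (frequency, time) plane.

    The invariant semblance == cos(phase) holds elementwise for the phase
    channel stored here (the smoothed cross-spectrum phase for coherence
    maps, the raw cross-wavelet phase for semblance maps).
    """

    freqs: np.ndarray
    t: np.ndarray
    phase: np.ndarray
    semblance: np.ndarray
    coi: np.ndarray
    coherence: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.coherence is not None:
            if np.any(self.coherence < 0) or np.any(self.coherence > 1):
                raise ConfigurationError("coherence: values outside [0, 1]")
        if np.any(self.semblance < -1) or np.any(self.semblance > 1):
            raise ConfigurationError("semblance: values outside [-1, 1]")
        if not np.allclose(self.semblance, np.cos(self.phase), atol=1e-12):
            raise ConfigurationError("semblance != cos(phase)")


@dataclass
class CouplingSummary:
    """Band-averaged coherence and semblance for one signal pair."""

    pair: str
    band_coherence: float
    band_semblance: float
    n_cells: int
    config_hash: str = ""

    def __post_init__(self) -> None:
        if self.pair not in PAIR_ORDER:
            raise ConfigurationError(f"pair: {self.pair!r} not in {PAIR_ORDER}")
        if not (0.0 <= self.band_coherence <= 1.0):
            raise ConfigurationError("band_coherence: outside [0, 1]")
        if not (-1.0 <= self.band_semblance <= 1.0):
            raise ConfigurationError("band_semblance: outside [-1, 1]")
        if self.n_cells <= 0:
            raise ConfigurationError("n_cells: must be > 0")


def _next_pow2(n: int) -> int:
    return 1 << (n - 1).bit_length()


def cwt_morlet(x, fs: float, cfg: WaveletConfig | None = None) -> WaveletField:
    """Continuous wavelet transform with the analytic complex Morlet wavelet.

    The series is symmetrically zero-padded to the next power of two (edge
    handling recorded in ``meta``); coefficients are computed in the Fourier
    domain at log-spaced frequencies spanning [fmin_factor * band_low, fs/2].
    The cone of influence uses the Morlet e-folding time sqrt(2) * scale.
    """
    cfg = cfg or WaveletConfig()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 64:
        raise ConfigurationError("x: need a 1-D series of length >= 64")
    if not np.all(np.isfinite(x)):
        raise ConfigurationError("x: non-finite values")
    if np.ptp(x) == 0.0:
        raise DegenerateSignalError("degenerate signal: zero variance input")
    if cfg.band_high >= fs / 2:
        raise ConfigurationError(
            f"band_high: {cfg.band_high} Hz not below Nyquist {fs / 2} Hz"
        )

    n = x.size
    npad = _next_pow2(n)
    pad_left = (npad - n) // 2
    xp = np.zeros(npad)
    xp[pad_left : pad_left + n] = x - x.mean()

    ff = cfg.fourier_factor
    fmax = fs / 2.0
    fmin = cfg.fmin_factor * cfg.band_low
    n_octaves = math.log2(fmax / fmin)
    n_scales = int(math.ceil(n_octaves * cfg.voices_per_octave)) + 1
    freqs = fmax * 2.0 ** (-np.arange(n_scales) / cfg.voices_per_octave)
    scales = 1.0 / (ff * freqs)

    omega = 2.0 * np.pi * np.fft.fftfreq(npad, d=1.0 / fs)
    xhat = np.fft.fft(xp)
    # analytic Morlet in the Fourier domain, L2-normalised per scale
    arg = scales[:, None] * omega[None, :]
    psi_hat = (
        math.pi**-0.25
        * np.sqrt(2.0 * np.pi * scales[:, None] * fs)
        * np.exp(-0.5 * (arg - cfg.omega0) ** 2)
        * (omega[None, :] > 0)
    )
    W = np.fft.ifft(xhat[None, :] * psi_hat, axis=1)[:, pad_left : pad_left + n]

    t = np.arange(n) / fs
    edge_dist = np.minimum(t, t[-1] - t)
    with np.errstate(divide="ignore"):
        coi = np.where(edge_dist > 0, math.sqrt(2.0) / (ff * edge_dist), np.inf)

    return WaveletField(
        freqs=freqs, t=t, W=W, coi=coi, scales=scales, fs=fs,
        meta={
            "padding": {"mode": "symmetric-zero", "n_padded": npad, "pad_left": pad_left},
            "config": asdict(cfg),
        },
    )


def _check_grids(Wx: WaveletField, Wy: WaveletField) -> None:
    if Wx.freqs.size != Wy.freqs.size or not np.allclose(Wx.freqs, Wy.freqs):
        raise GridMismatchError("wavelet fields have different frequency grids")
    if Wx.t.size != Wy.t.size or not np.allclose(Wx.t, Wy.t):
        raise GridMismatchError("wavelet fields have different time grids")


def _smooth(A: np.ndarray, field_: WaveletField, cfg: WaveletConfig) -> np.ndarray:
    """Scale-dependent time smoothing then fixed-octave scale smoothing."""
    out = A
    if cfg.smoothing_time_scalefactor > 0:
        out = np.empty_like(A)
        sigmas = field_.scales * field_.fs * cfg.smoothing_time_scalefactor
        for i, sig in enumerate(sigmas):
            out[i] = gaussian_filter1d(A[i], sigma=max(sig, 1e-6), mode="reflect")
    if cfg.smoothing_scale_octaves > 0:
        size = int(round(cfg.smoothing_scale_octaves * cfg.voices_per_octave))
        if size >= 2:
            out = uniform_filter1d(out, size=size, axis=0, mode="nearest")
    return out


def _smooth_complex(A: np.ndarray, field_: WaveletField, cfg: WaveletConfig) -> np.ndarray:
    return _smooth(A.real, field_, cfg) + 1j * _smooth(A.imag, field_, cfg)


def coherence_map(Wx: WaveletField, Wy: WaveletField, cfg: WaveletConfig | None = None) -> CouplingMap:
    """Smoothed magnitude-squared wavelet coherence with cross-spectrum phase."""
    cfg = cfg or WaveletConfig()
    _check_grids(Wx, Wy)
    sinv = 1.0 / Wx.scales[:, None]
    cross = _smooth_complex(Wx.W * np.conj(Wy.W) * sinv, Wx, cfg)
    sxx = _smooth(np.abs(Wx.W) ** 2 * sinv, Wx, cfg)
    syy = _smooth(np.abs(Wy.W) ** 2 * sinv, Wx, cfg)
    den = sxx * syy
    num = np.abs(cross) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    coh = np.clip(coh, 0.0, 1.0)
    phase = np.angle(cross)
    return CouplingMap(
        freqs=Wx.freqs, t=Wx.t, phase=phase, semblance=np.cos(phase),
        coi=np.maximum(Wx.coi, Wy.coi), coherence=coh,
        meta={"config": asdict(cfg), "phase_channel": "smoothed_cross_spectrum"},
    )


def semblance_map(Wx: WaveletField, Wy: WaveletField) -> CouplingMap:
    """Semblance cos(arg(Wx Wy*)) from the unsmoothed cross-wavelet spectrum."""
    _check_grids(Wx, Wy)
    phase = np.angle(Wx.W * np.conj(Wy.W))
    return CouplingMap(
        freqs=Wx.freqs, t=Wx.t, phase=phase, semblance=np.cos(phase),
        coi=np.maximum(Wx.coi, Wy.coi), coherence=None,
        meta={"phase_channel": "raw_cross_spectrum"},
    )


def band_average(
    cmap: CouplingMap,
    cfg: WaveletConfig | None = None,
    pair: str = "oxCCO-HbO2",
    semblance_src: Optional[CouplingMap] = None,
) -> CouplingSummary:
    """Arithmetic mean of coherence and semblance over in-band cells.

    Cells outside the cone of influence are excluded when
    ``cfg.coi_policy == 'exclude'`` (the default).  ``semblance_src`` lets the
    caller average semblance from a raw-phase map while coherence comes from
    ``cmap``; by default both channels come from ``cmap``.
    """
    cfg = cfg or WaveletConfig()
    f = cmap.freqs
    in_band = (f >= cfg.band_low) & (f <= cfg.band_high)
    if not np.any(in_band):
        raise ConfigurationError("band does not intersect the map's frequency grid")
    mask = np.broadcast_to(in_band[:, None], cmap.semblance.shape)
    if cfg.coi_policy == "exclude":
        mask = mask & (f[:, None] >= cmap.coi[None, :])
    n_cells = int(mask.sum())
    if n_cells == 0:
        raise ConfigurationError(
            "no in-band cells inside the cone of influence; record too short "
            "for this band (use a longer recording or coi_policy='include')"
        )
    semb_map = semblance_src if semblance_src is not None else cmap
    band_semblance = float(np.mean(semb_map.semblance[mask]))
    if cmap.coherence is not None:
        band_coherence = float(np.mean(cmap.coherence[mask]))
    else:
        band_coherence = 0.0
    return CouplingSummary(
        pair=pair,
        band_coherence=band_coherence,
        band_semblance=band_semblance,
        n_cells=n_cells,
        config_hash=cfg.config_hash(),
    )


def couple_recording(s: SignalSet, cfg: WaveletConfig | None = None) -> dict:
    """Band-averaged coupling of oxCCO with HbO2, HHb, HbT and HbDiff.

    Coherence is taken from the smoothed coherence map, semblance from the
    raw cross-wavelet phase; all four pairs share one configuration.
    Returns an ordered dict pair -> CouplingSummary.
    """
    cfg = cfg or WaveletConfig()
    fields = {}
    for name in ("oxcco", "hbo2", "hhb", "hbt", "hbdiff"):
        fields[name] = cwt_morlet(s.signals[name], s.fs, cfg)
    out = {}
    Wc = fields["oxcco"]
    for pair in PAIR_ORDER:
        Wh = fields[_PAIR_SIGNAL[pair]]
        cmap = coherence_map(Wc, Wh, cfg)
        smap = semblance_map(Wc, Wh)
        out[pair] = band_average(cmap, cfg, pair=pair, semblance_src=smap)
    return out
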
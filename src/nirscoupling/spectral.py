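"""Broadband spectral resolution of chromophore concentration changes.

Solves the modified Beer-Lambert law

    dA(lambda, t) = sum_i eps_i(lambda) * dC_i(t) * d * DPF(lambda)

for the three chromophores HbO2, HHb and oxCCO by ordinary least squares over
the full 780-900 nm attenuation-change spectrum at each time point.  dC is in
micromolar, the source-detector distance ``d`` in cm, and the specific
extinction coefficients eps in OD * uM^-1 * cm^-1.  Because only *changes*
relative to a baseline are resolved, a mis-specified (but wavelength-flat)
differential pathlength factor rescales the traces without distorting the
scale-invariant coupling metrics computed downstream.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .errors import ConfigurationError, GridMismatchError, RankDeficientError

__all__ = [
    "ExtinctionModel",
    "AttenuationSeries",
    "fit_concentrations",
    "regrid_extinction",
    "load_extinction_table",
    "load_default_extinction",
]

_CHROMOPHORES = ("hbo2", "hhb", "oxcco")

# epsilon in OD * uM^-1 * cm^-1 is O(1e-3); values this large suggest a
# mM^-1 table was loaded without rescaling.
_UNIT_WARN_EPS = 0.05


@dataclass
class ExtinctionModel:
    """Wavelength grid with specific extinction coefficients and pathlength.

    Parameters
    ----------
    wavelengths : array
        Strictly increasing grid in nm (nominally within 780-900 nm).
    eps_hbo2, eps_hhb, eps_oxcco : array
        Specific extinction coefficients per wavelength, OD * uM^-1 * cm^-1.
    dpf : float or array
        Differential pathlength factor, dimensionless; a scalar is broadcast
        over the grid.
    distance : float
        Source-detector separation in cm.
    """

    wavelengths: np.ndarray
    eps_hbo2: np.ndarray
    eps_hhb: np.ndarray
    eps_oxcco: np.ndarray
    dpf: np.ndarray = field(default_factory=lambda: np.array(4.0))
    distance: float = 1.0

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        for name in _CHROMOPHORES:
            key = f"eps_{name}"
            setattr(self, key, np.asarray(getattr(self, key), dtype=float))
        self.dpf = np.broadcast_to(
            np.asarray(self.dpf, dtype=float), self.wavelengths.shape
        ).copy()
        nl = self.wavelengths.size
        if nl < 3:
            raise ConfigurationError(
                "wavelengths: need >= 3 wavelengths to resolve 3 chromophores"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ConfigurationError("wavelengths: grid must be strictly increasing")
        for name in _CHROMOPHORES:
            eps = getattr(self, f"eps_{name}")
            if eps.shape != self.wavelengths.shape:
                raise ConfigurationError(f"eps_{name}: shape differs from wavelength grid")
            if not np.all(np.isfinite(eps)) or np.any(eps < 0):
                raise ConfigurationError(f"eps_{name}: coefficients must be finite and >= 0")
        if not np.all(np.isfinite(self.dpf)) or np.any(self.dpf <= 0):
            raise ConfigurationError("dpf: must be finite and > 0")
        if not np.isfinite(self.distance) or self.distance <= 0:
            raise ConfigurationError("distance: must be finite and > 0")
        self._check_rank()
        if max(float(np.max(getattr(self, f"eps_{c}"))) for c in _CHROMOPHORES) > _UNIT_WARN_EPS:
            warnings.warn(
                "extinction coefficients exceed 0.05 OD/uM/cm; check that the "
                "table is per-uM (a per-mM table would be ~1000x larger)",
                UserWarning,
                stacklevel=2,
            )

    @property
    def design_matrix(self) -> np.ndarray:
        """(n_wavelengths, 3) Beer-Lambert design: eps * dpf * distance."""
        eps = np.column_stack([self.eps_hbo2, self.eps_hhb, self.eps_oxcco])
        return eps * (self.dpf * self.distance)[:, None]

    def _check_rank(self) -> None:
        X = self.design_matrix
        rank = np.linalg.matrix_rank(X)
        if rank < 3:
            # name the most collinear pair for the error message
            Xn = X / np.maximum(np.linalg.norm(X, axis=0), 1e-300)
            corr = np.abs(Xn.T @ Xn)
            np.fill_diagonal(corr, 0.0)
            i, j = np.unravel_index(np.argmax(corr), corr.shape)
            raise RankDeficientError(
                f"extinction design matrix has rank {rank} < 3; columns "
                f"{_CHROMOPHORES[i]} and {_CHROMOPHORES[j]} are collinear"
            )


@dataclass
class AttenuationSeries:
    """Attenuation-change matrix dA (optical density), (n_wavelengths, n_times)."""

    wavelengths: np.ndarray
    t: np.ndarray
    dA: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        self.dA = np.asarray(self.dA, dtype=float)
        if self.dA.shape != (self.wavelengths.size, self.t.size):
            raise ConfigurationError(
                f"dA: shape {self.dA.shape} inconsistent with "
                f"{self.wavelengths.size} wavelengths x {self.t.size} times"
            )
        if not np.all(np.isfinite(self.dA)):
            raise ConfigurationError("dA: non-finite entries")


def fit_concentrations(atten: AttenuationSeries, model: ExtinctionModel):
    """Resolve HbO2/HHb/oxCCO concentration changes from attenuation spectra.

    Per-time-point ordinary least squares on the modified Beer-Lambert design.
    The wavelength grids must match exactly; use :func:`regrid_extinction`
    first if they do not.  Residual spectra are retained in ``meta`` for QC.

    Returns
    -------
    ChromophoreSeries
        Traces in uM; ``meta['residuals']`` holds the (n_wavelengths, n_times)
        residual matrix and ``meta['residual_rms']`` its per-time RMS.
    """
    from .synthetic import ChromophoreSeries  # local import avoids a cycle

    if atten.wavelengths.size != model.wavelengths.size or not np.array_equal(
        atten.wavelengths, model.wavelengths
    ):
        raise GridMismatchError(
            "attenuation and extinction wavelength grids differ; regrid the "
            "extinction model onto the spectrometer grid (no silent interpolation)"
        )
    X = model.design_matrix
    # lstsq solves all time points at once; rank was validated on the model
    C, *_ = np.linalg.lstsq(X, atten.dA, rcond=None)
    resid = atten.dA - X @ C
    t = atten.t
    if t.size >= 2:
        fs = 1.0 / float(np.median(np.diff(t)))
    else:
        fs = np.nan
    return ChromophoreSeries(
        t=t,
        hbo2=C[0],
        hhb=C[1],
        oxcco=C[2],
        fs=fs,
        meta={
            "source": "fit_concentrations",
            "residuals": resid,
            "residual_rms": np.sqrt(np.mean(resid**2, axis=0)),
            "distance_cm": model.distance,
        },
    )


def regrid_extinction(model: ExtinctionModel, target_wavelengths) -> ExtinctionModel:
    """Linearly interpolate the extinction model onto ``target_wavelengths``.

    Extrapolation outside the model's span is refused.  The interpolated model
    is revalidated (grid monotonicity, full rank).
    """
    target = np.asarray(target_wavelengths, dtype=float)
    lo, hi = model.wavelengths[0], model.wavelengths[-1]
    if target.size and (target.min() < lo or target.max() > hi):
        raise ConfigurationError(
            f"target_wavelengths: [{target.min():g}, {target.max():g}] nm extends "
            f"outside the model span [{lo:g}, {hi:g}] nm (extrapolation refused)"
        )
    interp = lambda y: np.interp(target, model.wavelengths, y)  # noqa: E731
    return ExtinctionModel(
        wavelengths=target,
        eps_hbo2=interp(model.eps_hbo2),
        eps_hhb=interp(model.eps_hhb),
        eps_oxcco=interp(model.eps_oxcco),
        dpf=interp(model.dpf),
        distance=model.distance,
    )


def load_extinction_table(path, distance: float = 1.0) -> ExtinctionModel:
    """Load an extinction table CSV (wavelength_nm, eps_hbo2, eps_hhb, eps_oxcco, dpf)."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"wavelength_nm", "eps_hbo2", "eps_hhb", "eps_oxcco", "dpf"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"extinction table missing columns: {sorted(missing)}")
    return ExtinctionModel(
        wavelengths=df["wavelength_nm"].to_numpy(),
        eps_hbo2=df["eps_hbo2"].to_numpy(),
        eps_hhb=df["eps_hhb"].to_numpy(),
        eps_oxcco=df["eps_oxcco"].to_numpy(),
        dpf=df["dpf"].to_numpy(),
        distance=distance,
    )


def load_default_extinction(distance: float = 1.0) -> ExtinctionModel:
    """Packaged synthetic stand-in extinction spectra over 780-900 nm.

    Smooth analytic curves shaped like published NIR spectra (HbO2 rising,
    HHb falling, oxidised-minus-reduced CCO broad band near 830 nm); see the
    JSON sidecar for units and provenance.  Synthetic: intended for simulation
    and round-trip testing, not for quantifying real recordings.
    """
    pkg = resources.files("nirscoupling.data")
    with resources.as_file(pkg / "extinction_synthetic.csv") as p:
        model = load_extinction_table(p, distance=distance)
    return model


def default_extinction_metadata() -> dict:
    pkg = resources.files("nirscoupling.data")
    return json.loads((pkg / "extinction_synthetic.json").read_text())
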
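"""Electro-mechanical model of an inverse-piezoresistive nanocomposite strain gauge.

Nickel-nanostrand / nickel-coated-carbon-fiber silicone composites exhibit
*inverse* piezoresistivity: past a critical strain their electrical resistance
falls monotonically with further stretch, dropping over several orders of
magnitude across the working range.  The strain-resistance curve of a
conductive composition is well described by a scaled log-normal shape,

    R(eps) = d / (sqrt(2*pi) * a * c * eps) * exp(-(ln(eps/c))**2 / (2*a**2))

where ``a`` is the log-normal shape parameter, ``c`` a strain-scale parameter
and ``d`` an amplitude scale (Ohm * strain).  The curve rises to a single
maximum at the critical strain ``eps_c = c * exp(-a**2)`` and decreases
strictly beyond it; the region above ``eps_c`` is the usable working range of
the sensor.

This module provides the forward model, its derived quantities (critical
strain, average gauge factor) and a nonlinear least-squares fit of the three
parameters to measured strain-resistance sweeps.  Because measured resistances
span many decades, fitting is performed on log10(resistance).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

_SQRT_2PI = math.sqrt(2.0 * math.pi)

__all__ = [
    "PiezoParams",
    "StrainSweep",
    "FitResult",
    "SensorError",
    "FitError",
    "resistance",
    "critical_strain",
    "gauge_factor",
    "fit_piezo_params",
]


class SensorError(ValueError):
    """Invalid input to the sensor model (domain violation)."""


class FitError(RuntimeError):
    """Parameter fit failed; carries the best parameters found so far."""

    def __init__(self, message: str, params: "PiezoParams | None" = None,
                 r_squared: float | None = None):
        super().__init__(message)
        self.params = params
        self.r_squared = r_squared


@dataclass(frozen=True)
class PiezoParams:
    """Parameters of the log-normal strain-resistance model.

    Attributes
    ----------
    a : float
        Log-normal shape parameter (dimensionless), > 0.
    c : float
        Strain scale parameter (strain fraction), > 0.
    d : float
        Amplitude scale (Ohm * strain), > 0.
    """

    a: float
    c: float
    d: float

    def __post_init__(self):
        for name in ("a", "c", "d"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise SensorError(f"PiezoParams.{name} must be finite and > 0, got {v!r}")

    def to_dict(self) -> dict:
        return {"a": self.a, "c": self.c, "d": self.d}

    @classmethod
    def from_dict(cls, d: dict) -> "PiezoParams":
        return cls(a=float(d["a"]), c=float(d["c"]), d=float(d["d"]))


@dataclass(frozen=True)
class StrainSweep:
    """A measured strain-resistance sweep of one sensor composition.

    ``strain`` is a strictly increasing sequence of strain fractions (> 0);
    ``resistance`` the matching positive resistances in Ohm.  At least four
    points are required (the model has three parameters).
    """

    strain: np.ndarray
    resistance: np.ndarray

    def __init__(self, strain: Sequence[float], resistance: Sequence[float]):
        strain = np.asarray(strain, dtype=float)
        resistance = np.asarray(resistance, dtype=float)
        if strain.ndim != 1 or resistance.ndim != 1 or len(strain) != len(resistance):
            raise SensorError("strain and resistance must be equal-length 1-D sequences")
        if len(strain) < 4:
            raise SensorError("a sweep needs at least 4 points")
        if not np.all(strain > 0):
            raise SensorError("strains must be positive")
        if not np.all(np.diff(strain) > 0):
            raise SensorError("strains must be strictly increasing")
        if not np.all(resistance > 0):
            raise SensorError("resistances must be positive")
        object.__setattr__(self, "strain", strain)
        object.__setattr__(self, "resistance", resistance)

    def __len__(self) -> int:
        return len(self.strain)

    @classmethod
    def from_csv(cls, path) -> "StrainSweep":
        """Read a sweep from CSV with header ``strain,resistance_ohm``."""
        df = pd.read_csv(path)
        missing = {"strain", "resistance_ohm"} - set(df.columns)
        if missing:
            raise SensorError(f"sweep CSV missing columns: {sorted(missing)}")
        return cls(df["strain"].to_numpy(), df["resistance_ohm"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"strain": self.strain, "resistance_ohm": self.resistance}).to_csv(
            path, index=False
        )


def resistance(eps, params: PiezoParams):
    """Model resistance (Ohm) at strain fraction ``eps``.

    Accepts a scalar or array of strains; every strain must be > 0.  The
    returned curve is strictly positive and unimodal: it rises to its single
    maximum at ``critical_strain(params)`` and decreases beyond it.
    """
    eps_arr = np.asarray(eps, dtype=float)
    if np.any(~np.isfinite(eps_arr)) or np.any(eps_arr <= 0):
        raise SensorError("strain must be finite and > 0")
    a, c, d = params.a, params.c, params.d
    log_ratio = np.log(eps_arr / c)
    out = d / (_SQRT_2PI * a * c * eps_arr) * np.exp(-(log_ratio ** 2) / (2.0 * a ** 2))
    if np.isscalar(eps) or np.ndim(eps) == 0:
        return float(out)
    return out


def critical_strain(params: PiezoParams) -> float:
    """Strain at the resistance maximum, ``c * exp(-a**2)``.

    Above this strain the resistance decreases monotonically; minimizing it
    widens the usable working range of the gauge.
    """
    return params.c * math.exp(-params.a ** 2)


def gauge_factor(params: PiezoParams, eps_lo: float | None = None,
                 eps_hi: float | None = None) -> float:
    """Average gauge factor |dR|/(R0 * d_eps) over a strain window.

    The gauge factor is the relative resistance change per unit strain,
    normalized by the resistance at the window start.  Without explicit
    bounds the window defaults to a 10% working-strain range starting at the
    critical strain, ``[eps_c, eps_c + 0.10]``.
    """
    if eps_lo is None and eps_hi is None:
        eps_lo = critical_strain(params)
        eps_hi = eps_lo + 0.10
    if eps_lo is None or eps_hi is None:
        raise SensorError("provide both strain bounds or neither")
    if not (eps_hi > eps_lo > 0):
        raise SensorError(f"need eps_hi > eps_lo > 0, got [{eps_lo}, {eps_hi}]")
    r_lo = resistance(eps_lo, params)
    r_hi = resistance(eps_hi, params)
    return abs(r_hi - r_lo) / (r_lo * (eps_hi - eps_lo))


def _log10_model(theta: np.ndarray, eps: np.ndarray) -> np.ndarray:
    # theta = (ln a, ln c, ln d): unconstrained parameterization keeps a,c,d > 0
    a, c, d = np.exp(theta)
    log_ratio = np.log(eps / c)
    ln_r = (np.log(d) - np.log(_SQRT_2PI * a * c) - np.log(eps)
            - log_ratio ** 2 / (2.0 * a ** 2))
    return ln_r / math.log(10.0)


@dataclass(frozen=True)
class FitResult:
    params: PiezoParams
    r_squared: float
    n_iter: int
    converged: bool

    def to_json(self, path=None) -> str:
        payload = {
            "params": self.params.to_dict(),
            "r_squared": self.r_squared,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def fit_piezo_params(sweep: StrainSweep, init: PiezoParams | None = None,
                     max_iter: int = 2000) -> FitResult:
    """Fit (a, c, d) to a sweep by least squares on log10(resistance).

    Measured resistances span several decades, so residuals are taken in
    log10 space; the reported R^2 is the coefficient of determination in the
    same space.  The warm start places ``c`` at the strain of the observed
    resistance maximum, ``a = 0.5``, and scales ``d`` to the peak height.

    Raises
    ------
    FitError
        If the sweep carries no usable variation (constant resistance) or the
        optimizer fails to converge; the error carries the best-so-far
        parameters.
    """
    y = np.log10(sweep.resistance)
    if np.ptp(y) < 1e-12:
        raise FitError("constant-resistance sweep carries no shape information")

    if init is None:
        i_peak = int(np.argmax(sweep.resistance))
        c0 = float(sweep.strain[i_peak])
        a0 = 0.5
        d0 = float(sweep.resistance[i_peak] * _SQRT_2PI * a0 * c0 * sweep.strain[i_peak])
        init = PiezoParams(a=a0, c=c0, d=d0)
    theta0 = np.log([init.a, init.c, init.d])

    res = least_squares(
        lambda th: _log10_model(th, sweep.strain) - y,
        theta0,
        method="lm",
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
        max_nfev=max_iter,
    )
    a, c, d = np.exp(res.x)
    params = PiezoParams(a=float(a), c=float(c), d=float(d))
    ss_res = float(np.sum(res.fun ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    if not res.success:
        raise FitError(f"fit did not converge: {res.message}", params=params, r_squared=r2)
    return FitResult(params=params, r_squared=r2, n_iter=int(res.nfev), converged=True)
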
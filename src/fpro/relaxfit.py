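"""Fitting of relaxation time series: exponential decays and NOE build-ups.

Inversion-recovery and echo/CPMG series are fitted with the three-parameter
monoexponential I(t) = A + B·e^(−R·t).  Selective-saturation NOE build-ups
are fitted with

    I(t) = I0 + (σ/ρ)·(γH/γF)·I0·(1 − e^(−ρ·t)),

whose plateau I0·(1 + NOEmax) gives the steady-state enhancement
NOEmax = (γH/γF)·σ/ρ.  Levenberg–Marquardt least squares throughout, with
initial guesses from a log-linear regression on the series tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import lmfit

from .constants import PhysicalConstants

__all__ = [
    "DecaySeries",
    "NOEBuildupFit",
    "MonoexponentialFit",
    "fit_noe_buildup",
    "fit_monoexponential",
    "noe_max_from_rates",
]

SERIES_KINDS = ("inversion_recovery", "decay", "noe_buildup")


@dataclass(frozen=True)
class DecaySeries:
    """A (time, intensity) relaxation series.

    Repeated time points are legitimate — replicate acquisitions used for
    empirical uncertainty estimates — and are treated as independent
    observations.
    """

    times: np.ndarray
    intensities: np.ndarray
    kind: str
    intensity_errors: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        y = np.asarray(self.intensities, float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)
        if self.intensity_errors is not None:
            object.__setattr__(
                self, "intensity_errors", np.asarray(self.intensity_errors, float)
            )
        if self.kind not in SERIES_KINDS:
            raise ValueError(f"kind must be one of {SERIES_KINDS}, got {self.kind!r}")
        if t.shape != y.shape:
            raise ValueError("times and intensities must have equal length")
        if np.any(t < 0):
            raise ValueError("times must be non-negative")
        if len(np.unique(t)) < 4:
            raise ValueError("need at least 4 distinct time points")

    def replicate_spread(self) -> float | None:
        """Empirical noise estimate from repeated time points (None if none)."""
        t = self.times
        spreads = []
        for u in np.unique(t):
            grp = self.intensities[t == u]
            if len(grp) > 1:
                spreads.append(np.std(grp, ddof=1))
        return float(np.mean(spreads)) if spreads else None


@dataclass(frozen=True)
class MonoexponentialFit:
    rate: float
    amplitude: float
    offset: float
    rate_err: float
    amplitude_err: float
    offset_err: float
    residual_norm: float


@dataclass(frozen=True)
class NOEBuildupFit:
    i0: float
    rho: float
    sigma: float
    noe_max: float
    i0_err: float
    rho_err: float
    sigma_err: float
    noe_max_err: float
    residual_norm: float


def noe_max_from_rates(
    rho: float, sigma: float, constants: PhysicalConstants | None = None
) -> float:
    """Steady-state NOE (fractional) from the rate pair: (γH/γF)·σ/ρ."""
    if rho <= 0:
        raise ValueError(f"rho must be positive, got {rho}")
    c = constants or PhysicalConstants()
    return c.gamma_ratio * sigma / rho


def _weights(series: DecaySeries) -> np.ndarray | None:
    if series.intensity_errors is None:
        return None
    return 1.0 / np.where(series.intensity_errors > 0, series.intensity_errors, np.inf)


def _initial_rate(t: np.ndarray, y: np.ndarray) -> float:
    """Rough rate from a log-linear regression on |y − y(∞)| over the tail."""
    tail = y[-1]
    dev = np.abs(y - tail)
    mask = dev > 0.05 * dev.max()
    if mask.sum() < 2:
        return 1.0 / max(t.max(), 1e-12)
    slope = np.polyfit(t[mask], np.log(dev[mask] + 1e-30), 1)[0]
    return float(abs(slope)) or 1.0 / max(t.max(), 1e-12)


def fit_monoexponential(series: DecaySeries) -> MonoexponentialFit:
    """Fit I(t) = A + B·e^(−R·t); R is R1 (inversion recovery) or R2 (decay)."""
    t, y = series.times, series.intensities
    span = y.max() - y.min()
    if span == 0 or span < 1e-12 * max(abs(y).max(), 1.0):
        raise ValueError("constant intensity series: decay rate is unidentifiable")

    p = lmfit.Parameters()
    p.add("offset", value=float(y[np.argmax(t)]))
    p.add("amplitude", value=float(y[np.argmin(t)] - y[np.argmax(t)]))
    p.add("rate", value=_initial_rate(t, y), min=0.0)

    def resid(params: lmfit.Parameters) -> np.ndarray:
        m = params["offset"] + params["amplitude"] * np.exp(-params["rate"] * t)
        r = y - m
        w = _weights(series)
        return r if w is None else r * w

    out = lmfit.minimize(resid, p, method="leastsq")
    if not out.success:
        raise RuntimeError(
            f"monoexponential fit did not converge (residual norm {np.linalg.norm(out.residual):.3g})"
        )

    def err(name: str) -> float:
        s = out.params[name].stderr
        return float(s) if s is not None else float("nan")

    return MonoexponentialFit(
        rate=float(out.params["rate"].value),
        amplitude=float(out.params["amplitude"].value),
        offset=float(out.params["offset"].value),
        rate_err=err("rate"),
        amplitude_err=err("amplitude"),
        offset_err=err("offset"),
        residual_norm=float(np.linalg.norm(out.residual)),
    )


def fit_noe_buildup(
    series: DecaySeries, constants: PhysicalConstants | None = None
) -> NOEBuildupFit:
    """Fit the three-parameter NOE build-up model for (I0, ρ, σ).

    NOEmax is computed from the fitted rates; its uncertainty propagates
    the fit covariance of σ/ρ.
    """
    if series.kind != "noe_buildup":
        raise ValueError(f"series kind must be 'noe_buildup', got {series.kind!r}")
    c = constants or PhysicalConstants()
    t, y = series.times, series.intensities

    p = lmfit.Parameters()
    i0_guess = float(y[np.argmin(t)])
    if i0_guess == 0:
        i0_guess = float(np.mean(y)) or 1.0
    p.add("i0", value=i0_guess)
    p.add("rho", value=_initial_rate(t, y), min=1e-6)
    plateau = float(y[np.argmax(t)])
    sigma_guess = (plateau / i0_guess - 1.0) / c.gamma_ratio * p["rho"].value
    p.add("sigma", value=sigma_guess)

    def resid(params: lmfit.Parameters) -> np.ndarray:
        i0, rho, sig = params["i0"], params["rho"], params["sigma"]
        m = i0 + (sig / rho) * c.gamma_ratio * i0 * (1.0 - np.exp(-rho * t))
        r = y - m
        w = _weights(series)
        return r if w is None else r * w

    out = lmfit.minimize(resid, p, method="leastsq")
    if not out.success:
        raise RuntimeError(
            f"NOE build-up fit did not converge (residual norm {np.linalg.norm(out.residual):.3g})"
        )
    rho = float(out.params["rho"].value)
    sig = float(out.params["sigma"].value)
    noe = noe_max_from_rates(rho, sig, c)

    def err(name: str) -> float:
        s = out.params[name].stderr
        return float(s) if s is not None else float("nan")

    rho_err, sig_err = err("rho"), err("sigma")
    if np.isfinite(rho_err) and np.isfinite(sig_err) and sig != 0:
        noe_err = abs(noe) * np.hypot(sig_err / sig, rho_err / rho)
    else:
        noe_err = float("nan")

    return NOEBuildupFit(
        i0=float(out.params["i0"].value),
        rho=rho,
        sigma=sig,
        noe_max=noe,
        i0_err=err("i0"),
        rho_err=rho_err,
        sigma_err=sig_err,
        noe_max_err=float(noe_err),
        residual_norm=float(np.linalg.norm(out.residual)),
    )
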
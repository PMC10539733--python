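"""Exchange broadening of ¹⁹F lines across a binding titration.

In fast exchange (k_exc ≫ Δω) the apparent transverse relaxation rate of a
population-averaged peptide signal is

    R2‡ = pf·R2f + pb·R2b + pf·pb·Δω²/k_exc,
    k_exc = kon·([SH3]_free + Kd),

where pf/pb are the free/bound peptide fractions, R2f/R2b the intrinsic
rates of the two forms and Δω the bound−free angular frequency difference.
R2‡ itself is read off 1D spectra as π × FWHM of a Lorentzian line fit.
With Δω, the populations and Kd fixed from the chemical-shift-perturbation
fit, a weighted least-squares fit of the R2‡ titration profile yields kon,
R2f and R2b.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import lmfit

from .binding import SpeciesConcentrations

__all__ = [
    "ExchangeParams",
    "PeakFit",
    "kexc",
    "r2_apparent",
    "fit_lorentzian_peaks",
    "fit_kon",
    "KonFit",
]

#: fast-exchange validity margin: flag when k_exc < 5·|Δω|
FAST_EXCHANGE_MARGIN = 5.0


@dataclass(frozen=True)
class ExchangeParams:
    """Kinetic and relaxation parameters of one exchanging ¹⁹F signal."""

    kon: float  # M^-1 s^-1
    kd_uM: float
    delta_omega: float  # rad s^-1 (2π × Δν)
    r2_free: float  # s^-1
    r2_bound: float  # s^-1

    def __post_init__(self) -> None:
        if self.kon < 0 or self.r2_free <= 0 or self.r2_bound <= 0 or self.kd_uM <= 0:
            raise ValueError("kon must be >= 0 and Kd, R2f, R2b positive")


def kexc(params: ExchangeParams, sh3_free_uM: float) -> float:
    """Exchange rate k_exc = kon·([SH3]_free + Kd) in s⁻¹ (concentrations µM → M)."""
    if sh3_free_uM < 0:
        raise ValueError("free SH3 concentration must be non-negative")
    return params.kon * (sh3_free_uM + params.kd_uM) * 1e-6


def r2_apparent(
    params: ExchangeParams, conc: SpeciesConcentrations
) -> tuple[float, bool]:
    """Apparent R2 of the averaged peptide line, plus a fast-exchange flag.

    Returns ``(R2‡, valid)`` where ``valid`` is False when
    k_exc < 5·|Δω|, i.e. when the fast-exchange expression is stretched.
    """
    pb, pf = conc.pb, conc.pf
    k = kexc(params, conc.free_SH3)
    base = pf * params.r2_free + pb * params.r2_bound
    if pb * pf > 0:
        if k == 0:
            raise ValueError("k_exc = 0 with both populations present")
        base += pf * pb * params.delta_omega**2 / k
    valid = k >= FAST_EXCHANGE_MARGIN * abs(params.delta_omega) or pb * pf == 0
    return base, valid


@dataclass(frozen=True)
class PeakFit:
    """One Lorentzian line: centre/width in Hz, R2‡ = π·FWHM."""

    centre_hz: float
    fwhm_hz: float
    amplitude: float
    baseline: float
    centre_err: float
    fwhm_err: float
    amplitude_err: float

    @property
    def r2_apparent(self) -> float:
        return math.pi * self.fwhm_hz

    @property
    def amplitude_significant(self) -> bool:
        """False when the fitted amplitude is within 3σ of zero (no real peak)."""
        return not (
            np.isfinite(self.amplitude_err)
            and abs(self.amplitude) < 3.0 * self.amplitude_err
        )


def _lorentz(f: np.ndarray, centre: float, fwhm: float, amp: float) -> np.ndarray:
    hw = fwhm / 2.0
    return amp * hw**2 / ((f - centre) ** 2 + hw**2)


def fit_lorentzian_peaks(
    freq_hz: Sequence[float],
    intensity: Sequence[float],
    n_peaks: int = 1,
    init_centres: Sequence[float] | None = None,
) -> list[PeakFit]:
    """Fit a sum of Lorentzians plus a constant baseline to a 1D spectrum.

    Initial centres default to the ``n_peaks`` highest well-separated
    samples.  A warning is emitted for peak pairs closer than FWHM/4,
    where the individual widths become strongly covariant.
    """
    f = np.asarray(freq_hz, float)
    y = np.asarray(intensity, float)
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    span = f.max() - f.min()

    if init_centres is None:
        order = np.argsort(y)[::-1]
        centres: list[float] = []
        for i in order:
            if all(abs(f[i] - c) > span / (4 * n_peaks) for c in centres):
                centres.append(float(f[i]))
            if len(centres) == n_peaks:
                break
    else:
        centres = [float(c) for c in init_centres]
        if len(centres) != n_peaks:
            raise ValueError("init_centres length must equal n_peaks")

    p = lmfit.Parameters()
    p.add("baseline", value=float(np.median(y)))
    for i, c in enumerate(centres):
        p.add(f"c{i}", value=c, min=f.min(), max=f.max())
        p.add(f"w{i}", value=span / 20.0, min=1e-6)
        p.add(f"a{i}", value=float(y.max() - np.median(y)))

    def model(params: lmfit.Parameters) -> np.ndarray:
        out = np.full_like(f, params["baseline"].value)
        for i in range(n_peaks):
            out += _lorentz(
                f, params[f"c{i}"].value, params[f"w{i}"].value, params[f"a{i}"].value
            )
        return out

    fit = lmfit.minimize(lambda q: y - model(q), p, method="leastsq")
    if not fit.success:
        raise RuntimeError("Lorentzian line fit did not converge")

    peaks = []
    for i in range(n_peaks):
        def err(name: str) -> float:
            s = fit.params[name].stderr
            return float(s) if s is not None else float("nan")

        peaks.append(
            PeakFit(
                centre_hz=float(fit.params[f"c{i}"].value),
                fwhm_hz=float(fit.params[f"w{i}"].value),
                amplitude=float(fit.params[f"a{i}"].value),
                baseline=float(fit.params["baseline"].value),
                centre_err=err(f"c{i}"),
                fwhm_err=err(f"w{i}"),
                amplitude_err=err(f"a{i}"),
            )
        )
    peaks.sort(key=lambda pk: pk.centre_hz)
    for a, b in zip(peaks, peaks[1:]):
        min_w = min(a.fwhm_hz, b.fwhm_hz)
        if abs(b.centre_hz - a.centre_hz) < min_w / 4.0:
            warnings.warn(
                f"peaks at {a.centre_hz:.2f} and {b.centre_hz:.2f} Hz are closer than "
                "FWHM/4; widths are strongly covariant",
                stacklevel=2,
            )
    return peaks


@dataclass(frozen=True)
class KonFit:
    kon: float
    r2_free: float
    r2_bound: float
    kon_err: float
    r2_free_err: float
    r2_bound_err: float
    reduced_chi2: float
    exchange_term_identifiable: bool


def fit_kon(
    r2app_s1: Sequence[float],
    concentrations: Sequence[SpeciesConcentrations],
    delta_nu_hz: float,
    kd_uM: float,
    r2_errors: Sequence[float] | None = None,
    kon_grid: Sequence[float] = tuple(10.0**e for e in (6, 7, 8, 9, 10)),
) -> KonFit:
    """Fit (kon, R2f, R2b) to an R2‡ titration profile.

    Δω and Kd come fixed from the CSP fit; speciation per point from the
    equilibrium solver.  The optimisation is restarted from each kon in a
    log grid spanning 10⁶–10¹⁰ M⁻¹s⁻¹ and the best solution kept.  The
    result is flagged unidentifiable when the exchange term contributes
    < 10 % of R2‡ at every point.
    """
    if delta_nu_hz == 0:
        raise ValueError("delta_nu = 0: kon is unidentifiable from exchange broadening")
    r2 = np.asarray(r2app_s1, float)
    if len(r2) < 4:
        raise ValueError("need at least 4 titration points")
    errs = (
        np.asarray(r2_errors, float)
        if r2_errors is not None
        else np.full_like(r2, 1.0)
    )
    dw = 2.0 * math.pi * abs(delta_nu_hz)

    def resid(p: lmfit.Parameters) -> np.ndarray:
        ep = ExchangeParams(
            kon=p["kon"].value,
            kd_uM=kd_uM,
            delta_omega=dw,
            r2_free=p["r2f"].value,
            r2_bound=p["r2b"].value,
        )
        pred = np.array([r2_apparent(ep, c)[0] for c in concentrations])
        return (r2 - pred) / errs

    best = None
    for kon0 in kon_grid:
        p = lmfit.Parameters()
        p.add("kon", value=kon0, min=1e4, max=1e12)
        p.add("r2f", value=max(float(r2.min()), 1.0), min=1e-3)
        p.add("r2b", value=max(float(r2.max()), 2.0), min=1e-3)
        try:
            fit = lmfit.minimize(resid, p, method="leastsq")
        except Exception:
            continue
        if fit.success and (best is None or fit.chisqr < best.chisqr):
            best = fit
    if best is None:
        raise RuntimeError("kon fit did not converge from any start")

    ep = ExchangeParams(
        kon=best.params["kon"].value,
        kd_uM=kd_uM,
        delta_omega=dw,
        r2_free=best.params["r2f"].value,
        r2_bound=best.params["r2b"].value,
    )
    fractions = []
    for c in concentrations:
        total, _ = r2_apparent(ep, c)
        exch = (
            c.pf * c.pb * dw**2 / kexc(ep, c.free_SH3) if c.pb * c.pf > 0 else 0.0
        )
        fractions.append(exch / total if total > 0 else 0.0)
    identifiable = max(fractions) >= 0.10

    def err(name: str) -> float:
        s = best.params[name].stderr
        return float(s) if s is not None else float("nan")

    nfree = best.residual.size - best.nvarys
    return KonFit(
        kon=float(best.params["kon"].value),
        r2_free=float(best.params["r2f"].value),
        r2_bound=float(best.params["r2b"].value),
        kon_err=err("kon"),
        r2_free_err=err("r2f"),
        r2_bound_err=err("r2b"),
        reduced_chi2=float(best.chisqr / nfree) if nfree > 0 else float("inf"),
        exchange_term_identifiable=identifiable,
    )
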
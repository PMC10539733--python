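"""Peptide–SH3 binding equilibria and chemical-shift-perturbation fitting.

A proline-rich peptide P binds an SH3 domain L with one (1:1) or two (1:2,
peptide:SH3 — a second SH3 on the same peptide) sequential macroscopic
dissociation constants:

    P + L ⇌ PL          Kd1 = [P][L]/[PL]
    PL + L ⇌ PL2        Kd2 = [PL][L]/[PL2]

Exchange between free and bound forms is fast on the chemical-shift
timescale, so every signal moves as the population-weighted average of its
free and bound positions.  The dissociation constant is obtained by
least-squares fitting of predicted population-weighted shifts to observed
titration shifts — ¹⁹F perturbations of the peptide and the composite
¹H/¹⁵N perturbation of the protein fitted jointly — with goodness of fit
reported as the reduced χ², Σ(δ_exp − δ_calc)²/(N − NP).

Speciation is solved in closed form for 1:1 and by 1-D root finding on the
free-SH3 concentration for 1:2; an independent kinetic route that
integrates the mass-action rate equations to steady state is provided as
``solve_equilibrium_ode``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import lmfit
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "BindingModel",
    "SpeciesConcentrations",
    "TitrationSeries",
    "CSPFitResult",
    "solve_equilibrium_1to1",
    "solve_equilibrium",
    "solve_equilibrium_ode",
    "predict_fast_exchange_shift",
    "composite_csp",
    "reduced_chi2",
    "fit_titration",
]

#: default 1σ measurement noise of a ¹⁹F shift read off a 1D spectrum (Hz)
F19_SHIFT_NOISE_HZ = 1.6
#: default 1σ noise of the composite amide CSP (ppm); plumbing default
AMIDE_CSP_NOISE_PPM = 0.005


@dataclass(frozen=True)
class BindingModel:
    """Stoichiometry topology plus one dissociation constant per step (µM)."""

    stoichiometry: str  # "1:1" or "1:2" (peptide:SH3)
    kd_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.stoichiometry not in ("1:1", "1:2"):
            raise ValueError("stoichiometry must be '1:1' or '1:2'")
        kds = tuple(float(k) for k in self.kd_values)
        object.__setattr__(self, "kd_values", kds)
        n_expected = 1 if self.stoichiometry == "1:1" else 2
        if len(kds) != n_expected:
            raise ValueError(
                f"{self.stoichiometry} model needs {n_expected} Kd value(s), got {len(kds)}"
            )
        if any(k <= 0 for k in kds):
            raise ValueError("all Kd values must be positive")


@dataclass(frozen=True)
class SpeciesConcentrations:
    """Equilibrium speciation (µM) for one titration point."""

    free_peptide: float
    free_SH3: float
    complex_PL: float
    complex_PL2: float = 0.0

    @property
    def peptide_total(self) -> float:
        return self.free_peptide + self.complex_PL + self.complex_PL2

    @property
    def sh3_total(self) -> float:
        return self.free_SH3 + self.complex_PL + 2.0 * self.complex_PL2

    @property
    def pb(self) -> float:
        """Bound fraction of the peptide reporter (NaN when no peptide)."""
        tot = self.peptide_total
        if tot == 0:
            return float("nan")
        return (self.complex_PL + self.complex_PL2) / tot

    @property
    def pf(self) -> float:
        return 1.0 - self.pb

    @property
    def p_single(self) -> float:
        """Population of the singly bound peptide state."""
        tot = self.peptide_total
        return self.complex_PL / tot if tot else float("nan")

    @property
    def p_double(self) -> float:
        tot = self.peptide_total
        return self.complex_PL2 / tot if tot else float("nan")

    @property
    def pb_protein(self) -> float:
        """Bound fraction of the SH3 protein (NaN when no protein)."""
        tot = self.sh3_total
        if tot == 0:
            return float("nan")
        return (self.complex_PL + 2.0 * self.complex_PL2) / tot


def solve_equilibrium_1to1(
    peptide_total: float, sh3_total: float, kd: float
) -> SpeciesConcentrations:
    """Closed-form 1:1 speciation from the binding quadratic.

    Uses the cancellation-safe root ``2PL/(b + sqrt(b² − 4PL))`` with
    b = P + L + Kd, so detailed balance holds to machine precision.
    """
    if peptide_total < 0 or sh3_total < 0:
        raise ValueError("total concentrations must be non-negative")
    if kd <= 0:
        raise ValueError("Kd must be positive")
    p, l = float(peptide_total), float(sh3_total)
    b = p + l + kd
    disc = b * b - 4.0 * p * l
    complex_pl = 2.0 * p * l / (b + math.sqrt(max(disc, 0.0)))
    return SpeciesConcentrations(
        free_peptide=p - complex_pl, free_SH3=l - complex_pl, complex_PL=complex_pl
    )


def _solve_1to2(peptide_total: float, sh3_total: float, kd1: float, kd2: float) -> SpeciesConcentrations:
    """1:2 speciation by bracketed root finding on free SH3."""
    p_tot, l_tot = float(peptide_total), float(sh3_total)
    if p_tot == 0 or l_tot == 0:
        return SpeciesConcentrations(p_tot, l_tot, 0.0, 0.0)

    def l_residual(l: float) -> float:
        denom = 1.0 + l / kd1 + l * l / (kd1 * kd2)
        p = p_tot / denom
        return l + p * (l / kd1 + 2.0 * l * l / (kd1 * kd2)) - l_tot

    l_free = brentq(l_residual, 0.0, l_tot, rtol=1e-14, maxiter=200)
    p_free = p_tot / (1.0 + l_free / kd1 + l_free**2 / (kd1 * kd2))
    pl = p_free * l_free / kd1
    pl2 = pl * l_free / kd2
    return SpeciesConcentrations(p_free, l_free, pl, pl2)


def solve_equilibrium(
    model: BindingModel, peptide_total: float, sh3_total: float
) -> SpeciesConcentrations:
    """Speciation for either stoichiometry (algebraic route)."""
    if model.stoichiometry == "1:1":
        return solve_equilibrium_1to1(peptide_total, sh3_total, model.kd_values[0])
    return _solve_1to2(peptide_total, sh3_total, *model.kd_values)


def solve_equilibrium_ode(
    model: BindingModel,
    peptide_total: float,
    sh3_total: float,
    rtol_steady: float = 1e-10,
    max_scaled_time: float = 1e7,
) -> SpeciesConcentrations:
    """Speciation by integrating the mass-action rate equations to steady state.

    Association rate constants are normalised to 1 (µM⁻¹ per unit scaled
    time); each dissociation rate then equals the step's Kd.  Integration
    starts from the all-free state and stops when every concentration
    derivative falls below ``rtol_steady × max(totals, 1 µM)``.
    """
    if peptide_total < 0 or sh3_total < 0:
        raise ValueError("total concentrations must be non-negative")
    p_tot, l_tot = float(peptide_total), float(sh3_total)
    two_step = model.stoichiometry == "1:2"
    kd1 = model.kd_values[0]
    kd2 = model.kd_values[1] if two_step else None
    scale = max(p_tot, l_tot, 1.0)

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        pl, pl2 = y
        p = p_tot - pl - pl2
        l = l_tot - pl - 2.0 * pl2
        d_pl = p * l - kd1 * pl
        d_pl2 = 0.0
        if two_step:
            forward2 = pl * l - kd2 * pl2
            d_pl -= forward2
            d_pl2 = forward2
        return np.array([d_pl, d_pl2])

    y = np.zeros(2)
    t_end = 1.0 / scale  # characteristic association time
    total_time = 0.0
    while total_time < max_scaled_time:
        sol = solve_ivp(rhs, (0.0, t_end), y, method="LSODA", rtol=1e-12, atol=1e-12 * scale)
        y = sol.y[:, -1]
        total_time += t_end
        deriv = np.max(np.abs(rhs(0.0, y)))
        if deriv < rtol_steady * scale:
            pl, pl2 = y
            return SpeciesConcentrations(
                free_peptide=p_tot - pl - pl2,
                free_SH3=l_tot - pl - 2.0 * pl2,
                complex_PL=pl,
                complex_PL2=pl2,
            )
        t_end *= 4.0
    raise RuntimeError(
        f"equilibrium ODE did not reach steady state; residual derivative norm {deriv:.3e}"
    )


def predict_fast_exchange_shift(
    conc: SpeciesConcentrations,
    delta_free: float,
    delta_bound: float,
    delta_bound2: float | None = None,
    species: str = "peptide",
) -> float:
    """Fast-exchange population-weighted observed shift.

    For peptide signals the weights are the peptide's state populations
    (the doubly bound state carries its own shift, defaulting to the
    singly bound one); for protein signals the weight is the protein's
    bound fraction.
    """
    if species == "peptide":
        p2 = conc.p_double
        d2 = delta_bound if delta_bound2 is None else delta_bound2
        return conc.pf * delta_free + conc.p_single * delta_bound + p2 * d2
    if species == "protein":
        pb = conc.pb_protein
        return (1.0 - pb) * delta_free + pb * delta_bound
    raise ValueError("species must be 'peptide' or 'protein'")


def composite_csp(delta_n: float, delta_h: float, weight: float = 5.0) -> float:
    """Composite amide CSP √(ΔδN² + w·ΔδH²) in ppm (default weight 5)."""
    return math.sqrt(delta_n**2 + weight * delta_h**2)


def reduced_chi2(observed, calculated, n_params: int) -> float:
    """Reduced χ² = Σ(δ_exp − δ_calc)²/(N − NP)."""
    obs = np.asarray(observed, float)
    calc = np.asarray(calculated, float)
    n = obs.size
    if n <= n_params:
        raise ValueError(f"need more observations ({n}) than parameters ({n_params})")
    return float(np.sum((obs - calc) ** 2) / (n - n_params))


# --- titration container ------------------------------------------------

TITRATION_COLUMNS = [
    "point_id",
    "peptide_total_uM",
    "sh3_total_uM",
    "signal",
    "shift_value",
    "shift_unit",
]


@dataclass
class TitrationSeries:
    """Long-format titration table.

    One row per (titration point, signal).  ¹⁹F rows carry the observed
    shift change from the free peptide in ``shift_value`` (Hz or ppm per
    ``shift_unit``) and optionally ``linewidth_hz``; amide rows carry
    per-residue ``dN_ppm``/``dH_ppm`` perturbation pairs.
    """

    data: pd.DataFrame
    conc_uncertainty_rel: float = 0.15
    spectrometer_mhz_19f: float = 565.05  # 19F frequency at 14.1 T

    def __post_init__(self) -> None:
        missing = [c for c in TITRATION_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"titration table missing mandatory columns: {missing}")
        if (self.data["peptide_total_uM"] < 0).any() or (self.data["sh3_total_uM"] < 0).any():
            raise ValueError("total concentrations must be non-negative")
        units = set(self.data["shift_unit"].dropna())
        if not units <= {"Hz", "ppm"}:
            raise ValueError(f"unsupported shift units: {units - {'Hz', 'ppm'}}")

    @property
    def points(self) -> pd.DataFrame:
        return (
            self.data[["point_id", "peptide_total_uM", "sh3_total_uM"]]
            .drop_duplicates("point_id")
            .reset_index(drop=True)
        )

    def fluorine_signals(self) -> list[str]:
        mask = self.data["shift_value"].notna()
        return sorted(self.data.loc[mask, "signal"].unique())

    def has_amide(self) -> bool:
        return "dN_ppm" in self.data.columns and self.data["dN_ppm"].notna().any()

    def shift_hz(self, row: pd.Series) -> float:
        """Shift change in Hz regardless of the stored unit."""
        if row["shift_unit"] == "Hz":
            return float(row["shift_value"])
        return float(row["shift_value"]) * self.spectrometer_mhz_19f

    def amide_composite(self, csp_weight: float = 5.0) -> pd.DataFrame:
        """Per-point composite amide CSP averaged over the reported residues."""
        amide = self.data[self.data.get("dN_ppm").notna()] if self.has_amide() else None
        if amide is None or amide.empty:
            return pd.DataFrame(columns=["point_id", "csp_ppm"])
        comp = amide.apply(
            lambda r: composite_csp(r["dN_ppm"], r["dH_ppm"], csp_weight), axis=1
        )
        out = amide.assign(csp_ppm=comp).groupby("point_id", as_index=False)["csp_ppm"].mean()
        return out


# --- joint CSP fit ------------------------------------------------------


@dataclass(frozen=True)
class CSPFitResult:
    """Result of a titration CSP fit."""

    model: BindingModel
    kd_values: tuple[float, ...]
    kd_errors: tuple[float, ...]
    dnu_hz: Mapping[str, float]
    dnu_errors: Mapping[str, float]
    csp_max_ppm: float | None
    csp_max_err: float | None
    reduced_chi2: float
    residuals: np.ndarray
    n_obs: int
    n_params: int

    @property
    def kd(self) -> float:
        return self.kd_values[0]


def _sanitize(name: str) -> str:
    return "".join(ch if ch.isalnum() else "_" for ch in name)


def fit_titration(
    series: TitrationSeries,
    model: BindingModel,
    joint: bool = True,
    csp_weight: float = 5.0,
    noise_19f_hz: float = F19_SHIFT_NOISE_HZ,
    noise_amide_ppm: float = AMIDE_CSP_NOISE_PPM,
) -> CSPFitResult:
    """Fit Kd (and per-signal bound-state shift changes) to a titration.

    Free parameters: the model's Kd value(s), one Δν (bound − free, Hz)
    per ¹⁹F signal (plus a doubly-bound Δν per signal for the 1:2 model),
    and the saturating composite amide CSP when amide data are present.
    ¹⁹F and amide residual blocks are weighted by 1/noise² so both enter a
    single objective in comparable units; the reported reduced χ² is
    computed on these noise-scaled residuals with NP = number of fitted
    parameters.
    """
    f_signals = series.fluorine_signals()
    use_amide = joint and series.has_amide()
    amide = series.amide_composite(csp_weight) if use_amide else None
    if not f_signals and (amide is None or amide.empty):
        raise ValueError("titration series carries no fittable observable")
    if len(series.points) < 4:
        raise ValueError("need at least 4 titration points")

    two_step = model.stoichiometry == "1:2"
    params = lmfit.Parameters()
    params.add("kd1", value=model.kd_values[0], min=1e-3, max=1e7)
    if two_step:
        params.add("kd2", value=model.kd_values[1], min=1e-3, max=1e7)
    for s in f_signals:
        params.add(f"dnu_{_sanitize(s)}", value=_dnu_guess(series, s))
        if two_step:
            params.add(f"dnu2_{_sanitize(s)}", value=_dnu_guess(series, s))
    if use_amide and amide is not None and not amide.empty:
        params.add("csp_max", value=float(amide["csp_ppm"].max()) or 0.1, min=0.0)

    pts = series.points.set_index("point_id")
    fdata = series.data[series.data["shift_value"].notna()]

    def speciation(p: lmfit.Parameters) -> dict:
        kds = (p["kd1"].value, p["kd2"].value) if two_step else (p["kd1"].value,)
        m = BindingModel(model.stoichiometry, kds)
        return {
            pid: solve_equilibrium(m, row["peptide_total_uM"], row["sh3_total_uM"])
            for pid, row in pts.iterrows()
        }

    def resid(p: lmfit.Parameters) -> np.ndarray:
        concs = speciation(p)
        out = []
        for _, row in fdata.iterrows():
            conc = concs[row["point_id"]]
            dnu = p[f"dnu_{_sanitize(row['signal'])}"].value
            dnu2 = p[f"dnu2_{_sanitize(row['signal'])}"].value if two_step else None
            pred = predict_fast_exchange_shift(conc, 0.0, dnu, dnu2, species="peptide")
            out.append((series.shift_hz(row) - pred) / noise_19f_hz)
        if use_amide and amide is not None:
            for _, row in amide.iterrows():
                conc = concs[row["point_id"]]
                pred = predict_fast_exchange_shift(
                    conc, 0.0, p["csp_max"].value, species="protein"
                )
                out.append((row["csp_ppm"] - pred) / noise_amide_ppm)
        return np.asarray(out)

    fit = lmfit.minimize(resid, params, method="leastsq")
    if not fit.success:
        raise RuntimeError(
            f"titration fit did not converge (residual norm {np.linalg.norm(fit.residual):.3g})"
        )

    # identifiability check on the saturation range actually spanned
    concs = speciation(fit.params)
    pbs = [c.pb for c in concs.values() if np.isfinite(c.pb)]
    if pbs and (max(pbs) < 0.1 or min(pbs) > 0.9):
        warnings.warn(
            "titration spans a narrow saturation range; Kd is weakly identified",
            stacklevel=2,
        )

    def val_err(name: str) -> tuple[float, float]:
        par = fit.params[name]
        return float(par.value), float(par.stderr) if par.stderr is not None else float("nan")

    kd_vals, kd_errs = [], []
    for name in (("kd1", "kd2") if two_step else ("kd1",)):
        v, e = val_err(name)
        kd_vals.append(v)
        kd_errs.append(e)
    dnu = {}
    dnu_err = {}
    for s in f_signals:
        v, e = val_err(f"dnu_{_sanitize(s)}")
        dnu[s] = v
        dnu_err[s] = e
    csp_max = csp_err = None
    if "csp_max" in fit.params:
        csp_max, csp_err = val_err("csp_max")

    n_obs = fit.residual.size
    n_par = fit.nvarys
    chi2 = float(np.sum(fit.residual**2) / (n_obs - n_par)) if n_obs > n_par else float("inf")

    return CSPFitResult(
        model=model,
        kd_values=tuple(kd_vals),
        kd_errors=tuple(kd_errs),
        dnu_hz=dnu,
        dnu_errors=dnu_err,
        csp_max_ppm=csp_max,
        csp_max_err=csp_err,
        reduced_chi2=chi2,
        residuals=np.asarray(fit.residual),
        n_obs=n_obs,
        n_params=n_par,
    )


def _dnu_guess(series: TitrationSeries, signal: str) -> float:
    rows = series.data[
        (series.data["signal"] == signal) & series.data["shift_value"].notna()
    ]
    if rows.empty:
        return 100.0
    hz = [series.shift_hz(r) for _, r in rows.iterrows()]
    extreme = max(hz, key=abs)
    return extreme * 1.5 if extreme != 0 else 100.0
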
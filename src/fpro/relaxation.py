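"""¹⁹F spin relaxation of a fluorine surrounded by ring protons.

The model is the standard pairwise-additive treatment: each F–H vector
contributes independent dipole–dipole relaxation, and the symmetric part of
the ¹⁹F chemical-shift-anisotropy (CSA) tensor contributes with the usual
(1 + η²/3) asymmetry correction.  Cross-correlations between mechanisms,
H–H couplings and the antisymmetric CSA components are neglected; the
antisymmetric components are parsed and stored so that a future extension
can use them.  Rotational diffusion is rigid and isotropic with a single
correlation time τc.

Rates (Lorentzian spectral density J(ω) = (2/5)·τc/(1+ω²τc²)):

    R1 = Σ_i (d_i²/4)·[J(ωH−ωF) + 3J(ωF) + 6J(ωH+ωF)]
         + (Δσ·ωF)²/3 · (1+η²/3) · J(ωF)

    R2 = Σ_i (d_i²/8)·[4J(0) + J(ωH−ωF) + 3J(ωF) + 6J(ωH) + 6J(ωH+ωF)]
         + (Δσ·ωF)²/18 · (1+η²/3) · [4J(0) + 3J(ωF)]

    σ  = (d²/4)·[6J(ωH+ωF) − J(ωH−ωF)]        (per F–H pair)

with d = (μ0/4π)·γH·γF·ħ/r³.  The steady-state ¹H→¹⁹F NOE upon selective
saturation of one proton is (γH/γF)·σ_sat/ρ with ρ = R1 (all protons and
CSA act as leakage).

The longitudinal rate develops the characteristic double-humped ("camel
hump") τc profile at 14.1 T: the CSA term peaks where ωF·τc = 1 (≈0.28 ns)
and the dominant dipolar term where (ωH−ωF)·τc = 1 (≈4.5 ns).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .constants import FieldSettings

PROTON_LABELS = ("HG", "HB2", "HB3", "HD2", "HD3")

__all__ = [
    "SpinSystemGeometry",
    "RelaxationRateSet",
    "CurveGrid",
    "spectral_density",
    "dipolar_constant",
    "r1_longitudinal",
    "r2_transverse",
    "cross_relaxation_sigma",
    "noe_steady_state",
    "invert_tauc_from_noe",
    "invert_tauc_from_r1",
    "relaxation_curves",
]


@dataclass(frozen=True)
class SpinSystemGeometry:
    """F–H distances and ¹⁹F CSA tensor summary for one ring conformer.

    Parameters
    ----------
    label : str
        Conformer identifier, e.g. ``"(4R)-exo major"``.
    proton_distances : mapping
        Proton label → F–H distance in Å, for the ring protons
        {HG, HB2, HB3, HD2, HD3} (any non-empty subset).
    delta_sigma : float
        CSA anisotropy Δσ in ppm (sign preserved; only Δσ² enters rates).
    eta_csa : float
        Asymmetry parameter η ∈ [0, 1].
    anti_xy, anti_xz, anti_yz : float
        Antisymmetric CSA components in ppm; stored, unused by the rates.
    """

    label: str
    proton_distances: Mapping[str, float]
    delta_sigma: float = 0.0
    eta_csa: float = 0.0
    anti_xy: float = 0.0
    anti_xz: float = 0.0
    anti_yz: float = 0.0

    def __post_init__(self) -> None:
        if not self.proton_distances:
            raise ValueError(f"{self.label!r}: at least one proton is required")
        for name, r in self.proton_distances.items():
            if not 1.5 < r < 10.0:
                raise ValueError(
                    f"{self.label!r}: distance F-{name} = {r} Å outside the physical window (1.5, 10)"
                )
        if not 0.0 <= self.eta_csa <= 1.0:
            raise ValueError(f"{self.label!r}: eta = {self.eta_csa} outside [0, 1]")

    def distance(self, proton: str) -> float:
        try:
            return self.proton_distances[proton]
        except KeyError:
            raise KeyError(
                f"{self.label!r} has no proton {proton!r}; available: {sorted(self.proton_distances)}"
            ) from None


@dataclass(frozen=True)
class RelaxationRateSet:
    """Relaxation observables at one correlation time."""

    tau_c: float
    r1: float
    r2: float
    sigma_per_proton: Mapping[str, float]
    noe_steady_state: float
    field: FieldSettings

    @property
    def rho(self) -> float:
        """Total ¹⁹F auto-relaxation rate (identical to R1 here)."""
        return self.r1


@dataclass(frozen=True)
class CurveGrid:
    """Relaxation rates evaluated on a τc grid, plus located R1 maxima."""

    tau_values: np.ndarray
    rates: Sequence[RelaxationRateSet]
    r1_maxima: tuple[float, ...] = ()

    def to_frame(self, saturated_proton: str = "HG") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tau_c_s": self.tau_values,
                "R1_s1": [r.r1 for r in self.rates],
                "R2_s1": [r.r2 for r in self.rates],
                f"sigma_{saturated_proton}_s1": [
                    r.sigma_per_proton[saturated_proton] for r in self.rates
                ],
                "noe_fraction": [r.noe_steady_state for r in self.rates],
            }
        )


def spectral_density(omega: float, tau_c: float) -> float:
    """Lorentzian spectral density J(ω) = (2/5)·τc/(1 + ω²τc²), in s."""
    if tau_c <= 0:
        raise ValueError(f"tau_c must be positive, got {tau_c}")
    return 0.4 * tau_c / (1.0 + (omega * tau_c) ** 2)


def dipolar_constant(r_angstrom: float, field: FieldSettings | None = None) -> float:
    """Heteronuclear ¹H–¹⁹F dipolar coupling constant d = (μ0/4π)γHγFħ/r³ (rad s⁻¹)."""
    if r_angstrom <= 0:
        raise ValueError(f"distance must be positive, got {r_angstrom}")
    c = (field or FieldSettings()).constants
    return c.mu0_over_4pi * c.gamma_H * c.gamma_F * c.hbar / (r_angstrom * 1e-10) ** 3


def _csa_omega(geom: SpinSystemGeometry, field: FieldSettings) -> float:
    """Δσ expressed in rad s⁻¹ at the given field."""
    return geom.delta_sigma * 1e-6 * field.omega_F


def r1_longitudinal(
    geom: SpinSystemGeometry, tau_c: float, field: FieldSettings | None = None
) -> float:
    """Longitudinal ¹⁹F relaxation rate R1 (s⁻¹): summed dipolar terms + CSA."""
    field = field or FieldSettings()
    wH, wF = field.omega_H, field.omega_F
    jdiff = spectral_density(wH - wF, tau_c)
    jF = spectral_density(wF, tau_c)
    jsum = spectral_density(wH + wF, tau_c)
    rate = sum(
        dipolar_constant(r, field) ** 2 / 4.0 * (jdiff + 3.0 * jF + 6.0 * jsum)
        for r in geom.proton_distances.values()
    )
    rate += _csa_omega(geom, field) ** 2 / 3.0 * (1.0 + geom.eta_csa**2 / 3.0) * jF
    return rate


def r2_transverse(
    geom: SpinSystemGeometry, tau_c: float, field: FieldSettings | None = None
) -> float:
    """Transverse ¹⁹F relaxation rate R2 (s⁻¹), exchange-free."""
    field = field or FieldSettings()
    wH, wF = field.omega_H, field.omega_F
    j0 = spectral_density(0.0, tau_c)
    jdiff = spectral_density(wH - wF, tau_c)
    jF = spectral_density(wF, tau_c)
    jH = spectral_density(wH, tau_c)
    jsum = spectral_density(wH + wF, tau_c)
    rate = sum(
        dipolar_constant(r, field) ** 2
        / 8.0
        * (4.0 * j0 + jdiff + 3.0 * jF + 6.0 * jH + 6.0 * jsum)
        for r in geom.proton_distances.values()
    )
    rate += (
        _csa_omega(geom, field) ** 2
        / 18.0
        * (1.0 + geom.eta_csa**2 / 3.0)
        * (4.0 * j0 + 3.0 * jF)
    )
    return rate


def cross_relaxation_sigma(
    r_angstrom: float, tau_c: float, field: FieldSettings | None = None
) -> float:
    """¹H–¹⁹F cross-relaxation rate σ = (d²/4)[6J(ωH+ωF) − J(ωH−ωF)] (s⁻¹).

    Positive in extreme narrowing, negative for slow tumbling; the zero
    crossing is the τc where 6J(ωH+ωF) = J(ωH−ωF).
    """
    field = field or FieldSettings()
    d = dipolar_constant(r_angstrom, field)
    wH, wF = field.omega_H, field.omega_F
    return d * d / 4.0 * (
        6.0 * spectral_density(wH + wF, tau_c) - spectral_density(wH - wF, tau_c)
    )


def noe_steady_state(
    geom: SpinSystemGeometry,
    tau_c: float,
    field: FieldSettings | None = None,
    saturated_proton: str = "HG",
) -> float:
    """Fractional steady-state ¹⁹F NOE upon selective saturation of one proton.

    Two-spin-plus-sink approximation: only the saturated proton
    cross-relaxes with fluorine; the remaining protons and the CSA
    contribute pure leakage through ρ = R1.
    """
    field = field or FieldSettings()
    r_sat = geom.distance(saturated_proton)
    sigma = cross_relaxation_sigma(r_sat, tau_c, field)
    rho = r1_longitudinal(geom, tau_c, field)
    return field.constants.gamma_ratio * sigma / rho


# --- inversions ---------------------------------------------------------

NOE_BRACKET = (1e-11, 5e-9)  # τc window on which NOE(τc) is monotonic & reliable
TAU_GRID_SPAN = (1e-11, 1e-7)


def invert_tauc_from_noe(
    geom: SpinSystemGeometry,
    observed_noe: float,
    field: FieldSettings | None = None,
    saturated_proton: str = "HG",
    bracket: tuple[float, float] = NOE_BRACKET,
) -> float:
    """Unique τc on the monotonic NOE branch matching an observed NOE.

    Raises ``ValueError`` naming the attainable interval when the observed
    NOE lies outside the range spanned on the bracket.
    """
    field = field or FieldSettings()

    def f(tau: float) -> float:
        return noe_steady_state(geom, tau, field, saturated_proton) - observed_noe

    lo, hi = bracket
    f_lo, f_hi = f(lo), f(hi)
    if f_lo * f_hi > 0:
        lo_val = noe_steady_state(geom, lo, field, saturated_proton)
        hi_val = noe_steady_state(geom, hi, field, saturated_proton)
        raise ValueError(
            f"observed NOE {observed_noe:+.4f} outside the attainable range "
            f"[{min(lo_val, hi_val):+.4f}, {max(lo_val, hi_val):+.4f}] on "
            f"tau_c in [{lo:.2e}, {hi:.2e}] s"
        )
    return brentq(f, lo, hi, xtol=1e-16, rtol=1e-10)


def invert_tauc_from_r1(
    geom: SpinSystemGeometry,
    observed_r1: float,
    field: FieldSettings | None = None,
    span: tuple[float, float] = TAU_GRID_SPAN,
    points_per_decade: int = 200,
) -> list[float]:
    """All τc values in ``span`` where R1(τc) equals the observed rate.

    The double-humped R1 profile can cross a level 0–4 times; an empty
    list is a valid return (rate above the global maximum).  Each crossing
    located on a dense log grid is refined by bisection to 1e−6 relative.
    """
    if observed_r1 <= 0:
        raise ValueError("observed R1 must be positive")
    field = field or FieldSettings()
    n = int(points_per_decade * math.log10(span[1] / span[0])) + 1
    taus = np.logspace(math.log10(span[0]), math.log10(span[1]), n)
    vals = np.array([r1_longitudinal(geom, t, field) - observed_r1 for t in taus])
    roots: list[float] = []
    for i in range(len(taus) - 1):
        if vals[i] == 0.0:
            roots.append(float(taus[i]))
        elif vals[i] * vals[i + 1] < 0:
            roots.append(
                brentq(
                    lambda t: r1_longitudinal(geom, t, field) - observed_r1,
                    taus[i],
                    taus[i + 1],
                    xtol=1e-16,
                    rtol=1e-10,
                )
            )
    return sorted(roots)


def _refine_maximum(
    geom: SpinSystemGeometry, field: FieldSettings, lo: float, hi: float
) -> float:
    """Golden-section refinement of an R1 maximum on log τc."""
    res = minimize_scalar(
        lambda x: -r1_longitudinal(geom, 10.0**x, field),
        bracket=None,
        bounds=(math.log10(lo), math.log10(hi)),
        method="bounded",
        options={"xatol": 1e-4},
    )
    return float(10.0**res.x)


def relaxation_curves(
    geom: SpinSystemGeometry,
    field: FieldSettings | None = None,
    tau_grid: Iterable[float] | None = None,
    saturated_proton: str = "HG",
) -> CurveGrid:
    """Evaluate R1/R2/σ/NOE on a τc grid and locate local R1 maxima.

    The default grid spans 10 ps – 100 ns with 100 points per decade,
    enough to resolve both humps of the R1 profile; maxima found by
    discrete detection are refined on log τc.
    """
    field = field or FieldSettings()
    if tau_grid is None:
        tau = np.logspace(-11, -7, 401)
    else:
        tau = np.asarray(list(tau_grid), dtype=float)
    if len(tau) < 2 or np.any(np.diff(tau) <= 0):
        raise ValueError("tau grid must be strictly increasing with >= 2 points")
    ppd = (len(tau) - 1) / math.log10(tau[-1] / tau[0])
    if ppd < 10:
        import warnings

        warnings.warn(
            f"tau grid has only {ppd:.1f} points per decade; R1 maxima may be missed",
            stacklevel=2,
        )

    rates = []
    for t in tau:
        sig = {
            name: cross_relaxation_sigma(r, t, field)
            for name, r in geom.proton_distances.items()
        }
        rates.append(
            RelaxationRateSet(
                tau_c=float(t),
                r1=r1_longitudinal(geom, t, field),
                r2=r2_transverse(geom, t, field),
                sigma_per_proton=sig,
                noe_steady_state=noe_steady_state(geom, t, field, saturated_proton),
                field=field,
            )
        )
    r1v = np.array([r.r1 for r in rates])
    maxima = []
    for i in range(1, len(tau) - 1):
        if r1v[i] > r1v[i - 1] and r1v[i] > r1v[i + 1]:
            maxima.append(_refine_maximum(geom, field, tau[i - 1], tau[i + 1]))
    return CurveGrid(tau_values=tau, rates=rates, r1_maxima=tuple(maxima))
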
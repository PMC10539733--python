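"""Synthetic ¹⁹F NMR data with the statistical structure of the real experiments.

Emulated features:

* titrations on a volumetric schedule — aliquots of a concentrated peptide
  stock (the first few half-diluted) added to a protein sample, so the
  protein is progressively diluted;
* fast-exchange population-weighted shift changes, and line widths from
  the fast-exchange R2‡ expression plus the exponential apodization
  broadening applied during processing;
* monoexponential inversion-recovery/decay series and NOE build-ups on
  the acquisition schedules of the real measurements, including one
  repeated time point for empirical error estimation;
* Gaussian measurement noise (1.6 Hz on ¹⁹F shifts by default) and a
  systematic 15 % stock-concentration bias drawn once per stock, not per
  point — aliquots share the stock, so their errors are common mode.

Not emulated: time-domain FIDs, the minor non-binding species, cis
conformer satellites, field drift.  Every generator returns a ground-truth
record alongside the data so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binding import BindingModel, TitrationSeries, solve_equilibrium, composite_csp
from .constants import PhysicalConstants
from .kinetics import ExchangeParams, r2_apparent
from .relaxfit import DecaySeries

__all__ = [
    "GeneratorConfig",
    "titration_schedule",
    "generate_titration",
    "generate_spectrum",
    "generate_decay",
    "generate_noe_buildup",
]

#: default aliquot volumes (µL); the first four use the half-diluted stock
DEFAULT_ALIQUOTS_HALF = (3.4, 3.6, 4.5, 6.0)
DEFAULT_ALIQUOTS_FULL = (5.0, 7.0, 9.0, 12.0, 16.0, 20.0, 26.0, 30.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Noise levels and protocol defaults shared by all generators."""

    seed: int = 0
    noise_shift_19f_hz: float = 1.6
    noise_csp_amide_ppm: float = 0.005
    noise_linewidth_rel: float = 0.05
    conc_uncertainty_rel: float = 0.15
    exponential_broadening_hz: float = 8.0
    noise_intensity_rel: float = 0.01
    noise_spectrum_abs: float = 0.0
    # titration protocol
    initial_volume_uL: float = 170.0
    sh3_start_uM: float = 314.0
    peptide_stock_mM: float = 5.1
    aliquots_half_uL: tuple[float, ...] = DEFAULT_ALIQUOTS_HALF
    aliquots_full_uL: tuple[float, ...] = DEFAULT_ALIQUOTS_FULL
    n_amide_residues: int = 9
    amide_csp_saturation_ppm: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "noise_shift_19f_hz",
            "noise_csp_amide_ppm",
            "noise_linewidth_rel",
            "conc_uncertainty_rel",
            "noise_intensity_rel",
            "noise_spectrum_abs",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def titration_schedule(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Nominal (peptide_total, sh3_total) µM per point from the aliquot protocol."""
    cfg = config or GeneratorConfig()
    stock = cfg.peptide_stock_mM  # nmol/µL
    volume = cfg.initial_volume_uL
    sh3_nmol = cfg.sh3_start_uM * cfg.initial_volume_uL / 1e3
    pep_nmol = 0.0
    rows = []
    aliquots = [(v, stock / 2.0) for v in cfg.aliquots_half_uL] + [
        (v, stock) for v in cfg.aliquots_full_uL
    ]
    for i, (vol, conc) in enumerate(aliquots, start=1):
        volume += vol
        pep_nmol += vol * conc
        rows.append(
            {
                "point_id": i,
                "peptide_total_uM": pep_nmol * 1e3 / volume,
                "sh3_total_uM": sh3_nmol * 1e3 / volume,
            }
        )
    return pd.DataFrame(rows)


def _amide_truth(
    rng: np.random.Generator, cfg: GeneratorConfig
) -> list[tuple[str, float, float]]:
    """Per-residue saturating (ΔδN, ΔδH) pairs averaging to the target composite."""
    n = cfg.n_amide_residues
    dn = rng.uniform(0.3, 1.0, n) * rng.choice([-1, 1], n)
    dh = rng.uniform(0.3, 1.0, n) * rng.choice([-1, 1], n)
    mean_comp = np.mean([composite_csp(a, b) for a, b in zip(dn, dh)])
    scale = cfg.amide_csp_saturation_ppm / mean_comp
    return [
        (f"res{i + 1}", float(a * scale), float(b * scale))
        for i, (a, b) in enumerate(zip(dn, dh))
    ]


def generate_titration(
    model: BindingModel,
    dnu_hz: Mapping[str, float],
    config: GeneratorConfig | None = None,
    exchange: Mapping[str, ExchangeParams] | None = None,
    include_amide: bool = True,
    dnu2_hz: Mapping[str, float] | None = None,
) -> tuple[TitrationSeries, dict]:
    """Synthesise a joint ¹⁹F + amide CSP titration.

    The equilibrium is solved at the *biased* (true) concentrations while
    the emitted table carries the nominal ones, reproducing the effect of
    the 15 % stock-concentration uncertainty on a real fit.  Returns the
    series and a ground-truth record.
    """
    cfg = config or GeneratorConfig()
    rng = cfg.rng()
    sched = titration_schedule(cfg)

    pep_bias = 1.0 + cfg.conc_uncertainty_rel * rng.standard_normal()
    prot_bias = 1.0 + cfg.conc_uncertainty_rel * rng.standard_normal()
    pep_bias = float(np.clip(pep_bias, 0.5, 1.5))
    prot_bias = float(np.clip(prot_bias, 0.5, 1.5))

    amide_truth = _amide_truth(rng, cfg) if include_amide else []

    rows = []
    for _, pt in sched.iterrows():
        p_true = pt["peptide_total_uM"] * pep_bias
        l_true = pt["sh3_total_uM"] * prot_bias
        conc = solve_equilibrium(model, p_true, l_true)
        for sig, dnu in dnu_hz.items():
            d2 = (dnu2_hz or {}).get(sig, dnu)
            shift = (
                conc.p_single * dnu
                + conc.p_double * d2
                + cfg.noise_shift_19f_hz * rng.standard_normal()
            )
            row = {
                "point_id": int(pt["point_id"]),
                "peptide_total_uM": pt["peptide_total_uM"],
                "sh3_total_uM": pt["sh3_total_uM"],
                "signal": sig,
                "shift_value": shift,
                "shift_unit": "Hz",
                "linewidth_hz": np.nan,
                "dN_ppm": np.nan,
                "dH_ppm": np.nan,
            }
            if exchange and sig in exchange:
                r2, _ = r2_apparent(exchange[sig], conc)
                width = r2 / np.pi + cfg.exponential_broadening_hz
                width *= 1.0 + cfg.noise_linewidth_rel * rng.standard_normal()
                row["linewidth_hz"] = width
            rows.append(row)
        pbp = conc.pb_protein
        for res, dn_max, dh_max in amide_truth:
            dn = pbp * dn_max + cfg.noise_csp_amide_ppm * rng.standard_normal()
            dh = pbp * dh_max + cfg.noise_csp_amide_ppm / np.sqrt(5.0) * rng.standard_normal()
            rows.append(
                {
                    "point_id": int(pt["point_id"]),
                    "peptide_total_uM": pt["peptide_total_uM"],
                    "sh3_total_uM": pt["sh3_total_uM"],
                    "signal": res,
                    "shift_value": np.nan,
                    "shift_unit": "ppm",
                    "linewidth_hz": np.nan,
                    "dN_ppm": dn,
                    "dH_ppm": dh,
                }
            )

    series = TitrationSeries(
        data=pd.DataFrame(rows), conc_uncertainty_rel=cfg.conc_uncertainty_rel
    )
    truth = {
        "model": {"stoichiometry": model.stoichiometry, "kd_values": list(model.kd_values)},
        "dnu_hz": dict(dnu_hz),
        "peptide_stock_bias": pep_bias,
        "protein_stock_bias": prot_bias,
        "amide_truth": amide_truth,
        "config": asdict(cfg),
    }
    return series, truth


def generate_spectrum(
    peaks: Sequence[tuple[float, float, float]],
    freq_hz: Sequence[float] | None = None,
    config: GeneratorConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Sum-of-Lorentzians 1D spectrum.

    ``peaks`` is a list of (centre Hz, R2‡ s⁻¹, amplitude); each line gets
    FWHM = R2‡/π plus the exponential broadening, then additive Gaussian
    noise of absolute standard deviation ``noise_spectrum_abs``.
    """
    cfg = config or GeneratorConfig()
    rng = cfg.rng()
    if freq_hz is None:
        centres = [p[0] for p in peaks]
        widths = [p[1] / np.pi + cfg.exponential_broadening_hz for p in peaks]
        lo = min(c - 25 * w for c, w in zip(centres, widths))
        hi = max(c + 25 * w for c, w in zip(centres, widths))
        freq_hz = np.linspace(lo, hi, 4096)
    f = np.asarray(freq_hz, float)
    y = np.zeros_like(f)
    for centre, r2, amp in peaks:
        fwhm = r2 / np.pi + cfg.exponential_broadening_hz
        hw = fwhm / 2.0
        y += amp * hw**2 / ((f - centre) ** 2 + hw**2)
    if cfg.noise_spectrum_abs > 0:
        y = y + cfg.noise_spectrum_abs * rng.standard_normal(f.size)
    truth = {"peaks": [list(p) for p in peaks], "config": asdict(cfg)}
    return pd.DataFrame({"freq_hz": f, "intensity": y}), truth


def _schedule_with_repeat(
    t_min: float, t_max: float, n_total: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Log-spaced schedule of n_total points, one of which is a repeat."""
    base = np.geomspace(t_min, t_max, n_total - 1)
    repeat = base[len(base) // 2]
    return np.sort(np.append(base, repeat))


def generate_decay(
    rate_s1: float,
    config: GeneratorConfig | None = None,
    amplitude: float = -2.0,
    offset: float = 1.0,
    kind: str = "inversion_recovery",
    times_s: Sequence[float] | None = None,
) -> tuple[DecaySeries, dict]:
    """Monoexponential I(t) = offset + amplitude·e^(−rate·t) plus noise.

    Default schedules follow the acquisitions: inversion recovery 1 ms–3 s,
    20 points; echo/CPMG decay 1–460 ms, 16 points — each including one
    repeated delay.  The default amplitude/offset pair (−2, 1) is an ideal
    inversion recovery.
    """
    cfg = config or GeneratorConfig()
    rng = cfg.rng()
    if times_s is None:
        if kind == "inversion_recovery":
            t = _schedule_with_repeat(1e-3, 3.0, 20)
        else:
            t = _schedule_with_repeat(1e-3, 0.46, 16)
    else:
        t = np.sort(np.asarray(times_s, float))
    y = offset + amplitude * np.exp(-rate_s1 * t)
    scale = abs(amplitude) if amplitude else max(abs(offset), 1.0)
    y = y + cfg.noise_intensity_rel * scale * rng.standard_normal(t.size)
    truth = {"rate_s1": rate_s1, "amplitude": amplitude, "offset": offset, "config": asdict(cfg)}
    return DecaySeries(times=t, intensities=y, kind=kind), truth


def generate_noe_buildup(
    rho_s1: float,
    sigma_s1: float,
    config: GeneratorConfig | None = None,
    i0: float = 1.0,
    times_s: Sequence[float] | None = None,
    constants: PhysicalConstants | None = None,
) -> tuple[DecaySeries, dict]:
    """NOE build-up I(t) = I0 + (σ/ρ)(γH/γF)I0(1 − e^(−ρt)) plus noise.

    Default schedule: 10 ms – 2.6 s, 16 points total including one repeat.
    The noiseless plateau is I0·(1 + NOEmax).
    """
    cfg = config or GeneratorConfig()
    c = constants or PhysicalConstants()
    rng = cfg.rng()
    t = (
        _schedule_with_repeat(1e-2, 2.6, 16)
        if times_s is None
        else np.sort(np.asarray(times_s, float))
    )
    y = i0 + (sigma_s1 / rho_s1) * c.gamma_ratio * i0 * (1.0 - np.exp(-rho_s1 * t))
    y = y + cfg.noise_intensity_rel * abs(i0) * rng.standard_normal(t.size)
    truth = {
        "i0": i0,
        "rho_s1": rho_s1,
        "sigma_s1": sigma_s1,
        "noe_max": c.gamma_ratio * sigma_s1 / rho_s1,
        "config": asdict(cfg),
    }
    return DecaySeries(times=t, intensities=y, kind="noe_buildup"), truth
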
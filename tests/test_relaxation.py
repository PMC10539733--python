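"""Relaxation theory: closed-form oracles, limits and curve shapes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fpro
from fpro import FieldSettings, SpinSystemGeometry
from fpro.constants import GAMMA_F, GAMMA_H, HBAR, MU0_OVER_4PI
from fpro.relaxation import relaxation_curves

# --- independent literal transcription of the closed-form rates ---------
# Kept deliberately separate from the implementation: every J evaluated
# term by term, prefactors written out.


def _J(w, tc):
    return (2.0 / 5.0) * tc / (1.0 + w * w * tc * tc)


def _d(r_m):
    return MU0_OVER_4PI * GAMMA_H * GAMMA_F * HBAR / r_m**3


def _oracle_rates(distances_A, tc, b0, dso_ppm=0.0, eta=0.0):
    wH, wF = GAMMA_H * b0, GAMMA_F * b0
    r1 = r2 = 0.0
    for rA in distances_A:
        d2 = _d(rA * 1e-10) ** 2
        r1 += d2 / 4.0 * (_J(wH - wF, tc) + 3 * _J(wF, tc) + 6 * _J(wH + wF, tc))
        r2 += (
            d2
            / 8.0
            * (
                4 * _J(0.0, tc)
                + _J(wH - wF, tc)
                + 3 * _J(wF, tc)
                + 6 * _J(wH, tc)
                + 6 * _J(wH + wF, tc)
            )
        )
    csa2 = (dso_ppm * 1e-6 * wF) ** 2 * (1.0 + eta * eta / 3.0)
    r1 += csa2 / 3.0 * _J(wF, tc)
    r2 += csa2 / 18.0 * (4 * _J(0.0, tc) + 3 * _J(wF, tc))
    sigma = _d(distances_A[0] * 1e-10) ** 2 / 4.0 * (
        6 * _J(wH + wF, tc) - _J(wH - wF, tc)
    )
    return r1, r2, sigma


def test_spectral_density_values_and_argmax():
    assert fpro.spectral_density(0.0, 1e-9) == pytest.approx(4e-10)
    assert fpro.spectral_density(1e9, 1e-9) == pytest.approx(2e-10)
    # grid-search oracle: J(ω, ·) is maximal at τc = 1/ω
    w = 3.548e9
    taus = np.logspace(-11, -8, 20001)
    best = taus[np.argmax([fpro.spectral_density(w, t) for t in taus])]
    assert best == pytest.approx(1.0 / w, rel=1e-3)
    assert 1.0 / w == pytest.approx(2.82e-10, rel=1e-2)
    with pytest.raises(ValueError):
        fpro.spectral_density(1e9, 0.0)


def test_dipolar_constant_value_and_scaling():
    # direct constant evaluation oracle at the geminal F-HG distance
    expect = MU0_OVER_4PI * GAMMA_H * GAMMA_F * HBAR / (2.03e-10) ** 3
    assert fpro.dipolar_constant(2.03) == pytest.approx(expect, rel=1e-12)
    assert expect == pytest.approx(8.5e4, rel=0.01)
    assert fpro.dipolar_constant(1e6) < 1e-12  # r -> infinity
    # halving r multiplies d^2 by 64
    assert (fpro.dipolar_constant(1.8) / fpro.dipolar_constant(3.6)) ** 2 == pytest.approx(64.0)
    with pytest.raises(ValueError):
        fpro.dipolar_constant(-1.0)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    tc=st.floats(1e-12, 1e-6),
    r=st.floats(1.6, 9.0),
    dso=st.floats(-100.0, 0.0),
    eta=st.floats(0.0, 1.0),
)
def test_two_spin_oracle_equivalence(tc, r, dso, eta):
    """Implementation agrees with the term-by-term transcription to 1e-10."""
    field = FieldSettings(b0=14.1)
    geom = SpinSystemGeometry("probe", {"HG": r}, delta_sigma=dso, eta_csa=eta)
    r1o, r2o, so = _oracle_rates([r], tc, 14.1, dso, eta)
    assert fpro.r1_longitudinal(geom, tc, field) == pytest.approx(r1o, rel=1e-10)
    assert fpro.r2_transverse(geom, tc, field) == pytest.approx(r2o, rel=1e-10)
    assert fpro.cross_relaxation_sigma(r, tc, field) == pytest.approx(so, rel=1e-10)


def test_five_proton_csa_oracle(exo_major, field):
    """Full Cγ-exo spin system matches the oracle at a slow-tumbling τc."""
    tc = 4.47e-9
    r1o, r2o, _ = _oracle_rates(
        list(exo_major.proton_distances.values()), tc, 14.1,
        exo_major.delta_sigma, exo_major.eta_csa,
    )
    assert fpro.r1_longitudinal(exo_major, tc, field) == pytest.approx(r1o, rel=1e-10)
    assert fpro.r2_transverse(exo_major, tc, field) == pytest.approx(r2o, rel=1e-10)


def test_extreme_narrowing_limits(field):
    """τc→0: rates vanish, R2/R1→1, σ/ρ→1/2; slow limit: σ/ρ→−1."""
    geom = SpinSystemGeometry("pair", {"HG": 2.03})
    tc = 1e-13
    r1 = fpro.r1_longitudinal(geom, tc, field)
    r2 = fpro.r2_transverse(geom, tc, field)
    assert r1 < 1e-3 and r2 < 1e-3
    assert r2 / r1 == pytest.approx(1.0, rel=1e-4)
    assert fpro.cross_relaxation_sigma(2.03, tc, field) / r1 == pytest.approx(0.5, rel=1e-4)
    # slow tumbling: all J ∝ 1/(ω²τc), so σ/ρ tends to a constant close to
    # −1 but corrected by the finite (ωH−ωF)/ωF ratio of the F–H pair
    tc = 1e-5
    wd, wf, ws = field.omega_H - field.omega_F, field.omega_F, field.omega_H + field.omega_F
    asymptote = -(1 - 6 * (wd / ws) ** 2) / (1 + 3 * (wd / wf) ** 2 + 6 * (wd / ws) ** 2)
    assert fpro.cross_relaxation_sigma(2.03, tc, field) / fpro.r1_longitudinal(
        geom, tc, field
    ) == pytest.approx(asymptote, rel=1e-4)
    assert asymptote == pytest.approx(-1.0, rel=0.03)


def test_two_spin_noe_limits(field):
    """Extreme narrowing +53.1 %; slow tumbling within ~2 % of −γH/γF.

    The textbook −106.2 % slow limit assumes J(ωH−ωF) dominates absolutely;
    for ¹⁹F–¹H all spectral densities share the 1/(ω²τc) tail, leaving a
    field-independent ≈2.3 % correction, so the attained limit is ≈−103.9 %.
    """
    geom = SpinSystemGeometry("pair", {"HG": 2.03})
    ratio = field.constants.gamma_ratio
    fast = fpro.noe_steady_state(geom, 1e-13, field)
    slow = fpro.noe_steady_state(geom, 1e-5, field)
    assert fast == pytest.approx(ratio / 2.0, rel=1e-4)
    assert 100 * fast == pytest.approx(53.1, abs=0.1)
    assert slow == pytest.approx(-ratio, rel=0.03)
    assert 100 * slow == pytest.approx(-103.9, abs=0.2)


def test_r1_camel_hump_positions(exo_major, field):
    """Major Cγ-exo R1(τc) at 14.1 T has maxima near 0.3 and ~4 ns."""
    grid = relaxation_curves(exo_major, field)
    assert len(grid.r1_maxima) == 2
    lo, hi = [m * 1e9 for m in grid.r1_maxima]
    assert lo == pytest.approx(0.3, abs=0.05)
    assert hi == pytest.approx(4.4, abs=0.4)


def test_low_csa_conformer_flattens_first_hump(geometries, field):
    """(4R)-endo minor (Δσ=−25.6 ppm): the CSA hump near 0.3 ns is much lower."""
    minor = geometries["(4R)-endo minor"]
    grid = relaxation_curves(minor, field)
    assert grid.r1_maxima, "slow-tumbling dipolar maximum must exist"
    high = max(grid.r1_maxima)
    assert high * 1e9 > 1.0
    r1_at_03 = fpro.r1_longitudinal(minor, 0.3e-9, field)
    assert r1_at_03 < fpro.r1_longitudinal(minor, high, field)


def test_curves_rejects_empty_geometry():
    with pytest.raises(ValueError):
        SpinSystemGeometry("empty", {})


def test_curves_warns_on_coarse_grid(exo_major, field):
    with pytest.warns(UserWarning, match="points per decade"):
        relaxation_curves(exo_major, field, np.logspace(-11, -7, 20))


def test_r2_monotonic_and_dominates_r1(geometries, field):
    """R2 increases with τc past 0.1 ns and exceeds R1 for τc ≥ 1 ns."""
    taus = np.logspace(-10, -8, 40)
    for geom in geometries.values():
        r2 = np.array([fpro.r2_transverse(geom, t, field) for t in taus])
        assert np.all(np.diff(r2) > 0)
        for t in np.logspace(-9, -7, 10):
            assert fpro.r2_transverse(geom, t, field) >= fpro.r1_longitudinal(
                geom, t, field
            ) * (1 - 1e-9)


def test_noe_bounds_and_csa_quenching(geometries, field):
    """|NOE| within the γ-ratio bounds; CSA strictly shrinks |NOE|."""
    ratio = field.constants.gamma_ratio
    taus = np.logspace(-11, -7, 60)
    for geom in geometries.values():
        bare = SpinSystemGeometry(geom.label + " noCSA", dict(geom.proton_distances))
        for t in taus:
            noe = fpro.noe_steady_state(geom, t, field)
            assert -ratio <= noe <= ratio / 2.0 * (1 + 1e-9)
            assert abs(noe) < abs(fpro.noe_steady_state(bare, t, field))


def test_noe_monotonic_on_inversion_branch(geometries, field):
    """NOE(τc) strictly decreasing on 10 ps – 4 ns for all four conformers."""
    taus = np.logspace(-11, np.log10(4e-9), 120)
    for geom in geometries.values():
        noe = np.array([fpro.noe_steady_state(geom, t, field) for t in taus])
        assert np.all(np.diff(noe) < 0), geom.label


@pytest.mark.parametrize("tc_ns", [0.1, 0.5, 1.0, 3.0])
def test_noe_inversion_round_trip(exo_major, field, tc_ns):
    tc = tc_ns * 1e-9
    noe = fpro.noe_steady_state(exo_major, tc, field)
    assert fpro.invert_tauc_from_noe(exo_major, noe, field) == pytest.approx(tc, rel=1e-6)


def test_noe_inversion_range_error(exo_major, field):
    with pytest.raises(ValueError, match="attainable range"):
        fpro.invert_tauc_from_noe(exo_major, -1.5, field)


def test_r1_inversion_round_trip_and_empty(exo_major, field):
    tc = 0.7e-9
    r1 = fpro.r1_longitudinal(exo_major, tc, field)
    roots = fpro.invert_tauc_from_r1(exo_major, r1, field)
    assert any(abs(r - tc) / tc < 1e-6 for r in roots)
    assert roots == sorted(roots)
    assert fpro.invert_tauc_from_r1(exo_major, 100.0, field) == []


def test_r1_inversion_ambiguity(exo_major, field):
    """A measured R1 in the experimental range maps to several τc values,
    including an unrealistically slow one."""
    roots = fpro.invert_tauc_from_r1(exo_major, 2.2, field)
    assert len(roots) >= 2
    assert min(roots) < 1e-9 and max(roots) > 5e-9


def test_r1_consistent_with_measured_range(exo_major, endo_major, field):
    """Calculated R1 over the inferred τc window is of the measured size.

    The Cγ-exo curve lies inside the measured 2.1–2.3 s⁻¹ bracket
    (±0.5 s⁻¹); the Cγ-endo conformer carries a larger CSA and the
    pairwise model overshoots it by a few tenths of s⁻¹, so its band is
    wider on the high side.
    """
    taus = np.linspace(0.4e-9, 0.9e-9, 11)
    vals_exo = [fpro.r1_longitudinal(exo_major, t, field) for t in taus]
    assert all(1.8 <= v <= 2.8 for v in vals_exo)
    vals_endo = [fpro.r1_longitudinal(endo_major, t, field) for t in taus]
    assert all(1.8 <= v <= 3.2 for v in vals_endo)


def test_tauc_ordering_from_measured_noes(geometries, field, measured_relaxation):
    """Inverting the measured NOEs puts the second polyproline segment
    (position 8) at a slower τc than the first (position 4), both peptides."""
    geom_for = {
        "P4(4R)": "(4R)-exo major",
        "P8(4S)": "(4S)-endo major",
        "P4(4S)": "(4S)-endo major",
        "P8(4R)": "(4R)-exo major",
    }
    taus = {}
    for _, row in measured_relaxation.iterrows():
        geom = geometries[geom_for[row["signal"]]]
        taus[(row["peptide"], row["signal"])] = fpro.invert_tauc_from_noe(
            geom, row["noe_max_pct"] / 100.0, field
        )
    assert taus[("MpRS", "P8(4S)")] > taus[("MpRS", "P4(4R)")]
    assert taus[("MpSR", "P8(4R)")] > taus[("MpSR", "P4(4S)")]


def test_curve_frame_columns(exo_major, field):
    grid = relaxation_curves(exo_major, field, np.logspace(-11, -7, 81))
    df = grid.to_frame()
    assert list(df.columns) == ["tau_c_s", "R1_s1", "R2_s1", "sigma_HG_s1", "noe_fraction"]
    assert len(df) == 81
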
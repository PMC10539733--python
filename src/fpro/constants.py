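"""Physical constants and magnetic-field settings for ¹⁹F/¹H spin systems.

Gyromagnetic ratios are CODATA-style values in rad s⁻¹ T⁻¹.  The ¹H/¹⁹F
ratio (≈1.0624) enters both the steady-state NOE and the conversion of
cross-relaxation rates into fractional enhancements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

GAMMA_H = 2.6752218744e8  # rad s^-1 T^-1
GAMMA_F = 2.51815e8  # rad s^-1 T^-1
HBAR = 1.054571817e-34  # J s
MU0_OVER_4PI = 1e-7  # T^2 J^-1 m^3


@dataclass(frozen=True)
class PhysicalConstants:
    """Bundle of the constants entering dipolar and CSA relaxation."""

    gamma_H: float = GAMMA_H
    gamma_F: float = GAMMA_F
    hbar: float = HBAR
    mu0_over_4pi: float = MU0_OVER_4PI

    def __post_init__(self) -> None:
        if min(self.gamma_H, self.gamma_F, self.hbar, self.mu0_over_4pi) <= 0:
            raise ValueError("all physical constants must be strictly positive")
        ratio = self.gamma_H / self.gamma_F
        if not 1.062 <= ratio <= 1.063:
            raise ValueError(
                f"gamma_H/gamma_F = {ratio:.5f} outside the 1H/19F window [1.062, 1.063]"
            )

    @property
    def gamma_ratio(self) -> float:
        return self.gamma_H / self.gamma_F


@dataclass(frozen=True)
class FieldSettings:
    """Static field and the angular Larmor frequencies derived from it.

    Parameters
    ----------
    b0 : float
        Static magnetic field in tesla.  14.1 T corresponds to a 600 MHz
        (¹H) spectrometer, the field used for all ¹⁹F work here.
    """

    b0: float = 14.1
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)

    def __post_init__(self) -> None:
        if self.b0 <= 0:
            raise ValueError("B0 must be positive")

    @property
    def omega_H(self) -> float:
        """¹H angular Larmor frequency (rad s⁻¹, magnitude)."""
        return self.constants.gamma_H * self.b0

    @property
    def omega_F(self) -> float:
        """¹⁹F angular Larmor frequency (rad s⁻¹, magnitude)."""
        return self.constants.gamma_F * self.b0

    @property
    def larmor_19f_mhz(self) -> float:
        """¹⁹F spectrometer frequency in MHz (for ppm ↔ Hz conversions)."""
        return self.omega_F / (2e6 * 3.141592653589793)

    @classmethod
    def from_proton_mhz(cls, mhz: float, constants: PhysicalConstants | None = None) -> "FieldSettings":
        c = constants or PhysicalConstants()
        return cls(b0=mhz * 2e6 * 3.141592653589793 / c.gamma_H, constants=c)
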
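"""Chemical-shift and J-coupling diagnostics of proline conformation.

Three reporters:

* the ¹³Cβ−¹³Cγ shift difference, which flags the Xaa–Pro peptide-bond
  isomer (≲5 ppm trans, ≳8 ppm cis);
* the diastereotopic Hδ2−Hδ3 shift difference, an empirical probe of
  local ring dynamics;
* classification of the pyrrolidine ring pucker (Cγ-exo vs Cγ-endo) by
  nearest-reference matching of ³J(F,H) and ³J(Hα,Hβ) couplings against
  the free 4-fluoroproline amino acids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import math

__all__ = [
    "CouplingSet",
    "cis_trans_indicator",
    "hd_diastereotopic_difference",
    "classify_pucker",
    "PUCKER_BY_STEREO",
]

COUPLING_NAMES = ("jf_b2", "jf_b3", "jf_d2", "jf_d3", "jab2", "jab3")

#: fluorination stereochemistry → dominant ring pucker
PUCKER_BY_STEREO = {"(4R)": "Cg-exo", "(4S)": "Cg-endo"}

TRANS_MAX_PPM = 5.0  # Cβ−Cγ below this → trans
CIS_MIN_PPM = 8.0  # above this → cis; between: ambiguous
FLUORINATED_CG_PPM = 80.0  # Cγ beyond this is fluorinated (≈95 ppm)


@dataclass(frozen=True)
class CouplingSet:
    """Six ring couplings in Hz; missing ones are None."""

    jf_b2: float | None = None
    jf_b3: float | None = None
    jf_d2: float | None = None
    jf_d3: float | None = None
    jab2: float | None = None
    jab3: float | None = None

    def __post_init__(self) -> None:
        for name in COUPLING_NAMES:
            v = getattr(self, name)
            if v is not None and not 0.0 <= v < 60.0:
                raise ValueError(f"{name} = {v} Hz outside the plausible window [0, 60)")

    def present(self) -> set[str]:
        return {n for n in COUPLING_NAMES if getattr(self, n) is not None}


def cis_trans_indicator(cb_ppm: float, cg_ppm: float) -> tuple[float, str]:
    """Xaa–Pro isomer call from the Cβ−Cγ shift difference.

    Returns ``(delta, call)`` with call ∈ {trans, cis, ambiguous,
    not_applicable}; a Cγ shift past ~80 ppm marks a fluorinated Cγ for
    which the indicator does not apply.
    """
    delta = cb_ppm - cg_ppm
    if cg_ppm > FLUORINATED_CG_PPM:
        return delta, "not_applicable"
    if delta <= TRANS_MAX_PPM:
        return delta, "trans"
    if delta >= CIS_MIN_PPM:
        return delta, "cis"
    return delta, "ambiguous"


def hd_diastereotopic_difference(hd2_ppm: float, hd3_ppm: float) -> float:
    """Signed Hδ2 − Hδ3 shift difference (ppm)."""
    return hd2_ppm - hd3_ppm


def classify_pucker(
    measured: CouplingSet, references: Mapping[str, CouplingSet]
) -> dict:
    """Nearest-reference pucker call by RMS coupling distance.

    Returns a dict with the best label(s) (ties reported together), the
    implied pucker, per-coupling residuals for the best match and the RMS
    distance.  The largest single residual is reported as
    ``dominant_deviation`` so systematic discrepancies (e.g. the ~5 Hz
    ³J(F,Hδ2) offset between peptide-bound and free (4S)-FPro) are
    surfaced rather than silently absorbed.
    """
    results = []
    for label, ref in references.items():
        shared = measured.present() & ref.present()
        if len(shared) < 2:
            continue
        residuals = {
            n: getattr(measured, n) - getattr(ref, n) for n in sorted(shared)
        }
        rms = math.sqrt(sum(r * r for r in residuals.values()) / len(residuals))
        results.append((rms, label, residuals))
    if not results:
        raise ValueError("no reference shares >= 2 couplings with the measurement")
    results.sort(key=lambda x: x[0])
    best_rms = results[0][0]
    ties = [r for r in results if abs(r[0] - best_rms) < 1e-12]
    best_labels = [label for _, label, _ in ties]
    residuals = ties[0][2]
    dominant = max(residuals.items(), key=lambda kv: abs(kv[1]))
    pucker = next(
        (p for stereo, p in PUCKER_BY_STEREO.items() if stereo in best_labels[0]),
        None,
    )
    return {
        "label": best_labels[0],
        "tied_labels": best_labels,
        "pucker": pucker,
        "rms_hz": best_rms,
        "residuals_hz": residuals,
        "dominant_deviation": {"coupling": dominant[0], "residual_hz": dominant[1]},
    }
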
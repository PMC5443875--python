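"""Doppler-echo hemodynamic derivations and the prognosis classifier.

Stroke volume is the product of the aortic velocity–time integral (VTI,
cm, averaged over one respiratory cycle) and the aortic cross-sectional
area (cm^2, circular, literature diameter 2.6 mm for rats of this age);
cardiac output is stroke volume times heart rate.  Peak systolic aortic
flow velocity above 0.93 m/s at 24 h classifies an animal as "good
prognosis" (strictly above: equality is "bad").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_AORTIC_DIAMETER_MM",
    "DEFAULT_PV_CUTOFF",
    "EchoMeasurement",
    "HemodynamicIndices",
    "aortic_area",
    "stroke_volume",
    "cardiac_output",
    "classify_prognosis",
    "derive_hemodynamics",
    "hemodynamics_table",
]

DEFAULT_AORTIC_DIAMETER_MM = 2.6
DEFAULT_PV_CUTOFF = 0.93  # m/s

# warn-only physiologic screen for peak velocity, m/s
_PV_SCREEN = (0.2, 2.5)


@dataclass
class EchoMeasurement:
    """Per-animal echo inputs: VTI (cm), peak velocity (m/s), HR (bpm)."""

    vti: float
    peak_velocity: float
    heart_rate: float
    aortic_diameter: float = DEFAULT_AORTIC_DIAMETER_MM  # mm

    def __post_init__(self) -> None:
        for name in ("vti", "peak_velocity", "heart_rate", "aortic_diameter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def pv_in_physiologic_range(self) -> bool:
        lo, hi = _PV_SCREEN
        return lo <= self.peak_velocity <= hi


@dataclass
class HemodynamicIndices:
    aortic_area: float  # cm^2
    stroke_volume: float  # ml
    cardiac_output: float  # ml/min
    prognosis: str  # "good" | "bad"


def aortic_area(diameter_mm: float = DEFAULT_AORTIC_DIAMETER_MM) -> float:
    """Circular cross-sectional area in cm^2 from a diameter in mm."""
    if diameter_mm <= 0:
        raise ValueError("diameter must be positive")
    radius_cm = diameter_mm / 2.0 / 10.0
    return float(np.pi * radius_cm**2)


def stroke_volume(vti_cm: float, area_cm2: float) -> float:
    """SV = VTI * area; cm * cm^2 = cm^3 = ml."""
    if vti_cm <= 0 or area_cm2 <= 0:
        raise ValueError("vti and area must be positive")
    return vti_cm * area_cm2


def cardiac_output(sv_ml: float, hr_bpm: float) -> float:
    """CO = SV * HR; ml * 1/min = ml/min."""
    if sv_ml < 0:
        raise ValueError("stroke volume must be non-negative")
    if hr_bpm <= 0:
        raise ValueError("heart rate must be positive")
    return sv_ml * hr_bpm


def classify_prognosis(
    peak_velocity: float, cutoff: float = DEFAULT_PV_CUTOFF
) -> str:
    """"good" iff peak velocity is strictly above the cutoff."""
    if peak_velocity <= 0:
        raise ValueError("peak velocity must be positive")
    return "good" if peak_velocity > cutoff else "bad"


def derive_hemodynamics(
    echo: EchoMeasurement, cutoff: float = DEFAULT_PV_CUTOFF
) -> HemodynamicIndices:
    area = aortic_area(echo.aortic_diameter)
    sv = stroke_volume(echo.vti, area)
    return HemodynamicIndices(
        aortic_area=area,
        stroke_volume=sv,
        cardiac_output=cardiac_output(sv, echo.heart_rate),
        prognosis=classify_prognosis(echo.peak_velocity, cutoff),
    )


def hemodynamics_table(
    echo: pd.DataFrame,
    cutoff: float = DEFAULT_PV_CUTOFF,
    diameter_mm: float = DEFAULT_AORTIC_DIAMETER_MM,
) -> pd.DataFrame:
    """Vectorized derivation for an echo table.

    Expects columns ``animal_id, vti_cm, pv_ms, hr_bpm`` and optionally a
    per-animal ``diameter_mm`` override; returns the input plus
    ``aortic_area_cm2, stroke_volume_ml, cardiac_output_ml_min, prognosis``.
    """
    out = echo.copy()
    d = out["diameter_mm"] if "diameter_mm" in out else pd.Series(
        diameter_mm, index=out.index
    )
    area = np.pi * (d / 20.0) ** 2
    out["aortic_area_cm2"] = area
    out["stroke_volume_ml"] = out["vti_cm"] * area
    out["cardiac_output_ml_min"] = out["stroke_volume_ml"] * out["hr_bpm"]
    out["prognosis"] = np.where(out["pv_ms"] > cutoff, "good", "bad")
    return out
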
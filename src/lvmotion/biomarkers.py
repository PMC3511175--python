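"""Scalar biomechanical markers derived from fitted motion profiles."""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .fit import ParamProfile

__all__ = [
    "radius_change_endo",
    "cavity_area_reduction",
    "twist_apex_base",
    "MarkerReport",
    "build_report",
]


def radius_change_endo(alpha: float, r_endo: float) -> float:
    """Endocardial radius decrease ``alpha**2 / r_endo`` (mm)."""
    if not (r_endo > alpha >= 0):
        raise ValueError(f"requires r_endo > alpha >= 0, got alpha={alpha}, r_endo={r_endo}")
    return (alpha * alpha) / r_endo


def cavity_area_reduction(alpha: float, r_endo: float, approximate: bool = False) -> float:
    """Reduction of the LV cavity cross-sectional area (mm^2).

    Exact mode: ``pi * (r_endo**2 - r'**2)`` with
    ``r' = r_endo - alpha**2 / r_endo``.  Approximate mode uses
    ``(r**2 - r'**2) ~ 2 r (r - r')``, giving ``2 * pi * alpha**2``
    independently of ``r_endo`` (overestimates the exact value by the
    relative amount ``alpha**2 / (2 r_endo**2)``).
    """
    if not (r_endo > alpha >= 0):
        raise ValueError(f"requires r_endo > alpha >= 0, got alpha={alpha}, r_endo={r_endo}")
    if approximate:
        return 2.0 * math.pi * alpha * alpha
    r_prime = r_endo - (alpha * alpha) / r_endo
    return math.pi * (r_endo * r_endo - r_prime * r_prime)


def twist_apex_base(apex: ParamProfile, base: ParamProfile) -> pd.DataFrame:
    """Per-phase normalized twist: beta_norm(apex) - beta_norm(base).

    Positive twist = apex rotating clockwise relative to the base in the
    head-to-toe view.  ``twist_epi_deg`` converts the difference to the
    epicardial rotation-angle difference in degrees
    (beta/r_epi evaluated at r = r_epi is the angle in radians).
    """
    ph_a = apex.table["phase_fraction"].to_numpy()
    ph_b = base.table["phase_fraction"].to_numpy()
    if ph_a.shape != ph_b.shape or not np.allclose(ph_a, ph_b):
        raise ValueError("apex and base profiles have mismatched phase grids")
    twist = apex.table["beta_norm"].to_numpy() - base.table["beta_norm"].to_numpy()
    return pd.DataFrame(
        {
            "phase_fraction": ph_a,
            "twist_norm": twist,
            "twist_epi_deg": np.degrees(twist),
        }
    )


@dataclasses.dataclass
class MarkerReport:
    """Per-phase derived markers for one fitted profile (plus optional twist)."""

    table: pd.DataFrame
    slice_level: str
    r_epi: float
    r_endo: float
    twist: pd.DataFrame | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "slice_level": self.slice_level,
            "r_epi_mm": self.r_epi,
            "r_endo_mm": self.r_endo,
            "per_phase": self.table.to_dict(orient="records"),
        }
        if self.twist is not None:
            payload["twist_apex_base"] = self.twist.to_dict(orient="records")
        Path(path).write_text(json.dumps(payload, indent=2))


def build_report(
    profile: ParamProfile,
    r_endo: float,
    apex: ParamProfile | None = None,
    base: ParamProfile | None = None,
) -> MarkerReport:
    """Compute per-phase markers from a fitted profile.

    ``cavity_area_fraction`` is the area reduction relative to the
    end-diastolic cavity area.
    """
    if profile.r_epi is None:
        raise ValueError("profile lacks r_epi metadata")
    alphas = profile.table["alpha_norm"].to_numpy() * profile.r_epi
    radius_change = np.array([radius_change_endo(a, r_endo) for a in alphas])
    area_red = np.array([cavity_area_reduction(a, r_endo) for a in alphas])
    cavity_area = math.pi * r_endo * r_endo
    table = pd.DataFrame(
        {
            "phase_fraction": profile.table["phase_fraction"].to_numpy(),
            "radius_change_endo_mm": radius_change,
            "cavity_area_reduction_mm2": area_red,
            "cavity_area_fraction": area_red / cavity_area,
        }
    )
    twist = twist_apex_base(apex, base) if apex is not None and base is not None else None
    return MarkerReport(
        table=table,
        slice_level=profile.slice_level,
        r_epi=profile.r_epi,
        r_endo=r_endo,
        twist=twist,
    )
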
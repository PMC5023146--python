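"""Statsmodels-style facade: a patient model object with fit() and results.

``TwoGeometryModel`` bundles the inputs of one patient simulation -- the
in-vivo minimum-volume contour stack, the measured (min, max) cavity volume
pair, the pressure schedule and per-phase base materials.  ``fit()`` performs
the full calibration (pre-shrink of both zero-load geometries plus stiffness
scaling) and returns a ``TwoGeometryResults`` carrying the calibrated
chambers, the simulated cycle, landmark states and diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import constitutive, forward_model, geometry
from .calibrate import PhaseCalibration, calibrate_patient
from .forward_model import (LANDMARKS, CycleResult, PressureSchedule,
                            extract_phase_metrics, simulate_cycle_1G,
                            simulate_cycle_2G)
from .geometry import ContourStack


class TwoGeometryModel:
    """Two-zero-load-geometry ventricle model for a single patient.

    Parameters
    ----------
    stack_min : ContourStack
        In-vivo geometry at minimum cavity volume.
    v_max : float
        Maximum (end-filling / begin-ejection) cavity volume in cm^3.
    v_min : float, optional
        Minimum cavity volume; defaults to the stack's cavity volume.
    schedule : PressureSchedule, optional
    material_dia, material_sys : MaterialParams, optional
        Base materials; per-patient stiffness is set by calibration.
    """

    def __init__(self, stack_min: ContourStack, v_max: float,
                 v_min: float | None = None,
                 schedule: PressureSchedule | None = None,
                 material_dia=None, material_sys=None,
                 axial_ratio: float = 1.0):
        self.stack_min = stack_min
        self.v_min = (geometry.stack_volume(stack_min, "inner")
                      if v_min is None else float(v_min))
        self.v_max = float(v_max)
        if self.v_max <= self.v_min:
            raise ValueError("v_max must exceed v_min")
        self.schedule = schedule or PressureSchedule()
        self.material_dia = (material_dia or
                             constitutive.DEFAULT_MATERIALS["ventricle_diastole"])
        self.material_sys = (material_sys or
                             constitutive.DEFAULT_MATERIALS["ventricle_systole"])
        self.axial_ratio = axial_ratio

    def fit(self, tol: float = 0.005) -> "TwoGeometryResults":
        """Calibrate both phases and simulate the 2G cycle."""
        cal = calibrate_patient(self.stack_min, self.v_min, self.v_max,
                                self.schedule, self.material_dia,
                                self.material_sys, tol=tol,
                                axial_ratio=self.axial_ratio)
        materials = {k: c.material for k, c in cal.items()}
        cycle = simulate_cycle_2G(cal["diastole"].preshrink,
                                  cal["systole"].preshrink,
                                  materials, self.schedule)
        return TwoGeometryResults(model=self, calibration=cal, cycle=cycle)


@dataclass
class TwoGeometryResults:
    """Calibrated 2G simulation results for one patient."""

    model: TwoGeometryModel
    calibration: dict[str, PhaseCalibration]
    cycle: CycleResult

    @property
    def landmark_table(self) -> pd.DataFrame:
        rows = []
        for name in LANDMARKS:
            lm = self.cycle.landmarks[name]
            rows.append({"state": name, "p_kpa": float(lm["p_kpa"]),
                         "vol_cm3": float(lm["vol_cm3"]),
                         "stress_p1_kpa": float(lm["stress_p1_kpa"]),
                         "strain_p1": float(lm["strain_p1"])})
        return pd.DataFrame(rows).set_index("state")

    @property
    def volume_targets(self) -> dict[str, float]:
        return {"BF": self.model.v_min, "EF": self.model.v_max,
                "BE": self.model.v_max, "EE": self.model.v_min}

    @property
    def volume_errors(self) -> dict[str, float]:
        """Relative deviation of simulated landmark volumes from their targets."""
        out = {}
        for name, target in self.volume_targets.items():
            vol = float(self.cycle.landmarks[name]["vol_cm3"])
            out[name] = abs(vol - target) / target
        return out

    @property
    def max_volume_error(self) -> float:
        return max(self.volume_errors.values())

    def phase_metrics(self, axial_ratio: float | None = None) -> pd.DataFrame:
        stacks = {k: c.preshrink.zero_load for k, c in self.calibration.items()}
        return extract_phase_metrics(
            self.cycle, stacks,
            axial_ratio=self.model.axial_ratio if axial_ratio is None
            else axial_ratio)

    def compare_1G(self) -> CycleResult:
        """Companion single-geometry cycle on the diastole zero-load geometry."""
        return simulate_cycle_1G(self.calibration["diastole"].preshrink,
                                 self.calibration["diastole"].material,
                                 self.model.schedule)

    def summary(self) -> str:
        cal = self.calibration
        lines = [
            "Two-geometry ventricle model results",
            "=" * 52,
            f"target volumes (cm^3): min {self.model.v_min:.2f}  "
            f"max {self.model.v_max:.2f}",
            f"pressures (kPa): Pmin {self.model.schedule.pmin}  "
            f"Pdia {self.model.schedule.pdia}  Pmax {self.model.schedule.pmax}  "
            f"Psys {self.model.schedule.psys}",
            "",
            "phase     shrink-rate  stiffness-factor  vol-err(lo)  vol-err(hi)",
        ]
        for phase in ("diastole", "systole"):
            c = cal[phase]
            lines.append(
                f"{phase:<9} {c.preshrink.inner_rate:>10.4f}  "
                f"{c.stiffness_factor:>15.4g}  {c.volume_error_low:>10.3%}  "
                f"{c.volume_error_high:>10.3%}")
        lines.append("")
        lines.append("landmark states:")
        lines.append(self.landmark_table.to_string(
            float_format=lambda v: f"{v:.4g}"))
        lines.append("")
        lines.append(f"max landmark volume error: {self.max_volume_error:.3%}")
        return "\n".join(lines)
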
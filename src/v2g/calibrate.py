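"""Patient-specific calibration: stiffness scaling and phase calibration.

Material parameter values are adjusted per patient so the simulated chamber
matches measured cavity volumes: a single multiplicative factor on all
stress-like parameters (c1, c2, D1, K1; C for the Fung law) is found by
root-finding, and the zero-load geometry and the stiffness factor of each
phase are iterated together until the chamber reproduces the measured
(minimum, maximum) volume pair at the phase's end pressures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .constitutive import MaterialParams
from .errors import CalibrationError
from .forward_model import (EquivalentChamber, PressureSchedule, inflate,
                            to_equivalent_chamber)
from .geometry import ContourStack
from .preshrink import PreShrinkResult, find_zero_load

FACTOR_BOUNDS = (1e-3, 1e3)


def scale_stiffness_to_volume(material: MaterialParams,
                              chamber: EquivalentChamber | ContourStack,
                              pressure: float, target_volume: float,
                              tol: float = 0.005) -> tuple[MaterialParams, float]:
    """Scale the stress-like parameters so inflation matches a target volume.

    The inflated volume decreases monotonically in the stiffness factor, so a
    bracketed root-find on log-factor converges unconditionally when the
    target is reachable within the factor bounds [1e-3, 1e3].
    Returns (scaled material, factor).
    """
    ch = (chamber if isinstance(chamber, EquivalentChamber)
          else to_equivalent_chamber(chamber))
    if pressure > 0 and target_volume <= ch.cavity_volume:
        raise CalibrationError(
            "target volume must exceed the zero-load cavity volume under "
            "positive pressure")

    def err(logf):
        m = material.scaled(float(np.exp(logf)))
        return inflate(ch, m, pressure).volume - target_volume

    lo, hi = np.log(FACTOR_BOUNDS[0]), np.log(FACTOR_BOUNDS[1])
    e0 = err(0.0)
    if abs(e0) / target_volume < 1e-12:
        return material, 1.0
    try:
        # stiffer (larger factor) -> smaller volume; pick the half-bracket
        if e0 > 0:
            logf = optimize.brentq(err, 0.0, hi, xtol=1e-12)
        else:
            logf = optimize.brentq(err, lo, 0.0, xtol=1e-12)
    except ValueError as exc:
        raise CalibrationError(
            f"volume target {target_volume:.3g} cm^3 unreachable within "
            f"stiffness factor bounds {FACTOR_BOUNDS}") from exc
    factor = float(np.exp(logf))
    scaled = material.scaled(factor)
    achieved = inflate(ch, scaled, pressure).volume
    if abs(achieved - target_volume) / target_volume > tol:
        raise CalibrationError("stiffness scaling did not meet tolerance")
    return scaled, factor


@dataclass
class PhaseCalibration:
    """Calibrated zero-load geometry + material for one cardiac phase."""

    preshrink: PreShrinkResult
    material: MaterialParams
    stiffness_factor: float
    volume_error_low: float   # at the phase's low-volume pressure
    volume_error_high: float  # at the phase's high-volume pressure


_START_RATE = {"diastole": 0.02, "systole": 0.15}


def calibrate_phase(stack_min: ContourStack, material: MaterialParams,
                    p_low: float, p_high: float, v_min: float, v_max: float,
                    phase: str, tol: float = 0.005,
                    axial_ratio: float = 1.0) -> PhaseCalibration:
    """Jointly determine shrink rate and material adjustment for one phase.

    Constraints: inflating the zero-load chamber to ``p_low`` must give
    ``v_min`` and to ``p_high`` must give ``v_max``.  A single stiffness
    factor moves both volumes along the same pressure-volume curve, so the
    curve shape itself must be adjustable: the solve is a bounded
    least-squares over (shrink rate, log stiffness factor, log exponent
    scale), where the exponent scale multiplies the dimensionless stiffening
    exponents (D2, K2).  A weak prior keeps the exponent scale at 1 whenever
    the prescribed curve shape can already satisfy both volumes.
    """
    from scipy.optimize import least_squares

    from .preshrink import shrink_stack

    lo_f, hi_f = np.log(FACTOR_BOUNDS)

    def unpack(theta):
        rate, logf, logs = theta
        m = material.scaled(float(np.exp(logf)))
        m = m.exponent_scaled(float(np.exp(logs)))
        return rate, m

    def residuals(theta):
        rate, m = unpack(theta)
        shrunk = shrink_stack(stack_min, rate, axial_ratio * rate)
        ch = to_equivalent_chamber(shrunk)
        try:
            e_low = inflate(ch, m, p_low).volume / v_min - 1.0
            e_high = inflate(ch, m, p_high).volume / v_max - 1.0
        except Exception:
            return np.array([10.0, 10.0, theta[2]])
        return np.array([e_low, e_high, 0.02 * theta[2]])

    x0 = np.array([_START_RATE[phase], 0.0, 0.0])
    sol = least_squares(residuals, x0,
                        bounds=([0.0, lo_f, np.log(0.2)],
                                [0.45, hi_f, np.log(5.0)]),
                        xtol=1e-12, ftol=1e-14, gtol=1e-14,
                        diff_step=1e-4, max_nfev=400)
    rate, m = unpack(sol.x)
    shrunk = shrink_stack(stack_min, rate, axial_ratio * rate)
    ch = to_equivalent_chamber(shrunk)
    err_low = abs(inflate(ch, m, p_low).volume - v_min) / v_min
    err_high = abs(inflate(ch, m, p_high).volume - v_max) / v_max
    if err_low > tol or err_high > tol:
        raise CalibrationError(
            f"{phase} calibration did not reach tolerance "
            f"(errors {err_low:.3%}, {err_high:.3%})")
    ps = PreShrinkResult(zero_load=shrunk, iterations=int(sol.nfev),
                         inner_rate=float(rate), volume_error=err_low,
                         phase=phase, target_volume=v_min, pressure=p_low)
    return PhaseCalibration(ps, m, float(np.exp(sol.x[1])), err_low, err_high)


def calibrate_patient(stack_min: ContourStack, v_min: float, v_max: float,
                      sched: PressureSchedule,
                      material_dia: MaterialParams,
                      material_sys: MaterialParams,
                      tol: float = 0.005,
                      axial_ratio: float = 1.0) -> dict[str, PhaseCalibration]:
    """Calibrate both phases of the 2G model to a (v_min, v_max) volume pair.

    Diastole: chamber at Pmin matches v_min, at Pdia matches v_max.
    Systole: chamber at Psys matches v_min, at Pmax matches v_max (so volume
    is continuous across the skipped isovolumic transitions).
    """
    dia = calibrate_phase(stack_min, material_dia, sched.pmin, sched.pdia,
                          v_min, v_max, "diastole", tol=tol,
                          axial_ratio=axial_ratio)
    sys_ = calibrate_phase(stack_min, material_sys, sched.psys, sched.pmax,
                           v_min, v_max, "systole", tol=tol,
                           axial_ratio=axial_ratio)
    return {"diastole": dia, "systole": sys_}
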
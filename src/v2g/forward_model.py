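"""Quasi-static chamber inflation and the two-phase (2G) cycle simulator.

The three-dimensional finite-element solve is replaced by the inflation of an
incompressible thick-walled spherical chamber whose inner and outer radii are
chosen by volume equivalence with the contour stack.  This preserves the
quantities the downstream analysis consumes -- the pressure-volume relation,
transmural mean stress/strain and the inter-phase discontinuities -- with
closed-form kinematics:

    r^3 = R^3 + ri^3 - Ri^3          (incompressible radial map)
    p   = int_{ri}^{ro} 2 (sigma_hoop - sigma_rr) / r dr

where sigma_hoop - sigma_rr follows from the equibiaxial derivative of the
strain-energy density, lambda = r / R.  The radial stress satisfies
sigma_rr(ri) = -p and sigma_rr(ro) = 0 by construction.

The cycle simulator runs the filling phase on the diastole zero-load chamber
(pressure Pmin -> Pdia) and the ejection phase on the systole chamber
(Pmax -> Psys), skipping the two isovolumic phases, so stress and strain jump
at the end-filling -> begin-ejection and end-ejection -> begin-filling
transitions while volume stays continuous (both phases are calibrated to the
same measured volume pair).  Inertia is neglected (quasi-static): the solution
is periodic by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize

from .constitutive import (AnisoMRParams, FungParams, IsoMRParams,
                           MaterialParams, _as_aniso, _mr_derivatives,
                           _safe_exp)
from .errors import ConvergenceError, ParameterRangeError, V2GError
from .geometry import ContourStack, stack_volume, wall_volume
from .preshrink import PreShrinkResult, shrink_stack

LANDMARKS = ("BF", "EF", "BE", "EE")


# ---------------------------------------------------------------------------
# pressure schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PressureSchedule:
    """Four-point RV pressure schedule (kPa) with phase timing.

    Pmin: begin-filling, Pdia: end-filling, Pmax: begin-ejection,
    Psys: end-ejection.  The default values are configuration placeholders at
    physiological magnitudes for a pressure-loaded right ventricle and should
    be overridden with catheterization data when available.
    """

    pmin: float = 0.3
    pdia: float = 1.3
    pmax: float = 8.7
    psys: float = 2.7
    fill_fraction: float = 0.6
    samples_per_phase: int = 25

    def __post_init__(self):
        if not (self.pmin < self.pdia <= self.pmax):
            raise ValueError("need Pmin < Pdia <= Pmax")
        if not (self.pmin <= self.psys < self.pmax):
            raise ValueError("need Pmin <= Psys < Pmax")
        if not (0.0 < self.fill_fraction < 1.0):
            raise ValueError("fill_fraction must be in (0, 1)")
        if self.samples_per_phase < 2:
            raise ValueError("need at least 2 samples per phase")


# ---------------------------------------------------------------------------
# equivalent chamber
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EquivalentChamber:
    """Zero-load thick-walled sphere equivalent to a contour stack by volume."""

    Ri: float
    Ro: float
    source_label: str = ""

    def __post_init__(self):
        if not (0.0 < self.Ri < self.Ro):
            raise V2GError("need 0 < Ri < Ro")

    @property
    def cavity_volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.Ri ** 3

    @property
    def wall_volume(self) -> float:
        return 4.0 / 3.0 * np.pi * (self.Ro ** 3 - self.Ri ** 3)


def to_equivalent_chamber(stack: ContourStack) -> EquivalentChamber:
    """Inner radius from cavity-volume equivalence, outer from cavity + wall."""
    v_in = stack_volume(stack, "inner")
    v_wall = wall_volume(stack)
    if v_wall <= 0:
        raise V2GError("stack has non-positive wall volume")
    Ri = (3.0 * v_in / (4.0 * np.pi)) ** (1.0 / 3.0)
    Ro = (3.0 * (v_in + v_wall) / (4.0 * np.pi)) ** (1.0 / 3.0)
    return EquivalentChamber(Ri=Ri, Ro=Ro, source_label=stack.label)


# ---------------------------------------------------------------------------
# inflation
# ---------------------------------------------------------------------------

def _hoop_minus_radial(material: MaterialParams, lam: np.ndarray) -> np.ndarray:
    """Mean in-plane minus radial Cauchy stress at equibiaxial stretch lambda.

    g(lambda) = (lambda / 2) dW~/dlambda with W~ the energy along the
    spherically symmetric incompressible path F = diag(1/lambda^2, lambda,
    lambda); for the fiber term the in-plane mean is used (fibers are tangent
    to the wall, and under equibiaxial symmetry the fiber stretch is
    independent of the in-plane fiber angle).
    """
    lam = np.asarray(lam, dtype=float)
    if isinstance(material, FungParams):
        Ef = Ec = (lam ** 2 - 1.0) / 2.0
        Er = (lam ** -4 - 1.0) / 2.0
        Q = material.b1 * Ef ** 2 + material.b2 * (Ec ** 2 + Er ** 2)
        dQ = (2.0 * material.b1 * Ef * lam
              + 2.0 * material.b2 * (Ec * lam - 2.0 * Er * lam ** -5))
        return 0.25 * lam * material.C_f * _safe_exp(Q) * dQ
    pa = _as_aniso(material)
    I1 = 2.0 * lam ** 2 + lam ** -4
    I4 = lam ** 2
    W1 = pa.iso.c1 + pa.iso.D1 * pa.iso.D2 * _safe_exp(pa.iso.D2 * (I1 - 3.0))
    W2 = pa.iso.c2
    if pa.K2 == 0.0:
        W4 = pa.K1 * (I4 - 1.0)
    else:
        W4 = pa.K1 * (I4 - 1.0) * _safe_exp(pa.K2 * (I4 - 1.0) ** 2)
    return (2.0 * W1 * (lam ** 2 - lam ** -4)
            + 2.0 * W2 * (lam ** 4 - lam ** -2)
            + W4 * lam ** 2)


@dataclass
class TransmuralState:
    """Deformed chamber state at one pressure with transmural profiles."""

    pressure: float
    ri: float
    ro: float
    volume: float
    r: np.ndarray
    sigma_rr: np.ndarray
    sigma_hoop: np.ndarray
    strain_hoop: np.ndarray
    stress_p1: float
    strain_p1: float
    boundary_residual: float
    chamber: EquivalentChamber = None

    @property
    def wall_thickness(self) -> float:
        return self.ro - self.ri


def _pressure_of_inner_radius(ch: EquivalentChamber, material, ri: float,
                              nodes: np.ndarray, weights: np.ndarray) -> float:
    a = ri ** 3 - ch.Ri ** 3
    R = nodes
    r = np.cbrt(R ** 3 + a)
    lam = r / R
    g = _hoop_minus_radial(material, lam)
    # dr/dR = R^2 / r^2  =>  integrand in R: 2 g / r * R^2 / r^2
    return float(np.sum(weights * 2.0 * g * R ** 2 / r ** 3))


def inflate(ch: EquivalentChamber, material: MaterialParams, p: float,
            n_quad: int = 48, n_profile: int = 101,
            lam_max: float = 4.0) -> TransmuralState:
    """Quasi-static inflation of the chamber to internal pressure p (kPa)."""
    if p < 0:
        raise ValueError("pressure must be non-negative")
    x, w = np.polynomial.legendre.leggauss(n_quad)
    nodes = 0.5 * (ch.Ro - ch.Ri) * x + 0.5 * (ch.Ro + ch.Ri)
    weights = 0.5 * (ch.Ro - ch.Ri) * w

    if p == 0.0:
        ri = ch.Ri
    else:
        def h(ri):
            return _pressure_of_inner_radius(ch, material, ri, nodes, weights) - p

        # bracket: expand the inner stretch until pressure is exceeded
        hi = None
        for lam_i in np.geomspace(1.001, lam_max, 40):
            cand = ch.Ri * lam_i
            try:
                val = h(cand)
            except ParameterRangeError:
                break
            if val > 0:
                hi = cand
                break
        if hi is None:
            raise ConvergenceError(
                f"pressure {p} kPa not supportable by the material up to "
                f"inner stretch {lam_max}")
        ri = optimize.brentq(h, ch.Ri * (1.0 + 1e-12), hi, xtol=1e-12,
                             rtol=1e-14)

    # transmural profiles on a uniform reference grid
    Rp = np.linspace(ch.Ri, ch.Ro, n_profile)
    a = ri ** 3 - ch.Ri ** 3
    r = np.cbrt(Rp ** 3 + a)
    lam = r / Rp
    g = _hoop_minus_radial(material, lam)
    integrand = 2.0 * g * Rp ** 2 / r ** 3
    # sigma_rr(r_k) = -p + int_{ri}^{r_k} 2 g / r dr   (trapezoid, cumulative)
    cum = np.concatenate([[0.0], np.cumsum(
        0.5 * (integrand[1:] + integrand[:-1]) * np.diff(Rp))])
    sigma_rr = -p + cum
    sigma_hoop = sigma_rr + g
    strain_hoop = (lam ** 2 - 1.0) / 2.0

    w_vol = r ** 2  # volume weighting of the spherical shell
    stress_p1 = float(np.trapezoid(sigma_hoop * w_vol, r)
                      / np.trapezoid(w_vol, r)) if p > 0 else 0.0
    strain_p1 = float(np.trapezoid(strain_hoop * w_vol, r)
                      / np.trapezoid(w_vol, r))
    residual = abs(sigma_rr[-1])  # outer surface must be traction-free

    return TransmuralState(
        pressure=p, ri=float(ri), ro=float(r[-1]),
        volume=4.0 / 3.0 * np.pi * float(ri) ** 3,
        r=r, sigma_rr=sigma_rr, sigma_hoop=sigma_hoop,
        strain_hoop=strain_hoop, stress_p1=stress_p1, strain_p1=strain_p1,
        boundary_residual=residual, chamber=ch)


# ---------------------------------------------------------------------------
# cycle simulation
# ---------------------------------------------------------------------------

@dataclass
class CycleResult:
    """Phase-resolved time series plus the four landmark states."""

    series: pd.DataFrame
    landmarks: dict
    chambers: dict
    materials: dict
    schedule: PressureSchedule

    def landmark_value(self, name: str, column: str) -> float:
        return float(self.landmarks[name][column])

    @property
    def has_discontinuity(self) -> bool:
        """Whether stress jumps at the phase transitions (2G signature)."""
        s = self.series
        fill_end = s[s.phase == "filling"].iloc[-1]
        eject_start = s[s.phase == "ejection"].iloc[0]
        denom = max(abs(fill_end.stress_p1), abs(eject_start.stress_p1), 1e-12)
        return abs(eject_start.stress_p1 - fill_end.stress_p1) / denom > 1e-6


def simulate_cycle_2G(dia: PreShrinkResult | ContourStack,
                      sys: PreShrinkResult | ContourStack,
                      materials: Mapping[str, MaterialParams],
                      sched: PressureSchedule) -> CycleResult:
    """Two-phase cycle: filling on the diastole chamber, ejection on the systole.

    Phase 1 ramps the pressure Pmin -> Pdia on the diastole zero-load chamber;
    the model then switches instantaneously to the systole chamber at
    begin-ejection with p = Pmax (the isovolumic contraction is skipped), and
    Phase 3 ramps Pmax -> Psys; the switch back to the diastole chamber at
    begin-filling with p = Pmin skips the isovolumic relaxation.
    """
    stacks = {"diastole": dia.zero_load if isinstance(dia, PreShrinkResult) else dia,
              "systole": sys.zero_load if isinstance(sys, PreShrinkResult) else sys}
    chambers = {k: to_equivalent_chamber(v) for k, v in stacks.items()}
    n = sched.samples_per_phase

    rows = []
    t_fill = np.linspace(0.0, sched.fill_fraction, n)
    p_fill = np.linspace(sched.pmin, sched.pdia, n)
    for t, p in zip(t_fill, p_fill):
        st = inflate(chambers["diastole"], materials["diastole"], float(p))
        rows.append(_row(t, "filling", st))
    t_ej = np.linspace(sched.fill_fraction, 1.0, n)
    p_ej = np.linspace(sched.pmax, sched.psys, n)
    for t, p in zip(t_ej, p_ej):
        st = inflate(chambers["systole"], materials["systole"], float(p))
        rows.append(_row(t, "ejection", st))

    series = pd.DataFrame(rows)
    landmarks = {
        "BF": series.iloc[0],
        "EF": series.iloc[n - 1],
        "BE": series.iloc[n],
        "EE": series.iloc[2 * n - 1],
    }
    return CycleResult(series=series, landmarks=landmarks, chambers=chambers,
                       materials=dict(materials), schedule=sched)


def simulate_cycle_1G(geom: PreShrinkResult | ContourStack,
                      material: MaterialParams,
                      sched: PressureSchedule) -> CycleResult:
    """Single-geometry cycle: same code path as 2G with a degenerate schedule.

    The one chamber is loaded continuously from Pmin to Pmax and back, so
    end-filling coincides with begin-ejection and end-ejection with
    begin-filling; stress and strain are continuous everywhere.
    """
    sched_1g = PressureSchedule(pmin=sched.pmin, pdia=sched.pmax,
                                pmax=sched.pmax, psys=sched.pmin,
                                fill_fraction=sched.fill_fraction,
                                samples_per_phase=sched.samples_per_phase)
    return simulate_cycle_2G(geom, geom,
                             {"diastole": material, "systole": material},
                             sched_1g)


def _row(t: float, phase: str, st: TransmuralState) -> dict:
    r_mid = 0.5 * (st.ri + st.ro)
    return {
        "t": t, "phase": phase, "p_kpa": st.pressure, "vol_cm3": st.volume,
        "stress_p1_kpa": st.stress_p1, "strain_p1": st.strain_p1,
        "stress_p1": st.stress_p1,  # alias
        "wt_cm": st.wall_thickness, "ccur_1cm": 1.0 / r_mid,
        "lcur_1cm": 1.0 / r_mid,
    }


# ---------------------------------------------------------------------------
# mapping deformed states back onto the contour stack
# ---------------------------------------------------------------------------

def _expand_stack_to_volume(stack: ContourStack, target_volume: float,
                            axial_ratio: float = 1.0) -> ContourStack:
    """Scale a stack (shrink with a possibly negative rate) to a cavity volume,
    conserving wall volume, so thickness thins as the cavity dilates."""

    def f(rate):
        s = _signed_shrink(stack, rate, axial_ratio)
        return stack_volume(s, "inner") - target_volume

    rate = optimize.brentq(f, -0.75, 0.5, xtol=1e-10)
    return _signed_shrink(stack, rate, axial_ratio)


def _signed_shrink(stack: ContourStack, rate: float,
                   axial_ratio: float) -> ContourStack:
    if rate >= 0:
        return shrink_stack(stack, rate, min(axial_ratio * rate, 0.5),
                            conserve="volume")
    # expansion: invert the conservation relation with negative rates
    from .geometry import VentricleSlice, contour_area  # local import for clarity
    import numpy as _np
    fi = 1.0 - rate  # > 1
    ax = 1.0 - axial_ratio * rate
    z0 = stack.slices[0].z
    new_slices = []
    for s in stack.slices:
        a_in = abs(contour_area(s.inner))
        a_out = abs(contour_area(s.outer))
        target_out = (a_out - a_in) / ax + a_in * fi ** 2
        fo = _np.sqrt(target_out / a_out)
        c_i, c_o = s.inner.mean(axis=0), s.outer.mean(axis=0)
        new_slices.append(VentricleSlice(c_i + fi * (s.inner - c_i),
                                         c_o + fo * (s.outer - c_o),
                                         z0 + (s.z - z0) * ax))
    return ContourStack(new_slices, spacing=stack.spacings * ax,
                        label=stack.label)


def extract_phase_metrics(result: CycleResult,
                          stack_map: Mapping[str, ContourStack] | None = None,
                          axial_ratio: float = 1.0) -> pd.DataFrame:
    """Geometry-module metrics (WT, C-cur, L-cur) at the four landmark states.

    Each landmark's deformation is mapped back onto its phase's zero-load
    contour stack by dilating the inner contours to the deformed cavity
    volume while conserving wall volume; the geometric quantities are then
    evaluated with the geometry module on the mapped stack.
    """
    from .geometry import stack_metrics

    if stack_map is None:
        raise ValueError("stack_map with 'diastole' and 'systole' stacks needed")
    phase_of = {"BF": "diastole", "EF": "diastole",
                "BE": "systole", "EE": "systole"}
    rows = []
    for name in LANDMARKS:
        lm = result.landmarks[name]
        stack = stack_map[phase_of[name]]
        mapped = _expand_stack_to_volume(stack, float(lm["vol_cm3"]),
                                         axial_ratio)
        m = stack_metrics(mapped)
        rows.append({"state": name, "p_kpa": float(lm["p_kpa"]),
                     "vol_cm3": float(lm["vol_cm3"]),
                     "stress_p1_kpa": float(lm["stress_p1_kpa"]),
                     "strain_p1": float(lm["strain_p1"]),
                     "WT": m["WT"], "C-cur": m["C-cur"], "L-cur": m["L-cur"]})
    return pd.DataFrame(rows).set_index("state")
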
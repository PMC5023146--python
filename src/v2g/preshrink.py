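"""Zero-load geometry recovery by iterative pre-shrink.

Under in-vivo conditions the ventricle is pressurized, so the imaged geometry
is not the zero-load reference required by a finite-deformation model.  The
zero-load geometry is recovered by shrinking the in-vivo minimum-volume
geometry slice by slice: the inner contour is shrunk by a rate, the outer
contour by the smaller rate that conserves the wall cross-sectional area of
the slice (the muscle must not lose volume), and the slice spacing is reduced
in proportion.  The shrink rate is then iterated (secant method with a
bisection fallback) until re-pressurizing the candidate zero-load geometry
reproduces the measured cavity volume to within 0.5 %.

Starting rates are phase-specific: 2 % for the diastole geometry and 15 % for
the systole geometry (consistent with a 10-15 % sarcomere shortening).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .errors import ConvergenceError, V2GError
from .geometry import ContourStack, VentricleSlice, contour_area

START_RATE = {"diastole": 0.02, "systole": 0.15}


@dataclass(frozen=True)
class ShrinkParams:
    """Shrink rates: inner contour, axial (slice-spacing) reduction."""

    inner_rate: float
    axial_rate: float

    def __post_init__(self):
        if not (0.0 <= self.inner_rate < 1.0):
            raise ValueError("inner_rate must be in [0, 1)")
        if not (0.0 <= self.axial_rate < 1.0):
            raise ValueError("axial_rate must be in [0, 1)")


@dataclass
class PreShrinkResult:
    """Converged zero-load geometry plus iteration diagnostics."""

    zero_load: ContourStack
    iterations: int
    inner_rate: float
    volume_error: float
    phase: str
    trace: list = field(default_factory=list)
    target_volume: float = float("nan")
    pressure: float = float("nan")


def _scale_about(points: np.ndarray, factor: float) -> np.ndarray:
    c = points.mean(axis=0)
    return c + factor * (points - c)


def shrink_stack(stack: ContourStack, inner_rate: float, axial_rate: float = 0.0,
                 conserve: str = "area") -> ContourStack:
    """Shrink every slice toward its centroid, conserving the wall.

    The inner contour is scaled by (1 - inner_rate) about the inner centroid;
    the outer contour scale factor k solves per-slice wall conservation.  With
    ``conserve="area"`` the wall cross-sectional area is kept (for an annulus
    Ri/Ro this gives the closed form Ro' = sqrt(Ro^2 - Ri^2 + ((1-r) Ri)^2));
    with ``conserve="volume"`` the area is inflated by 1/(1 - axial_rate) so
    the three-dimensional wall volume survives the axial shrink as well.
    Slice spacing (and the z positions) contract by (1 - axial_rate).
    """
    if not (0.0 <= inner_rate <= 0.5) or not (0.0 <= axial_rate <= 0.5):
        raise ValueError("shrink rates must be in [0, 0.5]")
    if conserve not in ("area", "volume"):
        raise ValueError("conserve must be 'area' or 'volume'")
    blowup = 1.0 if conserve == "area" else 1.0 / (1.0 - axial_rate)

    z0 = stack.slices[0].z
    new_slices = []
    fi = 1.0 - inner_rate
    for s in stack.slices:
        a_in = abs(contour_area(s.inner))
        a_out = abs(contour_area(s.outer))
        target_out = blowup * (a_out - a_in) + a_in * fi ** 2
        if target_out <= 0:  # cannot occur for inner_rate < 1, guarded anyway
            raise V2GError("wall-conservation equation has no real solution")
        fo = np.sqrt(target_out / a_out)
        new_z = z0 + (s.z - z0) * (1.0 - axial_rate)
        new_slices.append(VentricleSlice(_scale_about(s.inner, fi),
                                         _scale_about(s.outer, fo), new_z))
    return ContourStack(new_slices, spacing=stack.spacings * (1.0 - axial_rate),
                        label=stack.label)


def find_zero_load(stack: ContourStack, material, pressure: float,
                   target_volume: float, phase: str = "diastole",
                   tol: float = 0.005, max_iter: int = 50,
                   axial_ratio: float = 1.0) -> PreShrinkResult:
    """Iterate the shrink rate until the pressurized volume matches the target.

    ``axial_ratio`` couples the axial rate to the inner rate
    (axial_rate = axial_ratio * inner_rate).  The scalar objective
    f(rate) = V_inflated(rate) - V_target is smooth and strictly decreasing in
    the rate, so a secant iteration (falling back to bisection once a sign
    change is bracketed) converges in a handful of steps.
    """
    from .forward_model import inflate, to_equivalent_chamber  # local: avoid cycle

    if pressure < 0:
        raise ValueError("pressure must be non-negative")
    if phase not in START_RATE:
        raise ValueError("phase must be 'diastole' or 'systole'")

    trace: list[tuple[float, float]] = []

    def f(rate: float) -> tuple[float, ContourStack]:
        rate = min(max(rate, 0.0), 0.5)
        shrunk = shrink_stack(stack, rate, axial_ratio * rate)
        ch = to_equivalent_chamber(shrunk)
        vol = inflate(ch, material, pressure).volume
        trace.append((rate, vol))
        return vol - target_volume, shrunk

    lo, hi = None, None  # bracket: f(lo) > 0 > f(hi)

    def note(rate, err):
        nonlocal lo, hi
        if err > 0 and (lo is None or rate > lo):
            lo = rate
        if err < 0 and (hi is None or rate < hi):
            hi = rate

    x0 = START_RATE[phase]
    e0, stack0 = f(x0)
    note(x0, e0)
    best = (abs(e0), x0, e0, stack0)
    if abs(e0) / target_volume < tol:
        return PreShrinkResult(stack0, 1, x0, abs(e0) / target_volume, phase,
                               trace, target_volume, pressure)
    x1 = min(x0 + 0.01, 0.5)
    for it in range(2, max_iter + 1):
        e1, stack1 = f(x1)
        note(x1, e1)
        if abs(e1) < best[0]:
            best = (abs(e1), x1, e1, stack1)
        if abs(e1) / target_volume < tol:
            return PreShrinkResult(stack1, it, x1, abs(e1) / target_volume,
                                   phase, trace, target_volume, pressure)
        if e1 == e0:
            x2 = 0.5 * (lo + hi) if (lo is not None and hi is not None) else x1 + 0.01
        else:
            x2 = x1 - e1 * (x1 - x0) / (e1 - e0)
        if not np.isfinite(x2):
            x2 = x1 + 0.01
        x2 = min(max(x2, 0.0), 0.5)
        if lo is not None and hi is not None and not (lo < x2 < hi) and x2 not in (0.0,):
            x2 = 0.5 * (lo + hi)
        if x2 == x1:  # clamped to the same point twice: done or stuck
            if x1 in (0.0, 0.5):
                err = abs(e1) / target_volume
                return PreShrinkResult(stack1, it, x1, err, phase, trace,
                                       target_volume, pressure)
            x2 = x1 + 1e-4
        x0, e0 = x1, e1
        x1 = x2
    raise ConvergenceError(
        f"pre-shrink did not converge in {max_iter} iterations "
        f"(best volume error {best[0] / target_volume:.3%})",
        best={"inner_rate": best[1], "volume_error": best[0] / target_volume},
        trace=trace)


def wall_volume_drift(stack: ContourStack, shrunk: ContourStack,
                      axial_rate: float = 0.0) -> float:
    """Relative wall-volume drift of a shrink, accounting for the axial rate."""
    v0 = geometry.wall_volume(stack) * (1.0 - axial_rate)
    v1 = geometry.wall_volume(shrunk)
    return abs(v1 - v0) / v0
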
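"""Contour-stack data model and geometric quantification.

A ventricle is represented as an ordered stack of short-axis slices, each
holding a closed inner (endocardial) and outer (epicardial) contour in cm.
From the stack the module computes the quantities used throughout the cohort
analysis: disk-summation ("Simpson", in the cardiology sense) cavity and wall
volumes, per-point wall thickness, circumferential and longitudinal curvature
(sliding-window least-squares circle fits), the equal-arc-length quarter
partition of a slice, and two-layer fiber direction fields.

Conventions: coordinates in cm; contours stored counter-clockwise with closure
implicit (first point is not repeated); the canonical parameterization is 100
points per contour at equal arc length with point 0 at the +x axis crossing;
z increases from base to apex.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from shapely.geometry import LinearRing, LineString, Point

from .errors import V2GError

N_CANONICAL = 100  # nodal points per slice used for all per-point quantities


# ---------------------------------------------------------------------------
# contours
# ---------------------------------------------------------------------------

def contour_area(points: np.ndarray) -> float:
    """Signed shoelace area (positive for counter-clockwise contours)."""
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def contour_perimeter(points: np.ndarray) -> float:
    p = np.asarray(points, dtype=float)
    d = np.diff(np.vstack([p, p[:1]]), axis=0)
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def ensure_ccw(points: np.ndarray) -> np.ndarray:
    p = np.asarray(points, dtype=float)
    return p if contour_area(p) >= 0 else p[::-1].copy()


def _canonical_start(points: np.ndarray) -> np.ndarray:
    """Rotate the point order so point 0 is the +x axis crossing (max x-x_c side)."""
    p = np.asarray(points, dtype=float)
    c = p.mean(axis=0)
    rel = p - c
    ang = np.arctan2(rel[:, 1], rel[:, 0])
    k = int(np.argmin(np.abs(((ang + np.pi) % (2 * np.pi)) - np.pi)))
    return np.roll(p, -k, axis=0)


def resample_contour(points: np.ndarray, n: int = N_CANONICAL,
                     canonical_start: bool = True) -> np.ndarray:
    """Resample a closed contour to n points at equal arc-length spacing.

    The total perimeter is preserved to well within 0.1 % for smooth contours.
    """
    if n < 8:
        raise ValueError("need n >= 8 points")
    p = ensure_ccw(np.asarray(points, dtype=float))
    if p.shape[0] < 3:
        raise V2GError("contour needs at least 3 points")
    closed = np.vstack([p, p[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    L = s[-1]
    if L <= 0:
        raise V2GError("degenerate contour with zero perimeter")
    t = np.linspace(0.0, L, n, endpoint=False)
    x = np.interp(t, s, closed[:, 0])
    y = np.interp(t, s, closed[:, 1])
    out = np.column_stack([x, y])
    return _canonical_start(out) if canonical_start else out


# ---------------------------------------------------------------------------
# slices and stacks
# ---------------------------------------------------------------------------

@dataclass
class VentricleSlice:
    """One short-axis slice: inner/outer closed contours (cm) at height z."""

    inner: np.ndarray
    outer: np.ndarray
    z: float

    def __post_init__(self):
        self.inner = ensure_ccw(np.asarray(self.inner, dtype=float))
        self.outer = ensure_ccw(np.asarray(self.outer, dtype=float))
        if abs(contour_area(self.inner)) >= abs(contour_area(self.outer)):
            raise V2GError("inner contour area must be smaller than outer")

    @property
    def wall_area(self) -> float:
        return contour_area(self.outer) - contour_area(self.inner)

    def resampled(self, n: int = N_CANONICAL) -> "VentricleSlice":
        return VentricleSlice(inner=resample_contour(self.inner, n),
                              outer=resample_contour(self.outer, n), z=self.z)


@dataclass
class ContourStack:
    """Ordered slices with slice spacing (cm) and a phase label."""

    slices: list[VentricleSlice]
    spacing: float | np.ndarray
    label: str = "in-vivo"

    def __post_init__(self):
        z = self.z
        if len(self.slices) >= 2 and np.any(np.diff(z) <= 0):
            raise V2GError("slice z positions must be strictly monotone")

    @property
    def z(self) -> np.ndarray:
        return np.array([s.z for s in self.slices])

    @property
    def spacings(self) -> np.ndarray:
        sp = np.asarray(self.spacing, dtype=float)
        if sp.ndim == 0:
            return np.full(len(self.slices), float(sp))
        if sp.size != len(self.slices):
            raise V2GError("per-slice spacing length mismatch")
        return sp

    def resampled(self, n: int = N_CANONICAL) -> "ContourStack":
        return ContourStack([s.resampled(n) for s in self.slices],
                            spacing=np.array(self.spacings), label=self.label)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: Sequence[float] = (0.0, 0.0, 0.0),
                    scale: float = 1.0) -> "ContourStack":
        """Rigid motion (in-plane rotation, 3D translation) plus uniform scale."""
        R = np.eye(2) if rotation is None else np.asarray(rotation, dtype=float)
        tx, ty, tz = translation
        new = []
        for s in self.slices:
            inner = (s.inner * scale) @ R.T + [tx, ty]
            outer = (s.outer * scale) @ R.T + [tx, ty]
            new.append(VentricleSlice(inner, outer, s.z * scale + tz))
        return ContourStack(new, spacing=self.spacings * scale, label=self.label)

    # ---- I/O -------------------------------------------------------------
    def to_json(self, path=None) -> str:
        doc = {
            "label": self.label,
            "spacing_cm": self.spacings.tolist(),
            "slices": [{"z": s.z,
                        "inner": np.asarray(s.inner).tolist(),
                        "outer": np.asarray(s.outer).tolist()}
                       for s in self.slices],
        }
        text = json.dumps(doc)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ContourStack":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        sp = doc["spacing_cm"]
        slices = [VentricleSlice(np.array(s["inner"]), np.array(s["outer"]),
                                 float(s["z"])) for s in doc["slices"]]
        return cls(slices, spacing=np.asarray(sp, dtype=float)
                   if np.ndim(sp) else float(sp),
                   label=doc.get("label", "in-vivo"))


@dataclass(frozen=True)
class FiberLayerSpec:
    """Two-layer helical fiber architecture relative to the circumferential axis.

    Defaults (-60 deg epicardial, +80 deg endocardial, split at half wall
    depth) are configuration values in the range reported for human hearts.
    """

    epi_angle_deg: float = -60.0
    endo_angle_deg: float = 80.0
    boundary_fraction: float = 0.5

    def __post_init__(self):
        for a in (self.epi_angle_deg, self.endo_angle_deg):
            if not (-90.0 < a <= 90.0):
                raise ValueError("fiber angles must be in (-90, 90] degrees")
        if not (0.0 < self.boundary_fraction < 1.0):
            raise ValueError("layer boundary fraction must be in (0, 1)")


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def stack_volume(stack: ContourStack,
                 surface: Literal["inner", "outer"] = "inner") -> float:
    """Disk-summation volume (cm^3): sum of slice areas times slice spacing."""
    if len(stack.slices) < 2:
        raise V2GError("need at least 2 slices for a volume")
    areas = np.array([abs(contour_area(getattr(s, surface)))
                      for s in stack.slices])
    return float(np.sum(areas * stack.spacings))


def wall_volume(stack: ContourStack) -> float:
    """Muscle volume between the outer and inner surfaces (cm^3)."""
    return stack_volume(stack, "outer") - stack_volume(stack, "inner")


# ---------------------------------------------------------------------------
# wall thickness
# ---------------------------------------------------------------------------

def _outward_normals(points: np.ndarray) -> np.ndarray:
    """Outward unit normals of a CCW closed contour (central differences)."""
    t = np.roll(points, -1, axis=0) - np.roll(points, 1, axis=0)
    n = np.column_stack([t[:, 1], -t[:, 0]])
    norm = np.hypot(n[:, 0], n[:, 1])
    norm[norm == 0] = 1.0
    return n / norm[:, None]


def wall_thickness(sl: VentricleSlice, n: int = N_CANONICAL):
    """Per-point wall thickness (cm) along the inner-contour normal.

    Thickness at each inner point is the distance to the first intersection of
    the outward normal ray with the outer contour; where the ray misses, the
    nearest-point distance is used and the point is flagged.

    Returns (thickness array, slice mean, miss flags).
    """
    s = sl.resampled(n)
    normals = _outward_normals(s.inner)
    ring = LinearRing(np.vstack([s.outer, s.outer[:1]]))
    span = 4.0 * np.sqrt(abs(contour_area(s.outer)))
    thick = np.empty(n)
    missed = np.zeros(n, dtype=bool)
    for i, (pt, nv) in enumerate(zip(s.inner, normals)):
        ray = LineString([pt, pt + span * nv])
        hit = ray.intersection(ring)
        if hit.is_empty:
            thick[i] = ring.distance(Point(pt))
            missed[i] = True
        else:
            pts = ([hit] if hit.geom_type == "Point"
                   else list(getattr(hit, "geoms", [])))
            ds = [np.hypot(g.x - pt[0], g.y - pt[1]) for g in pts
                  if g.geom_type == "Point"]
            if not ds:
                thick[i] = ring.distance(Point(pt))
                missed[i] = True
            else:
                thick[i] = min(ds)
    return thick, float(np.mean(thick)), missed


# ---------------------------------------------------------------------------
# curvature
# ---------------------------------------------------------------------------

def _circle_fit_curvature(xy: np.ndarray) -> float:
    """Unsigned curvature (1/cm) from an algebraic least-squares circle fit.

    Collinear (or nearly collinear) windows return 0.
    """
    x, y = xy[:, 0] - xy[:, 0].mean(), xy[:, 1] - xy[:, 1].mean()
    A = np.column_stack([x, y, np.ones_like(x)])
    b = x ** 2 + y ** 2
    try:
        sol, res, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    except np.linalg.LinAlgError:
        return 0.0
    if rank < 3:
        return 0.0
    cx, cy, c = sol[0] / 2.0, sol[1] / 2.0, sol[2]
    r2 = c + cx ** 2 + cy ** 2
    if r2 <= 0 or not np.isfinite(r2):
        return 0.0
    r = np.sqrt(r2)
    if r > 1e6:
        return 0.0
    return float(1.0 / r)


def circumferential_curvature(points: np.ndarray, window: int = 7):
    """Per-point unsigned in-slice curvature (1/cm) and mean.

    Sliding window of ``window`` points (cyclic) around each node, fit with a
    least-squares circle.
    """
    p = np.asarray(points, dtype=float)
    npts = p.shape[0]
    h = window // 2
    kappa = np.empty(npts)
    for i in range(npts):
        idx = (np.arange(i - h, i + h + 1)) % npts
        kappa[i] = _circle_fit_curvature(p[idx])
    return kappa, float(np.mean(kappa))


def longitudinal_curvature(stack: ContourStack, window: int = 5,
                           surface: Literal["inner", "outer"] = "inner"):
    """Per-point meridional curvature (1/cm) and mean.

    Meridians are the index-aligned point sequences across slices after
    canonical resampling; each meridian is projected into the (rho, z) plane
    through the long axis (rho = in-plane distance from the mean centroid
    axis) and fit with sliding-window circles.
    """
    if len(stack.slices) < 3:
        raise V2GError("need at least 3 slices for longitudinal curvature")
    rs = stack.resampled()
    pts = np.stack([getattr(s, surface) for s in rs.slices])  # (ns, np, 2)
    axis = pts.reshape(-1, 2).mean(axis=0)
    rho = np.hypot(pts[:, :, 0] - axis[0], pts[:, :, 1] - axis[1])  # (ns, np)
    z = rs.z
    ns, npts = rho.shape
    w = min(window, ns)
    if w < 3:
        w = 3
    h = w // 2
    kappa = np.empty((ns, npts))
    for j in range(npts):
        for i in range(ns):
            lo = max(0, min(i - h, ns - w))
            seg = np.column_stack([rho[lo:lo + w, j], z[lo:lo + w]])
            kappa[i, j] = _circle_fit_curvature(seg)
    return kappa, float(np.mean(kappa))


# ---------------------------------------------------------------------------
# quarter partition
# ---------------------------------------------------------------------------

def quarter_partition(sl: VentricleSlice, n: int = N_CANONICAL):
    """Split the slice into 4 contiguous index sets of equal inner arc length."""
    inner = resample_contour(sl.inner, n)
    closed = np.vstack([inner, inner[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])  # cum[i] = arc length to pt i
    L = cum[-1]
    bounds = [0]
    for q in (0.25, 0.5, 0.75):
        bounds.append(int(np.searchsorted(cum, q * L)))
    bounds.append(n)
    return [np.arange(bounds[k], bounds[k + 1]) for k in range(4)]


# ---------------------------------------------------------------------------
# fiber assignment
# ---------------------------------------------------------------------------

def assign_fibers(stack: ContourStack, spec: FiberLayerSpec | None = None):
    """Two-layer fiber unit vectors on the canonical inner-surface grid.

    For each slice point the local frame is (circumferential tangent t,
    longitudinal direction l, transmural normal n = t x l); the fiber of a
    layer lies in the (t, l) tangent plane at the layer's helix angle.

    Returns a dict with arrays of shape (n_slices, 100, 3):
    ``endo`` and ``epi`` fiber fields, plus ``transmural`` normals, and the
    wall-depth ``boundary_fraction`` separating the two layers.
    """
    spec = spec or FiberLayerSpec()
    rs = stack.resampled()
    pts = np.stack([s.inner for s in rs.slices])           # (ns, np, 2)
    z = rs.z
    ns, npts, _ = pts.shape
    p3 = np.concatenate([pts, np.broadcast_to(z[:, None, None], (ns, npts, 1))],
                        axis=2)

    # circumferential tangents (cyclic central differences, zero z-component)
    t = np.roll(p3, -1, axis=1) - np.roll(p3, 1, axis=1)
    t[:, :, 2] = 0.0
    t /= np.linalg.norm(t, axis=2, keepdims=True)

    # longitudinal direction: meridian slope, orthogonalized against t
    l = np.empty_like(p3)
    l[1:-1] = p3[2:] - p3[:-2]
    l[0] = p3[1] - p3[0]
    l[-1] = p3[-1] - p3[-2]
    l -= np.sum(l * t, axis=2, keepdims=True) * t
    norm = np.linalg.norm(l, axis=2, keepdims=True)
    if np.any(norm < 1e-12):
        raise V2GError("degenerate longitudinal direction")
    l /= norm

    n = np.cross(t, l)

    def fiber(angle_deg):
        a = np.deg2rad(angle_deg)
        f = np.cos(a) * t + np.sin(a) * l
        return f / np.linalg.norm(f, axis=2, keepdims=True)

    return {
        "endo": fiber(spec.endo_angle_deg),
        "epi": fiber(spec.epi_angle_deg),
        "transmural": n,
        "boundary_fraction": spec.boundary_fraction,
    }


# ---------------------------------------------------------------------------
# slice-level summary
# ---------------------------------------------------------------------------

def stack_metrics(stack: ContourStack) -> dict:
    """Mean WT, C-cur, L-cur and cavity volume of a stack (patient-level)."""
    rs = stack.resampled()
    wt = np.array([wall_thickness(s)[1] for s in rs.slices])
    cc = np.array([circumferential_curvature(s.inner)[1] for s in rs.slices])
    _, lc = longitudinal_curvature(rs)
    return {
        "WT": float(np.mean(wt)),
        "C-cur": float(np.mean(cc)),
        "L-cur": lc,
        "volume": stack_volume(rs, "inner"),
        "wall_volume": wall_volume(rs),
        "slice_WT": wt,
        "slice_Ccur": cc,
    }
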
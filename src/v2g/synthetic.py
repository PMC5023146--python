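"""Synthetic ventricle geometries and cohorts for simulation and testing.

Two generators make every part of the toolkit exercisable without imaging
data:

* ``generate_ventricle`` builds a truncated-ellipsoid two-wall contour stack
  (inner surface an ellipsoid, outer surface offset by the wall thickness)
  with optional radial contour noise -- the geometric substrate for volumes,
  thickness, curvature and pre-shrink.
* ``generate_cohort`` draws a two-group patient table shaped like the
  published begin-ejection cohort table: a group effect on stress (worse
  responders carry higher wall stress) and an ejection-fraction change built
  as a noisy decreasing function of stress.  It is a statistical test
  instrument, not a physiological model.

Both are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import V2GError
from .geometry import ContourStack, VentricleSlice

#: phase-stress ratios relative to begin-ejection stress, matching the
#: cohort-mean pattern of the published per-patient stress table
PHASE_RATIOS = {"BF": 7.17 / 108.41, "EF": 43.10 / 108.41,
                "BE": 1.0, "EE": 28.89 / 108.41}


@dataclass(frozen=True)
class SyntheticVentricleSpec:
    """Truncated-ellipsoid two-wall geometry.

    Default semi-axes and wall thickness give a chamber at the scale of a
    dilated right ventricle imaged in 12 short-axis slices of 100 points.
    """

    semi_axes: tuple[float, float, float] = (3.0, 2.5, 4.5)  # cm
    wall_thickness: float = 0.5                              # cm
    n_slices: int = 12
    points_per_slice: int = 100
    noise_sd: float = 0.0                                    # cm, radial
    truncation: float = 0.9   # fraction of the long semi-axis covered
    seed: int = 0

    def __post_init__(self):
        a, b, c = self.semi_axes
        if min(a, b, c) <= 0 or self.wall_thickness <= 0:
            raise ValueError("semi-axes and wall thickness must be positive")
        if self.wall_thickness >= min(a, b):
            raise V2GError("wall thickness must be smaller than the inner radii")
        if self.n_slices < 3:
            raise ValueError("need at least 3 slices")


def generate_ventricle(spec: SyntheticVentricleSpec | None = None,
                       **kwargs) -> ContourStack:
    """Build the contour stack for a synthetic ventricle.

    Slices are equidistant in z over ``truncation`` of the long axis, sampled
    at slice mid-heights so that disk summation integrates the shape well.
    """
    spec = spec or SyntheticVentricleSpec(**kwargs)
    a, b, c = spec.semi_axes
    h = spec.wall_thickness
    rng = np.random.default_rng(spec.seed)

    zmax = spec.truncation * c
    dz = 2.0 * zmax / spec.n_slices
    z_centers = -zmax + (np.arange(spec.n_slices) + 0.5) * dz
    theta = np.linspace(0.0, 2.0 * np.pi, spec.points_per_slice, endpoint=False)

    slices = []
    for z in z_centers:
        shrink = np.sqrt(max(1.0 - (z / c) ** 2, 1e-9))
        shrink_o = np.sqrt(max(1.0 - (z / (c + h)) ** 2, 1e-9))
        ri = np.column_stack([a * shrink * np.cos(theta),
                              b * shrink * np.sin(theta)])
        ro = np.column_stack([(a + h) * shrink_o * np.cos(theta),
                              (b + h) * shrink_o * np.sin(theta)])
        if spec.noise_sd > 0:
            ri *= (1.0 + spec.noise_sd * rng.standard_normal(len(theta))
                   )[:, None] / 1.0
            ro *= (1.0 + spec.noise_sd * rng.standard_normal(len(theta))
                   )[:, None] / 1.0
        slices.append(VentricleSlice(ri, ro, float(z)))
    return ContourStack(slices, spacing=dz, label="synthetic")


def truncated_ellipsoid_volume(semi_axes, truncation: float) -> float:
    """Analytic cavity volume of the truncated ellipsoid (oracle helper)."""
    a, b, c = semi_axes
    t = truncation
    # int_{-tc}^{tc} pi a b (1 - z^2/c^2) dz
    return float(np.pi * a * b * (2 * t * c - 2 * (t * c) ** 3 / (3 * c ** 2)))


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Two-group cohort with a planted stress effect.

    Defaults reproduce the published group structure: 8 + 8 patients, a
    begin-ejection stress ratio of ~1.6 between worse and better responders,
    and an EF-change correlation with stress near -0.6.
    """

    n_per_group: int = 8
    stress_mean_g1: float = 82.9         # kPa
    stress_ratio: float = 133.9 / 82.9   # group-2 / group-1 mean
    stress_sd: tuple[float, float] = (27.5, 31.4)
    def_corr: float = -0.609             # target corr(dEF, BE stress)
    def_mean: float = -4.9               # cohort-mean EF change (%)
    wt_mean: float = 0.49                # cm
    wt_sd: float = 0.11
    ccur_mean: float = 0.52              # 1/cm
    ccur_sd: float = 0.12
    lcur_mean: float = 1.27              # 1/cm
    lcur_sd: float = 0.44
    edv_mean: float = 345.0              # cm^3
    edv_sd: float = 130.0
    phase_noise_sd: float = 0.10         # lognormal-ish jitter on phase ratios
    seed: int = 0

    def __post_init__(self):
        if abs(self.def_corr) > 1.0:
            raise V2GError("correlation target must lie in [-1, 1]")
        if self.n_per_group < 2:
            raise ValueError("need at least 2 patients per group")


def generate_cohort(spec: SyntheticCohortSpec | None = None,
                    **kwargs) -> pd.DataFrame:
    """Draw a synthetic per-patient cohort table.

    Columns: group, Stress_BF/EF/BE/EE (kPa), WT, C-cur, L-cur, EDV, dEF.
    Group 2 stress is scaled by ``stress_ratio``; dEF is linear in the
    begin-ejection stress with Gaussian noise sized so the population
    correlation equals ``def_corr`` (zero slope when the target is 0).
    """
    spec = spec or SyntheticCohortSpec(**kwargs)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_group
    group = np.repeat([1, 2], n)

    mu = np.where(group == 1, spec.stress_mean_g1,
                  spec.stress_mean_g1 * spec.stress_ratio)
    sd = np.where(group == 1, spec.stress_sd[0], spec.stress_sd[1])
    stress_be = np.maximum(mu + sd * rng.standard_normal(2 * n), 1.0)

    phases = {}
    for ph, ratio in PHASE_RATIOS.items():
        jitter = np.exp(spec.phase_noise_sd * rng.standard_normal(2 * n))
        phases[f"Stress_{ph}"] = (stress_be if ph == "BE"
                                  else ratio * stress_be * jitter)

    if spec.def_corr == 0.0:
        dEF = spec.def_mean + 6.0 * rng.standard_normal(2 * n)
    else:
        sigma_s = float(np.std(stress_be))
        slope = np.sign(spec.def_corr) * 6.0 / max(sigma_s, 1e-9)
        sigma_e = (abs(slope) * sigma_s
                   * np.sqrt(max(1.0 / spec.def_corr ** 2 - 1.0, 0.0)))
        dEF = (spec.def_mean + slope * (stress_be - stress_be.mean())
               + sigma_e * rng.standard_normal(2 * n))

    df = pd.DataFrame({
        "group": group,
        **phases,
        "WT": np.maximum(spec.wt_mean + spec.wt_sd
                         * rng.standard_normal(2 * n), 0.1),
        "C-cur": np.maximum(spec.ccur_mean + spec.ccur_sd
                            * rng.standard_normal(2 * n), 0.05),
        "L-cur": np.maximum(spec.lcur_mean + spec.lcur_sd
                            * rng.standard_normal(2 * n), 0.1),
        "EDV": np.maximum(spec.edv_mean + spec.edv_sd
                          * rng.standard_normal(2 * n), 50.0),
        "dEF": dEF,
    })
    df.index = [f"S{i+1}" for i in range(2 * n)]
    df.index.name = "patient"
    return df


def cohort_predictor_matrix(cohort: pd.DataFrame) -> pd.DataFrame:
    """Predictor matrix (same 8 columns as the fixture pipeline) from a
    synthetic cohort table."""
    from .prediction import build_predictors

    stress = cohort.rename(columns={f"Stress_{ph}": f"2G-{ph}"
                                    for ph in PHASE_RATIOS})
    geom = cohort[["WT", "C-cur", "L-cur", "EDV", "group"]]
    return build_predictors(stress[["2G-BF", "2G-EF", "2G-BE", "2G-EE"]], geom)
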
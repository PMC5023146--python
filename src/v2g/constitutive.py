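"""Hyperelastic constitutive laws for ventricular tissue.

Implements the modified Mooney-Rivlin strain-energy functions used for the
ventricle wall (isotropic and transversely isotropic forms) and the Fung-type
exponential law expressed in the local fiber / cross-fiber / radial frame:

    W_iso   = c1 (I1 - 3) + c2 (I2 - 3) + D1 [exp(D2 (I1 - 3)) - 1]
    W_aniso = W_iso + K1/(2 K2) [exp(K2 (I4 - 1)^2) - 1]
    W_fung  = C/2 (exp(Q) - 1),
    Q = b1 Eff^2 + b2 (Ecc^2 + Err^2 + Ecr^2 + Erc^2)
             + b3 (Efc^2 + Ecf^2 + Efr^2 + Erf^2)

with I1, I2 the isotropic invariants of the right Cauchy-Green tensor C and
I4 = n_f . C n_f the squared fiber stretch.  The exponential terms are grouped
so that W and the Cauchy stress vanish identically at the reference state; the
alternative literal grouping exp(D2 (I1-3) - 1) (which does not vanish at
identity) is available through ``literal_grouping=True`` for comparison with
older formulations.

Incompressibility is enforced exactly through a Lagrange-pressure term fixed by
a traction-free direction, rather than a nearly-incompressible penalty.
All stresses are Cauchy stresses in kPa; stretches are dimensionless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

from .errors import InvalidDeformationError, ParameterRangeError, ConvergenceError

_EXP_MAX = 500.0  # exponent guard: exp args above this raise ParameterRangeError

Mode = Literal["equibiaxial", "uniaxial-fiber", "uniaxial-crossfiber"]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IsoMRParams:
    """Isotropic modified Mooney-Rivlin parameters (c1, c2, D1 in kPa)."""

    c1: float
    c2: float
    D1: float
    D2: float

    def __post_init__(self):
        if self.c1 < 0 or self.D1 < 0 or self.D2 < 0:
            raise ParameterRangeError("c1, D1, D2 must be non-negative")

    def scaled(self, factor: float) -> "IsoMRParams":
        """Scale all stress-like parameters by a common factor."""
        return replace(self, c1=self.c1 * factor, c2=self.c2 * factor,
                       D1=self.D1 * factor)

    def exponent_scaled(self, s: float) -> "IsoMRParams":
        """Scale the dimensionless stiffening exponent (curve-shape knob)."""
        return replace(self, D2=self.D2 * s)


@dataclass(frozen=True)
class AnisoMRParams:
    """Transversely isotropic Mooney-Rivlin: isotropic part + fiber term (K1 kPa, K2 -)."""

    iso: IsoMRParams
    K1: float
    K2: float

    def __post_init__(self):
        if self.K1 < 0 or self.K2 < 0:
            raise ParameterRangeError("K1 and K2 must be non-negative")

    def scaled(self, factor: float) -> "AnisoMRParams":
        return replace(self, iso=self.iso.scaled(factor), K1=self.K1 * factor)

    def exponent_scaled(self, s: float) -> "AnisoMRParams":
        return replace(self, iso=self.iso.exponent_scaled(s), K2=self.K2 * s)


@dataclass(frozen=True)
class FungParams:
    """Fung-type exponential law in fiber coordinates (C_f in kPa; b1..b3 -)."""

    C_f: float
    b1: float
    b2: float
    b3: float

    def __post_init__(self):
        if self.C_f < 0:
            raise ParameterRangeError("C_f must be non-negative")

    def scaled(self, factor: float) -> "FungParams":
        return replace(self, C_f=self.C_f * factor)

    def exponent_scaled(self, s: float) -> "FungParams":
        return replace(self, b1=self.b1 * s, b2=self.b2 * s, b3=self.b3 * s)


MaterialParams = IsoMRParams | AnisoMRParams | FungParams


def _as_aniso(p: IsoMRParams | AnisoMRParams) -> AnisoMRParams:
    if isinstance(p, IsoMRParams):
        return AnisoMRParams(iso=p, K1=0.0, K2=1.0)
    return p


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeformationState:
    """Deformation gradient F with an attached reference fiber direction.

    ``C = F^T F`` and ``E = (C - I)/2`` are derived on construction.
    """

    F: np.ndarray
    fiber_dir: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    C: np.ndarray = field(init=False)
    E: np.ndarray = field(init=False)

    def __post_init__(self):
        F = np.asarray(self.F, dtype=float)
        if F.shape != (3, 3):
            raise InvalidDeformationError("F must be 3x3")
        J = np.linalg.det(F)
        if J <= 0:
            raise InvalidDeformationError(f"det F = {J:.3g} <= 0")
        n = np.asarray(self.fiber_dir, dtype=float)
        nn = np.linalg.norm(n)
        if not np.isclose(nn, 1.0, atol=1e-6):
            if nn == 0:
                raise InvalidDeformationError("fiber_dir must be non-zero")
            n = n / nn
        C = F.T @ F
        object.__setattr__(self, "F", F)
        object.__setattr__(self, "fiber_dir", n)
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "E", (C - np.eye(3)) / 2.0)

    @property
    def J(self) -> float:
        return float(np.linalg.det(self.F))

    @property
    def is_incompressible(self) -> bool:
        return abs(self.J - 1.0) < 1e-8


def _check_spd(C: np.ndarray) -> np.ndarray:
    C = np.asarray(C, dtype=float)
    if C.shape != (3, 3):
        raise InvalidDeformationError("C must be 3x3")
    if not np.allclose(C, C.T, atol=1e-8):
        raise InvalidDeformationError("C must be symmetric")
    if np.any(np.linalg.eigvalsh(C) <= 0):
        raise InvalidDeformationError("C must be positive definite")
    return C


def strain_invariants(state: DeformationState | np.ndarray,
                      fiber_dir: np.ndarray | None = None):
    """Return (I1, I2, I4) of the right Cauchy-Green tensor.

    I1 = tr C, I2 = (I1^2 - tr C^2)/2, I4 = n_f . C n_f.
    Accepts either a DeformationState or a raw SPD tensor C plus fiber_dir.
    """
    if isinstance(state, DeformationState):
        C, n = state.C, state.fiber_dir
        _check_spd(C)
    else:
        C = _check_spd(state)
        n = np.asarray(fiber_dir if fiber_dir is not None else [1.0, 0, 0], float)
        n = n / np.linalg.norm(n)
    I1 = float(np.trace(C))
    I2 = float((I1 ** 2 - np.trace(C @ C)) / 2.0)
    I4 = float(n @ C @ n)
    return I1, I2, I4


# ---------------------------------------------------------------------------
# strain-energy densities
# ---------------------------------------------------------------------------

def _safe_exp(x):
    if np.any(np.asarray(x) > _EXP_MAX):
        raise ParameterRangeError(
            f"exponential overflow (exponent {np.max(x):.3g}); "
            "parameters or stretch range out of admissible range")
    return np.exp(x)


def energy_iso(p: IsoMRParams, I1: float, I2: float,
               literal_grouping: bool = False) -> float:
    """Isotropic Mooney-Rivlin energy density (kPa)."""
    if literal_grouping:
        expo = _safe_exp(p.D2 * (I1 - 3.0) - 1.0)
        return p.c1 * (I1 - 3.0) + p.c2 * (I2 - 3.0) + p.D1 * expo
    return (p.c1 * (I1 - 3.0) + p.c2 * (I2 - 3.0)
            + p.D1 * (_safe_exp(p.D2 * (I1 - 3.0)) - 1.0))


def energy_aniso(p: AnisoMRParams, I1: float, I2: float, I4: float,
                 literal_grouping: bool = False) -> float:
    """Transversely isotropic Mooney-Rivlin energy density (kPa)."""
    if I4 <= 0:
        raise InvalidDeformationError("I4 must be positive")
    w = energy_iso(p.iso, I1, I2, literal_grouping=literal_grouping)
    if p.K2 == 0.0:
        # K2 -> 0 limit of K1/(2 K2) [exp(K2 (I4-1)^2) - 1]
        return w + 0.5 * p.K1 * (I4 - 1.0) ** 2
    if literal_grouping:
        return w + p.K1 / (2.0 * p.K2) * _safe_exp(p.K2 * (I4 - 1.0) ** 2 - 1.0)
    return w + p.K1 / (2.0 * p.K2) * (_safe_exp(p.K2 * (I4 - 1.0) ** 2) - 1.0)


def fung_Q(p: FungParams, E: np.ndarray) -> float:
    """Quadratic form Q of the Fung law; E in fiber (f, c, r) coordinates."""
    E = np.asarray(E, dtype=float)
    return float(
        p.b1 * E[0, 0] ** 2
        + p.b2 * (E[1, 1] ** 2 + E[2, 2] ** 2 + E[1, 2] ** 2 + E[2, 1] ** 2)
        + p.b3 * (E[0, 1] ** 2 + E[1, 0] ** 2 + E[0, 2] ** 2 + E[2, 0] ** 2)
    )


def energy_fung(p: FungParams, E: np.ndarray) -> float:
    """Fung energy density W = C/2 (exp(Q) - 1) (kPa); E in fiber coordinates."""
    return 0.5 * p.C_f * (_safe_exp(fung_Q(p, E)) - 1.0)


def energy(p: MaterialParams, state: DeformationState,
           literal_grouping: bool = False) -> float:
    """Energy density for any supported law at a deformation state."""
    if isinstance(p, FungParams):
        # state.E is assumed expressed in the fiber frame (f, c, r axes)
        return energy_fung(p, state.E)
    I1, I2, I4 = strain_invariants(state)
    if isinstance(p, AnisoMRParams):
        return energy_aniso(p, I1, I2, I4, literal_grouping=literal_grouping)
    return energy_iso(p, I1, I2, literal_grouping=literal_grouping)


# ---------------------------------------------------------------------------
# Cauchy stress (incompressible, Lagrange pressure from a traction-free dir)
# ---------------------------------------------------------------------------

def _mr_derivatives(p: AnisoMRParams, I1: float, I4: float):
    """(W1, W2, W4) = dW/dI1, dW/dI2, dW/dI4 for the Mooney-Rivlin laws."""
    W1 = p.iso.c1 + p.iso.D1 * p.iso.D2 * _safe_exp(p.iso.D2 * (I1 - 3.0))
    W2 = p.iso.c2
    if p.K2 == 0.0:
        W4 = p.K1 * (I4 - 1.0)
    else:
        W4 = p.K1 * (I4 - 1.0) * _safe_exp(p.K2 * (I4 - 1.0) ** 2)
    return W1, W2, W4


def _fung_second_pk(p: FungParams, E: np.ndarray) -> np.ndarray:
    """S = dW/dE for the Fung law (fiber coordinates)."""
    Q = fung_Q(p, E)
    dQ = np.zeros((3, 3))
    dQ[0, 0] = 2.0 * p.b1 * E[0, 0]
    for (i, j) in [(1, 1), (2, 2), (1, 2), (2, 1)]:
        dQ[i, j] = 2.0 * p.b2 * E[i, j]
    for (i, j) in [(0, 1), (1, 0), (0, 2), (2, 0)]:
        dQ[i, j] = 2.0 * p.b3 * E[i, j]
    return 0.5 * p.C_f * _safe_exp(Q) * dQ


def cauchy_stress(p: MaterialParams, state: DeformationState,
                  traction_free_dir: np.ndarray | str = "z",
                  literal_grouping: bool = False) -> np.ndarray:
    """Cauchy stress tensor (kPa) for an incompressible deformation.

    The Lagrange pressure is fixed so that the normal stress along
    ``traction_free_dir`` (a current-configuration unit vector, or one of
    "x", "y", "z") vanishes.
    """
    if not state.is_incompressible:
        raise InvalidDeformationError(
            f"cauchy_stress requires det F = 1 (got {state.J:.6g})")
    F = state.F
    if isinstance(traction_free_dir, str):
        n = {"x": [1.0, 0, 0], "y": [0, 1.0, 0], "z": [0, 0, 1.0]}[traction_free_dir]
    else:
        n = traction_free_dir
    n = np.asarray(n, dtype=float)
    n = n / np.linalg.norm(n)

    if isinstance(p, FungParams):
        S = _fung_second_pk(p, state.E)
        sig = F @ S @ F.T  # J = 1
    else:
        pa = _as_aniso(p)
        I1, I2, I4 = strain_invariants(state)
        W1, W2, W4 = _mr_derivatives(pa, I1, I4)
        if literal_grouping:
            # derivatives of the literal-grouping energy
            W1 = (pa.iso.c1
                  + pa.iso.D1 * pa.iso.D2 * _safe_exp(pa.iso.D2 * (I1 - 3.0) - 1.0))
            if pa.K2 != 0.0:
                W4 = pa.K1 * (I4 - 1.0) * _safe_exp(pa.K2 * (I4 - 1.0) ** 2 - 1.0)
        B = F @ F.T
        f_cur = F @ state.fiber_dir  # pushed-forward fiber (length sqrt(I4))
        sig = (2.0 * (W1 + I1 * W2) * B - 2.0 * W2 * (B @ B)
               + 2.0 * W4 * np.outer(f_cur, f_cur))
    pressure = float(n @ sig @ n)
    sig = sig - pressure * np.eye(3)
    return 0.5 * (sig + sig.T)


# ---------------------------------------------------------------------------
# stress-stretch curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StressStretchCurve:
    """Fiber (T_ff) and cross-fiber (T_cc) Cauchy stress vs stretch."""

    stretch: np.ndarray
    T_ff: np.ndarray
    T_cc: np.ndarray
    mode: Mode


def _deformation_for_mode(lam: float, mode: Mode,
                          p: MaterialParams) -> tuple[DeformationState, str, str]:
    """Incompressible F for a test mode.  Fiber is always along x.

    Returns (state, fiber stress axis, cross-fiber stress axis).
    For the uniaxial cross-fiber mode of an anisotropic material the two
    transverse directions are inequivalent, so the transverse split is solved
    so that both unloaded directions are traction-free.
    """
    if mode == "equibiaxial":
        F = np.diag([lam, lam, lam ** -2])
        return DeformationState(F), "x", "y"
    if mode == "uniaxial-fiber":
        t = lam ** -0.5
        F = np.diag([lam, t, t])
        return DeformationState(F), "x", "y"
    if mode == "uniaxial-crossfiber":
        # stretch along y; solve mu = lambda_x so that sigma_xx = sigma_zz = 0
        def resid(mu):
            F = np.diag([mu, lam, 1.0 / (lam * mu)])
            sig = cauchy_stress(p, DeformationState(F), traction_free_dir="z")
            return sig[0, 0]

        if isinstance(p, IsoMRParams) or (isinstance(p, AnisoMRParams) and p.K1 == 0):
            mu = lam ** -0.5
        else:
            try:
                mu = optimize.brentq(resid, 0.2, max(1.05, lam ** -0.25 * 1.5),
                                     xtol=1e-12)
            except ValueError:
                mu = lam ** -0.5
        F = np.diag([mu, lam, 1.0 / (lam * mu)])
        return DeformationState(F), "x", "y"
    raise ValueError(f"unknown mode {mode!r}")


def stress_stretch_curve(p: MaterialParams, mode: Mode,
                         stretches: Sequence[float]) -> StressStretchCurve:
    """Evaluate T_ff / T_cc over an ascending stretch grid (lambda >= 1)."""
    lams = np.asarray(stretches, dtype=float)
    if lams.ndim != 1 or lams.size == 0:
        raise ValueError("stretch grid must be a non-empty 1-D array")
    if lams.size > 1 and np.any(np.diff(lams) <= 0):
        raise ValueError("stretch grid must be strictly ascending")
    if lams[0] < 1.0:
        raise ValueError("stretch grid must start at lambda >= 1")
    ax = {"x": 0, "y": 1, "z": 2}
    T_ff = np.empty_like(lams)
    T_cc = np.empty_like(lams)
    for k, lam in enumerate(lams):
        state, fa, ca = _deformation_for_mode(float(lam), mode, p)
        sig = cauchy_stress(p, state, traction_free_dir="z")
        T_ff[k] = sig[ax[fa], ax[fa]]
        T_cc[k] = sig[ax[ca], ax[ca]]
    return StressStretchCurve(stretch=lams, T_ff=T_ff, T_cc=T_cc, mode=mode)


# ---------------------------------------------------------------------------
# fitting the Mooney-Rivlin form to Fung-law target curves
# ---------------------------------------------------------------------------

def fit_aniso_to_fung(target: FungParams | AnisoMRParams,
                      lam_range: tuple[float, float] = (1.0, 1.3),
                      n_points: int = 25,
                      modes: Sequence[Mode] = ("equibiaxial",),
                      n_starts: int = 3,
                      seed: int = 0) -> tuple[AnisoMRParams, float]:
    """Least-squares fit of AnisoMRParams to stress-stretch curves of ``target``.

    Returns (fitted parameters, RMS stress residual in kPa).  Multi-start
    bounded least squares (fixed seeds) to avoid local minima; on optimizer
    failure the best-so-far parameters are returned.
    """
    lams = np.linspace(lam_range[0], lam_range[1], n_points)
    targets = [stress_stretch_curve(target, m, lams) for m in modes]
    y = np.concatenate([np.concatenate([c.T_ff, c.T_cc]) for c in targets])
    scale = max(float(np.max(np.abs(y))), 1e-12)

    def unpack(theta):
        c1, c2, D1, D2, K1, K2 = np.abs(theta)
        return AnisoMRParams(iso=IsoMRParams(c1, c2, D1, D2), K1=K1, K2=max(K2, 1e-9))

    def resid(theta):
        try:
            p = unpack(theta)
            model = [stress_stretch_curve(p, m, lams) for m in modes]
        except ParameterRangeError:
            return np.full_like(y, 1e6)
        yp = np.concatenate([np.concatenate([c.T_ff, c.T_cc]) for c in model])
        return yp - y

    rng = np.random.default_rng(seed)
    starts = [np.array([0.2 * scale, 0.05 * scale, 0.05 * scale, 2.0,
                        0.2 * scale, 1.0])]
    for _ in range(max(0, n_starts - 1)):
        starts.append(starts[0] * rng.uniform(0.2, 3.0, size=6))

    best_theta, best_cost = None, np.inf
    for x0 in starts:
        try:
            sol = optimize.least_squares(resid, x0, method="trf",
                                         bounds=(0.0, np.inf),
                                         xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if sol.cost < best_cost:
            best_cost, best_theta = sol.cost, sol.x
    if best_theta is None:
        raise ConvergenceError("least-squares fit failed from every start")
    p_fit = unpack(best_theta)
    rms = float(np.sqrt(np.mean(resid(best_theta) ** 2)))
    return p_fit, rms


# ---------------------------------------------------------------------------
# material-set I/O
# ---------------------------------------------------------------------------

#: Default parameter sets (kPa).  These are package configuration defaults at
#: physiologically plausible stiffness scales; per-patient values are always
#: obtained by calibration against measured volumes (see ``calibrate``).
DEFAULT_MATERIALS: dict[str, MaterialParams] = {
    "ventricle_diastole": AnisoMRParams(iso=IsoMRParams(2.0, 0.5, 0.5, 1.8),
                                        K1=4.0, K2=1.2),
    "ventricle_systole": AnisoMRParams(iso=IsoMRParams(10.0, 2.0, 2.0, 2.2),
                                       K1=15.0, K2=1.5),
    "patch": IsoMRParams(50.0, 10.0, 10.0, 2.0),
    "scar": IsoMRParams(20.0, 5.0, 5.0, 2.0),
}


def material_to_dict(p: MaterialParams) -> dict:
    if isinstance(p, AnisoMRParams):
        return {"type": "aniso_mr", "c1": p.iso.c1, "c2": p.iso.c2,
                "D1": p.iso.D1, "D2": p.iso.D2, "K1": p.K1, "K2": p.K2}
    if isinstance(p, IsoMRParams):
        return {"type": "iso_mr", "c1": p.c1, "c2": p.c2, "D1": p.D1, "D2": p.D2}
    return {"type": "fung", "C_f": p.C_f, "b1": p.b1, "b2": p.b2, "b3": p.b3}


def material_from_dict(d: dict) -> MaterialParams:
    kind = d.get("type", "aniso_mr")
    if kind == "iso_mr":
        return IsoMRParams(d["c1"], d["c2"], d["D1"], d["D2"])
    if kind == "aniso_mr":
        return AnisoMRParams(iso=IsoMRParams(d["c1"], d["c2"], d["D1"], d["D2"]),
                             K1=d["K1"], K2=d["K2"])
    if kind == "fung":
        return FungParams(d["C_f"], d["b1"], d["b2"], d["b3"])
    raise ValueError(f"unknown material type {kind!r}")


def load_materials(path) -> dict[str, MaterialParams]:
    """Read a JSON file of named parameter sets."""
    with open(path) as fh:
        raw = json.load(fh)
    return {name: material_from_dict(d) for name, d in raw.items()}


def save_materials(materials: dict[str, MaterialParams], path) -> None:
    with open(path, "w") as fh:
        json.dump({k: material_to_dict(v) for k, v in materials.items()}, fh,
                  indent=2)
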
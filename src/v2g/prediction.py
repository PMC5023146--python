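"""Outcome prediction: ridge-logistic regression with repeated 2-fold CV.

Eight candidate predictors are evaluated for the binary post-PVR outcome
group: wall thickness (WT), circumferential and longitudinal curvature
(C-cur, L-cur), RV end-diastolic volume (V), begin-ejection stress (StressE)
and the three stress differences StressE-D (begin-ejection minus end-filling),
StressE-F (minus end-ejection) and StressE-C (minus begin-filling).

Every non-empty subset of the 8 predictors (255 subsets) is scored by
logistic regression under stratified 2-fold cross-validation repeated 20
times; held-out probabilities are pooled per repeat, the per-repeat AUC and
optimal (Youden) cutoff are averaged, and the whole procedure is repeated for
100 rounds to form the AUC average and a 95 % percentile confidence interval.

The logistic fit is a small Newton / IRLS solver with a ridge penalty
(lambda = 1e-3 on standardized predictors, intercept unpenalized): several
subsets separate the 16 patients perfectly, and the penalty keeps the
maximum-likelihood problem well-posed.  The solver is written in-package for
speed (the full ranking performs ~10^6 fits); it is cross-checked against an
independent maximum-likelihood implementation in the test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConvergenceError, V2GError

PREDICTORS = ("WT", "C-cur", "L-cur", "V",
              "StressE", "StressE-D", "StressE-F", "StressE-C")


# ---------------------------------------------------------------------------
# predictor matrix
# ---------------------------------------------------------------------------

def build_predictors(stress_table: pd.DataFrame,
                     geometry_table: pd.DataFrame) -> pd.DataFrame:
    """Assemble the 8-predictor matrix plus the outcome column ``group``.

    ``stress_table`` must hold per-patient 2G phase stresses in columns
    ``2G-BF``, ``2G-EF``, ``2G-BE``, ``2G-EE`` (kPa); ``geometry_table`` must
    hold ``WT``, ``C-cur``, ``L-cur``, ``EDV`` and ``group``.  Both are
    indexed by patient and must cover the same patients.
    """
    missing = set(stress_table.index) ^ set(geometry_table.index)
    if missing:
        raise V2GError(f"patient mismatch between tables: {sorted(missing)}")
    s = stress_table.loc[geometry_table.index]
    X = pd.DataFrame(index=geometry_table.index)
    X["WT"] = geometry_table["WT"]
    X["C-cur"] = geometry_table["C-cur"]
    X["L-cur"] = geometry_table["L-cur"]
    X["V"] = geometry_table["EDV"]
    X["StressE"] = s["2G-BE"]
    X["StressE-D"] = s["2G-BE"] - s["2G-EF"]
    X["StressE-F"] = s["2G-BE"] - s["2G-EE"]
    X["StressE-C"] = s["2G-BE"] - s["2G-BF"]
    if X.isna().any().any():
        raise V2GError("missing predictor values")
    X["group"] = geometry_table["group"].astype(int)
    return X


# ---------------------------------------------------------------------------
# logistic regression (ridge IRLS)
# ---------------------------------------------------------------------------

def _penalized_loglik(A, y, beta, D):
    eta = A @ beta
    eta = np.minimum(np.maximum(eta, -30.0), 30.0)
    ll = np.sum(y * eta - np.log(1.0 + np.exp(eta)))
    return ll - 0.5 * beta @ (D @ beta)


def _irls_core(A, y, ridge, max_iter, tol):
    n, m = A.shape
    D = np.eye(m) * ridge
    D[0, 0] = 0.0  # intercept unpenalized
    beta = np.zeros(m)
    grad = np.zeros(m)
    ll = _penalized_loglik(A, y, beta, D)
    for _ in range(max_iter):
        eta = A @ beta
        eta = np.minimum(np.maximum(eta, -30.0), 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = A.T @ (y - mu) - D @ beta
        W = mu * (1.0 - mu)
        H = (A * W.reshape(n, 1)).T @ A + D + 1e-12 * np.eye(m)
        step = np.linalg.solve(H, grad)
        # step-halving: near-separable folds make the full Newton step overshoot
        t = 1.0
        for _half in range(25):
            cand = beta + t * step
            ll_new = _penalized_loglik(A, y, cand, D)
            if ll_new >= ll - 1e-14:
                break
            t *= 0.5
        beta = beta + t * step
        ll = _penalized_loglik(A, y, beta, D)
        if np.max(np.abs(step)) * t < tol:
            break
    return beta, grad


try:  # JIT the Newton loop when numba is available (the full subset ranking
    import numba  # performs ~10^6 fits); the pure-numpy path is equivalent

    _penalized_loglik = numba.njit(cache=True)(_penalized_loglik)
    _irls_core_jit = numba.njit(cache=True)(_irls_core)
except Exception:  # pragma: no cover - numba present in supported envs
    _irls_core_jit = None


def fit_logistic(X: np.ndarray, y: np.ndarray, ridge: float = 1e-3,
                 max_iter: int = 100, tol: float = 1e-10) -> np.ndarray:
    """Penalized-ML logistic coefficients by damped Newton (IRLS).

    X: (n, k) design without intercept (columns should be standardized);
    y: binary 0/1.  Returns coefficients [intercept, beta_1..beta_k]; the
    intercept is unpenalized.  Raises ConvergenceError with the gradient norm
    when Newton stalls.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    n, k = X.shape
    A = np.column_stack([np.ones(n), X])
    core = _irls_core_jit if _irls_core_jit is not None else _irls_core
    beta, grad = core(A, y, float(ridge), int(max_iter), float(tol))
    if np.linalg.norm(grad) > 1e-4 * (1.0 + np.linalg.norm(beta)):
        raise ConvergenceError(
            f"IRLS did not converge (|grad| = {np.linalg.norm(grad):.3g})")
    return beta


def predict_proba(beta: np.ndarray, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    eta = np.clip(beta[0] + X @ beta[1:], -30.0, 30.0)
    return 1.0 / (1.0 + np.exp(-eta))


# ---------------------------------------------------------------------------
# ROC quantities
# ---------------------------------------------------------------------------

def auc(scores, labels) -> float:
    """AUC by the Mann-Whitney formulation; ties count one half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos, neg = s[y == 1], s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise V2GError("AUC undefined with a single class")
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0))
                 / (pos.size * neg.size))


def optimal_cutoff(scores, labels) -> tuple[float, float, float]:
    """Probability cutoff maximizing sensitivity + specificity (Youden).

    Candidate cutoffs are midpoints between adjacent distinct scores (plus
    open ends); ties are broken toward the higher specificity (higher cutoff).
    Returns (cutoff, sensitivity, specificity).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if y.min() == y.max():
        raise V2GError("cutoff undefined with a single class")
    uniq = np.unique(s)
    cands = np.concatenate([[uniq[0] - 1.0],
                            (uniq[:-1] + uniq[1:]) / 2.0,
                            [uniq[-1] + 1.0]])
    pred = s[None, :] > cands[:, None]
    sens = (pred & (y == 1)).sum(axis=1) / np.sum(y == 1)
    spec = (~pred & (y == 0)).sum(axis=1) / np.sum(y == 0)
    youden = sens + spec
    # argmax over (youden, spec, cutoff), ties toward higher specificity
    order = np.lexsort((cands, spec, youden))
    i = order[-1]
    return float(cands[i]), float(sens[i]), float(spec[i])


# ---------------------------------------------------------------------------
# repeated cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVConfig:
    """Protocol: 2-fold CV, 20 repeats per round, 100 rounds."""

    folds: int = 2
    repeats: int = 20
    rounds: int = 100
    base_seed: int = 0
    stratified: bool = True
    ridge: float = 1e-3
    pooling: str = "repeat"  # "repeat": pool held-out scores; "fold": avg AUCs

    def __post_init__(self):
        if self.folds < 2 or self.repeats < 1 or self.rounds < 1:
            raise ValueError("need folds >= 2, repeats >= 1, rounds >= 1")
        if self.pooling not in ("repeat", "fold"):
            raise ValueError("pooling must be 'repeat' or 'fold'")


def _fold_assignment(y: np.ndarray, folds: int, rng: np.random.Generator,
                     stratified: bool) -> np.ndarray:
    n = y.size
    assign = np.empty(n, dtype=int)
    if stratified:
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            for f in range(folds):
                assign[idx[f::folds]] = f
    else:
        idx = rng.permutation(n)
        for f in range(folds):
            assign[idx[f::folds]] = f
        # a fold with a single class cannot be scored: re-draw
        for _ in range(100):
            ok = all(np.unique(y[assign == f]).size == 2 for f in range(folds))
            if ok:
                break
            idx = rng.permutation(n)
            for f in range(folds):
                assign[idx[f::folds]] = f
    return assign


def _standardize(train: np.ndarray, test: np.ndarray):
    m = train.mean(axis=0)
    s = train.std(axis=0, ddof=0)
    s[s == 0] = 1.0
    return (train - m) / s, (test - m) / s


def _one_round(X: np.ndarray, y: np.ndarray, cfg: CVConfig,
               rng: np.random.Generator):
    """Return (AUC, cutoff, sens, spec) averaged over the round's repeats."""
    aucs, cuts, sens_l, spec_l = [], [], [], []
    n = y.size
    for _ in range(cfg.repeats):
        assign = _fold_assignment(y, cfg.folds, rng, cfg.stratified)
        pooled = np.empty(n)
        fold_aucs = []
        for f in range(cfg.folds):
            test = assign == f
            Xtr, Xte = _standardize(X[~test], X[test])
            beta = fit_logistic(Xtr, y[~test], ridge=cfg.ridge)
            pooled[test] = predict_proba(beta, Xte)
            if cfg.pooling == "fold":
                fold_aucs.append(auc(pooled[test], y[test]))
        if cfg.pooling == "repeat":
            aucs.append(auc(pooled, y))
        else:
            aucs.append(float(np.mean(fold_aucs)))
        c, se, sp = optimal_cutoff(pooled, y)
        cuts.append(c)
        sens_l.append(se)
        spec_l.append(sp)
    return (float(np.mean(aucs)), float(np.mean(cuts)),
            float(np.mean(sens_l)), float(np.mean(spec_l)))


@dataclass
class SubsetCV:
    """CV report row for one predictor subset (cutoff, sens/spec, AUC, CI)."""

    subset: tuple[str, ...]
    auc: float            # single-run (first round) CV AUC
    auc_mean: float       # average over rounds
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    rank: int | None = None
    round_aucs: np.ndarray = field(default_factory=lambda: np.empty(0),
                                   repr=False)

    @property
    def sens_plus_spec(self) -> float:
        return self.sensitivity + self.specificity


def repeated_cv(X: pd.DataFrame | np.ndarray, y, subset=None,
                cfg: CVConfig = CVConfig()) -> SubsetCV:
    """Score one predictor subset under the repeated-CV protocol.

    Deterministic given ``cfg.base_seed``: round r uses generator seed
    base_seed + r.
    """
    if isinstance(X, pd.DataFrame):
        cols = list(subset) if subset else [c for c in X.columns if c != "group"]
        Xa = X[cols].to_numpy(dtype=float)
        names = tuple(cols)
    else:
        Xa = np.asarray(X, dtype=float)
        if subset is not None:
            Xa = Xa[:, list(subset)]
            names = tuple(str(i) for i in subset)
        else:
            names = tuple(str(i) for i in range(Xa.shape[1]))
    if Xa.ndim == 1:
        Xa = Xa[:, None]
    ya = np.asarray(y).astype(int)
    ya = (ya == ya.max()).astype(int) if set(np.unique(ya)) != {0, 1} else ya

    stats = [_one_round(Xa, ya, cfg,
                        np.random.default_rng(cfg.base_seed + r))
             for r in range(cfg.rounds)]
    round_aucs = np.array([s[0] for s in stats])
    lo, hi = np.percentile(round_aucs, [2.5, 97.5])
    return SubsetCV(
        subset=names,
        auc=float(round_aucs[0]),
        auc_mean=float(round_aucs.mean()),
        ci_low=float(lo), ci_high=float(hi),
        cutoff=float(np.mean([s[1] for s in stats])),
        sensitivity=float(np.mean([s[2] for s in stats])),
        specificity=float(np.mean([s[3] for s in stats])),
        round_aucs=round_aucs)


def rank_combinations(X: pd.DataFrame, y=None,
                      cfg: CVConfig = CVConfig(),
                      predictors=PREDICTORS) -> pd.DataFrame:
    """Score all non-empty predictor subsets and rank by AUC average.

    Returns a DataFrame with one row per subset (2^k - 1 rows), ranked 1..N
    by descending AUC average.
    """
    if y is None:
        if "group" not in X.columns:
            raise V2GError("outcome column 'group' missing")
        y = (X["group"].to_numpy(dtype=int) ==
             X["group"].to_numpy(dtype=int).max()).astype(int)
    rows = []
    for k in range(1, len(predictors) + 1):
        for combo in itertools.combinations(predictors, k):
            r = repeated_cv(X, y, subset=combo, cfg=cfg)
            rows.append({
                "subset": "+".join(combo), "n_predictors": k,
                "cutoff": r.cutoff, "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "sens_plus_spec": r.sens_plus_spec,
                "auc": r.auc, "auc_mean": r.auc_mean,
                "ci_low": r.ci_low, "ci_high": r.ci_high,
            })
    df = pd.DataFrame(rows).sort_values("auc_mean", ascending=False)
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)
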
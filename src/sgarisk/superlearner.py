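"""Cross-validated convex ensemble (Super Learner) for probability regressions.

The ensemble minimises cross-validated negative Bernoulli log-likelihood over
the probability simplex spanned by a fixed learner library.  Targets may be
fractional (iterated conditional expectations live in [0, 1]), so every
learner is a regression onto [0, 1] and the loss is quasi-binomial.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit as _expit

log = logging.getLogger(__name__)

CLIP = 1e-6
LEARNER_NAMES = ("mean", "linear", "logistic", "cart", "random_forest",
                 "neural_net", "saturated")


def _clip(p: np.ndarray, lo: float = CLIP) -> np.ndarray:
    return np.clip(p, lo, 1.0 - lo)


def bernoulli_loss(y: np.ndarray, p: np.ndarray) -> float:
    """Mean negative Bernoulli log-likelihood; valid for fractional y."""
    p = _clip(np.asarray(p, dtype=float))
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def fit_logistic(X: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None,
                 max_iter: int = 40, ridge: float = 1e-8) -> np.ndarray:
    """IRLS logistic fit with an intercept column appended; returns coefficients.

    Accepts fractional responses and optional case weights.  A tiny ridge term
    keeps separated or collinear designs solvable.
    """
    n = X.shape[0]
    Xd = np.column_stack([np.ones(n), X])
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    beta = np.zeros(Xd.shape[1])
    ybar = float(np.average(y, weights=w)) if w.sum() > 0 else 0.5
    beta[0] = np.log(_clip(np.array([ybar]))[0] / (1 - _clip(np.array([ybar]))[0]))
    for _ in range(max_iter):
        eta = Xd @ beta
        p = _expit(eta)
        g = Xd.T @ (w * (y - p)) - ridge * beta
        W = w * p * (1 - p) + 1e-10
        H = (Xd * W[:, None]).T @ Xd + ridge * np.eye(Xd.shape[1])
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def predict_logistic(beta: np.ndarray, X: np.ndarray) -> np.ndarray:
    eta = beta[0] + X @ beta[1:]
    return _expit(eta)


# ---------------------------------------------------------------------------
# learners


@dataclass(frozen=True)
class LearnerSpec:
    """A named learner with fixed hyperparameters."""

    name: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in LEARNER_NAMES:
            raise ValueError(f"unknown learner {self.name!r}; "
                             f"allowed: {LEARNER_NAMES}")


class _Fitted:
    def __init__(self, predict: Callable[[np.ndarray], np.ndarray]):
        self._predict = predict

    def predict(self, X: np.ndarray) -> np.ndarray:
        return _clip(np.asarray(self._predict(X), dtype=float))


def _fit_one(spec: LearnerSpec, X: np.ndarray, y: np.ndarray, seed: int) -> _Fitted:
    hp = spec.hyperparameters
    if spec.name == "mean":
        m = float(np.mean(y))
        return _Fitted(lambda Z: np.full(Z.shape[0], m))
    if spec.name == "linear":
        Xd = np.column_stack([np.ones(X.shape[0]), X])
        beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        return _Fitted(lambda Z: np.column_stack([np.ones(Z.shape[0]), Z]) @ beta)
    if spec.name == "logistic":
        beta = fit_logistic(X, y)
        return _Fitted(lambda Z: predict_logistic(beta, Z))
    if spec.name == "saturated":
        # stratum means over the exact covariate pattern; unseen patterns fall
        # back to the overall mean
        keys = [tuple(row) for row in X]
        sums: dict[tuple, list[float]] = {}
        for k, v in zip(keys, y):
            s = sums.setdefault(k, [0.0, 0.0])
            s[0] += v
            s[1] += 1.0
        means = {k: s[0] / s[1] for k, s in sums.items()}
        overall = float(np.mean(y))

        def pred(Z: np.ndarray) -> np.ndarray:
            return np.array([means.get(tuple(r), overall) for r in Z])

        return _Fitted(pred)
    if spec.name == "cart":
        from sklearn.tree import DecisionTreeRegressor
        model = DecisionTreeRegressor(
            min_samples_leaf=hp.get("min_samples_leaf", 20),
            random_state=seed)
        model.fit(X, y)
        return _Fitted(model.predict)
    if spec.name == "random_forest":
        from sklearn.ensemble import RandomForestRegressor
        model = RandomForestRegressor(
            n_estimators=hp.get("n_estimators", 500),
            min_samples_leaf=hp.get("min_samples_leaf", 5),
            random_state=seed, n_jobs=1)
        model.fit(X, y)
        return _Fitted(model.predict)
    if spec.name == "neural_net":
        from sklearn.neural_network import MLPRegressor
        model = MLPRegressor(
            hidden_layer_sizes=hp.get("hidden_layer_sizes", (8,)),
            max_iter=hp.get("max_iter", 500), random_state=seed)
        model.fit(X, y)
        return _Fitted(model.predict)
    raise ValueError(spec.name)


# ---------------------------------------------------------------------------
# folds and the ensemble


def assign_folds(n: int, k: int = 2, seed: int = 0) -> np.ndarray:
    """Balanced random fold labels in {0..k-1}; reproducible under the seed."""
    if n < k:
        raise ValueError(f"cannot split n={n} observations into k={k} folds")
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % k
    return labels[rng.permutation(n)]


@dataclass
class EnsembleFit:
    library: list[LearnerSpec]
    weights: np.ndarray            # convex, sum to one
    cv_losses: np.ndarray          # per-learner cross-validated loss
    ensemble_cv_loss: float
    folds: np.ndarray
    fitted: list[_Fitted | None]
    failed: list[bool]

    def summary(self) -> dict:
        return {
            "learners": [s.name for s in self.library],
            "weights": [float(w) for w in self.weights],
            "cv_losses": [float(v) for v in self.cv_losses],
            "ensemble_cv_loss": float(self.ensemble_cv_loss),
        }


def _solve_simplex_weights(Z: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Weights minimising CV Bernoulli loss over the simplex.

    Starts from the best single learner (a simplex vertex), so the solution
    can never be worse than the best library member.
    """
    L = Z.shape[1]
    losses = np.array([bernoulli_loss(y, Z[:, j]) for j in range(L)])
    if L == 1:
        return np.array([1.0])

    def objective(w: np.ndarray) -> float:
        return bernoulli_loss(y, Z @ w)

    w0 = np.zeros(L)
    w0[int(np.argmin(losses))] = 1.0
    res = minimize(
        objective, w0, method="SLSQP",
        bounds=[(0.0, 1.0)] * L,
        constraints=[{"type": "eq", "fun": lambda w: np.sum(w) - 1.0}],
        options={"maxiter": 200, "ftol": 1e-12},
    )
    w = np.clip(res.x, 0.0, None)
    w = w / w.sum() if w.sum() > 0 else w0
    if objective(w) > objective(w0):
        w = w0  # optimiser failed to beat the best vertex
    return w


def fit_super_learner(
    X: np.ndarray,
    y: np.ndarray,
    library: list[LearnerSpec] | list[str],
    k: int = 2,
    seed: int = 0,
) -> EnsembleFit:
    """Fit the cross-validated convex ensemble.

    A learner that raises during fitting is given weight zero with a logged
    warning; the ensemble never aborts.  With a single-learner library the
    cross-validation stage is skipped (the weight is one by construction).
    """
    specs = [s if isinstance(s, LearnerSpec) else LearnerSpec(s) for s in library]
    if not specs:
        raise ValueError("learner library is empty")
    if np.any(np.isnan(y)):
        raise ValueError("labels contain missing values")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, L = X.shape[0], len(specs)
    failed = [False] * L
    fitted: list[_Fitted | None] = [None] * L

    if L == 1:
        folds = np.zeros(n, dtype=int)
        fitted[0] = _fit_one(specs[0], X, y, seed)
        loss = bernoulli_loss(y, fitted[0].predict(X))
        return EnsembleFit(specs, np.array([1.0]), np.array([loss]), loss,
                           folds, fitted, failed)

    folds = assign_folds(n, k, seed)
    Z = np.full((n, L), np.nan)
    for j, spec in enumerate(specs):
        try:
            for f in range(k):
                tr, te = folds != f, folds == f
                m = _fit_one(spec, X[tr], y[tr], seed + 1000 * f)
                Z[te, j] = m.predict(X[te])
            fitted[j] = _fit_one(spec, X, y, seed)
        except Exception as exc:  # noqa: BLE001 - any learner failure is survivable
            log.warning("learner %s failed to fit (%s); weight forced to 0",
                        spec.name, exc)
            failed[j] = True
            Z[:, j] = np.mean(y)

    cv_losses = np.array([np.inf if failed[j] else bernoulli_loss(y, Z[:, j])
                          for j in range(L)])
    ok = ~np.array(failed)
    if not ok.any():
        raise RuntimeError("every learner in the library failed to fit")
    w_ok = _solve_simplex_weights(Z[:, ok], y)
    weights = np.zeros(L)
    weights[ok] = w_ok
    ens_loss = bernoulli_loss(y, Z[:, ok] @ w_ok)
    return EnsembleFit(specs, weights, cv_losses, ens_loss, folds, fitted, failed)


def predict_ensemble(fit: EnsembleFit, X: np.ndarray,
                     clip: float = CLIP) -> np.ndarray:
    """Convex combination of the full-data learner fits, clipped into (0, 1)."""
    X = np.asarray(X, dtype=float)
    out = np.zeros(X.shape[0])
    for w, m in zip(fit.weights, fit.fitted):
        if w > 0:
            if m is None:
                raise RuntimeError("positive weight on an unfitted learner")
            out += w * m.predict(X)
    return np.clip(out, clip, 1.0 - clip)
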
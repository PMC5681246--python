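"""Prediction models: single-polygenic-score regressions with causal-fraction
selection, and the elastic-net multi-score model with repeated cross-validated
hyperparameter tuning.

The elastic net minimizes

    (1/2n) * sum_i (y_i - b0 - x_i' beta)^2
        + lambda * ( alpha * ||beta||_1 + (1 - alpha)/2 * ||beta||_2^2 )

by cyclic coordinate descent with soft-thresholding.  Predictors entering the
model are already standardized polygenic scores, so fitted coefficients are
directly standardized coefficients.  Hyperparameters (alpha, lambda) are tuned
by maximizing mean cross-validated R^2 over a grid of alpha values and a
log-spaced lambda path, in k-fold cross-validation repeated with fresh random
partitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FoldPlan",
    "SingleScoreResult",
    "ElasticNetFit",
    "make_fold_plan",
    "cv_r2",
    "select_best_fraction",
    "enet_objective",
    "enet_fit",
    "enet_tune",
    "lambda_max",
]

DEFAULT_ALPHA_GRID = tuple(np.round(np.linspace(0.0, 1.0, 11), 2))
DEFAULT_FRACTIONS = (1.0, 0.1, 0.01)


@dataclass
class FoldPlan:
    """Repeated k-fold partition of the training individuals.

    ``assignments[r, i]`` is the fold of individual i in repeat r.  Within a
    repeat the folds partition all individuals with sizes differing by at most
    one.
    """

    k: int
    repeats: int
    assignments: np.ndarray   # repeats x n int array
    seed: int

    @property
    def n(self) -> int:
        return self.assignments.shape[1]

    def folds(self):
        """Yield (repeat, fold, train_idx, val_idx)."""
        for r in range(self.repeats):
            a = self.assignments[r]
            for f in range(self.k):
                val = np.flatnonzero(a == f)
                train = np.flatnonzero(a != f)
                yield r, f, train, val


def make_fold_plan(n: int, k: int = 10, repeats: int = 1, seed: int = 0) -> FoldPlan:
    """Seeded random k-fold assignments, one fresh partition per repeat."""
    if not n >= k >= 2:
        raise ValueError(f"need n >= k >= 2, got n={n}, k={k}")
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % k         # balanced sizes, remainder on low folds
    assignments = np.empty((repeats, n), dtype=np.int64)
    for r in range(repeats):
        assignments[r] = labels[rng.permutation(n)]
    return FoldPlan(k=k, repeats=repeats, assignments=assignments, seed=seed)


def _r2(y: np.ndarray, yhat: np.ndarray, convention: str = "corr") -> float:
    """R^2 between observation and prediction.

    Default is squared Pearson correlation; ``convention="ss"`` gives
    1 - SS_res/SS_tot.  A constant prediction has undefined correlation and
    scores 0.
    """
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    if convention == "ss":
        sst = float(((y - y.mean()) ** 2).sum())
        return 1.0 - float(((y - yhat) ** 2).sum()) / sst if sst > 0 else 0.0
    sy, syh = y.std(), yhat.std()
    if sy == 0 or syh == 0:
        return 0.0
    r = float(np.corrcoef(y, yhat)[0, 1])
    return r * r


def _ols_fit_predict(xtr, ytr, xval):
    design = np.column_stack([np.ones(len(ytr)), xtr])
    coef, *_ = np.linalg.lstsq(design, ytr, rcond=None)
    return np.column_stack([np.ones(xval.shape[0]), xval]) @ coef


def cv_r2(
    predictors: np.ndarray,
    y: np.ndarray,
    fold_plan: FoldPlan,
    model_spec="ols",
    r2_convention: str = "corr",
) -> tuple[float, np.ndarray]:
    """Mean cross-validated R^2 and its per-(repeat, fold) distribution.

    ``model_spec`` is either ``"ols"`` or a callable
    ``fit(X_train, y_train) -> predict`` returning a function of X.
    """
    x = np.asarray(predictors, float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(y, float)
    if len(y) != x.shape[0] or len(y) != fold_plan.n:
        raise ValueError("fold plan must cover all rows of predictors/y")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values in predictors or outcome")
    vals = np.empty(fold_plan.repeats * fold_plan.k)
    for i, (_r, _f, tr, va) in enumerate(fold_plan.folds()):
        if y[tr].std() == 0:
            raise ValueError("constant outcome within a training fold")
        if model_spec == "ols":
            yhat = _ols_fit_predict(x[tr], y[tr], x[va])
        else:
            predict = model_spec(x[tr], y[tr])
            yhat = predict(x[va])
        vals[i] = _r2(y[va], yhat, r2_convention)
    return float(vals.mean()), vals


@dataclass
class SingleScoreResult:
    """Best causal-fraction variant of one GWAS's score for one outcome."""

    chosen_fraction: float
    cv_r2_by_fraction: dict[float, float]
    slope: float
    intercept: float

    @property
    def cv_r2(self) -> float:
        return self.cv_r2_by_fraction[self.chosen_fraction]

    def predict(self, score: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(score, float)


def select_best_fraction(
    score_variants: dict[float, np.ndarray],
    y: np.ndarray,
    fold_plan: FoldPlan,
) -> SingleScoreResult:
    """Pick the causal-fraction score variant with the largest mean cv-R^2.

    One simple linear regression per fraction, evaluated by :func:`cv_r2`;
    exact ties break to the smallest fraction (sparsest prior).  The selected
    variant's regression is refit on all rows.
    """
    if not score_variants:
        raise ValueError("no score variants supplied")
    y = np.asarray(y, float)
    cv_means: dict[float, float] = {}
    for p, col in score_variants.items():
        cv_means[float(p)] = cv_r2(np.asarray(col, float), y, fold_plan)[0]
    best = max(cv_means.values())
    chosen = min(p for p, v in cv_means.items() if v == best)
    x = np.asarray(score_variants[chosen], float)
    design = np.column_stack([np.ones(len(y)), x])
    (b0, b1), *_ = np.linalg.lstsq(design, y, rcond=None)
    return SingleScoreResult(chosen_fraction=chosen, cv_r2_by_fraction=cv_means,
                             slope=float(b1), intercept=float(b0))


# ---------------------------------------------------------------------------
# elastic net

def enet_objective(beta, intercept, x, y, alpha, lam) -> float:
    """Elastic-net loss: (1/2n)||y - b0 - X beta||^2
    + lam (alpha ||beta||_1 + (1-alpha)/2 ||beta||^2)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    beta = np.asarray(beta, float)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    resid = y - intercept - x @ beta
    n = len(y)
    penalty = lam * (alpha * np.abs(beta).sum() + 0.5 * (1 - alpha) * (beta**2).sum())
    return float(0.5 * (resid @ resid) / n + penalty)


@dataclass
class ElasticNetFit:
    """A fitted (optionally tuned) elastic-net model."""

    alpha: float
    lam: float
    coef: np.ndarray
    intercept: float
    n_sweeps: int = 0
    converged: bool = True
    cv_r2_mean: float | None = None
    cv_r2_distribution: np.ndarray | None = None
    objective_path: np.ndarray | None = None

    @property
    def retained(self) -> np.ndarray:
        """Indices of predictors with nonzero coefficients."""
        return np.flatnonzero(self.coef)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(x, float) @ self.coef


def _soft(z: float, t: float) -> float:
    return np.sign(z) * max(abs(z) - t, 0.0)


def lambda_max(x: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Smallest lambda with an all-zero solution, max_j |x_j'(y - ybar)| / (n a).

    Undefined at alpha = 0; the conventional alpha = 0.001 surrogate is used
    there so a ridge path still has a finite, comparable top.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    yc = y - y.mean()
    a = max(alpha, 0.001)
    return float(np.abs(x.T @ yc).max() / (len(y) * a))


def enet_fit(
    x: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float,
    tol: float = 1e-7,
    max_sweeps: int = 10_000,
    beta0: np.ndarray | None = None,
    track_objective: bool = False,
) -> ElasticNetFit:
    """Cyclic coordinate descent with soft-thresholding.

    ``x`` is expected column-standardized (it is not re-standardized here, so
    coefficients stay on the standardized scale); the intercept absorbs the
    outcome mean.  Coordinate update with q_j = (1/n) x_j' x_j:

        beta_j <- S((1/n) x_j' r + q_j beta_j, lam * alpha) / (q_j + lam (1 - alpha))

    which for exactly unit-variance columns is the textbook
    S(rho_j, lam alpha) / (1 + lam (1 - alpha)).  Converges when the largest
    coefficient change in a sweep is below ``tol``.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n, m = x.shape
    xm = x.mean(axis=0)
    xc = x - xm
    ym = y.mean()
    yc = y - ym
    q = (xc**2).sum(axis=0) / n
    beta = np.zeros(m) if beta0 is None else np.asarray(beta0, float).copy()
    resid = yc - xc @ beta
    lam_l1 = lam * alpha
    lam_l2 = lam * (1 - alpha)
    objective = []
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        max_delta = 0.0
        for j in range(m):
            if q[j] == 0:
                continue
            rho = (xc[:, j] @ resid) / n + q[j] * beta[j]
            new = _soft(rho, lam_l1) / (q[j] + lam_l2)
            delta = new - beta[j]
            if delta != 0.0:
                resid -= delta * xc[:, j]
                beta[j] = new
                max_delta = max(max_delta, abs(delta))
        if track_objective:
            objective.append(enet_objective(beta, 0.0, xc, yc, alpha, lam))
        if max_delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"elastic net did not converge in {max_sweeps} sweeps "
            f"(alpha={alpha}, lambda={lam:.3g}); results may be inaccurate"
        )
    intercept = float(ym - xm @ beta)
    return ElasticNetFit(
        alpha=float(alpha), lam=float(lam), coef=beta, intercept=intercept,
        n_sweeps=sweeps, converged=converged,
        objective_path=np.array(objective) if track_objective else None,
    )


def _lambda_path(x, y, alpha, n_lambda, lambda_min_ratio):
    lmax = lambda_max(x, y, alpha)
    if lmax <= 0:
        lmax = 1e-3
    return np.geomspace(lmax, lmax * lambda_min_ratio, n_lambda)


def enet_tune(
    x: np.ndarray,
    y: np.ndarray,
    fold_plan: FoldPlan,
    alpha_grid=DEFAULT_ALPHA_GRID,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-3,
    tol: float = 1e-7,
    max_sweeps: int = 10_000,
    r2_convention: str = "corr",
) -> ElasticNetFit:
    """Tune (alpha, lambda) by repeated k-fold CV and refit on all rows.

    For each alpha, lambdas run down a log-spaced path from lambda_max to
    lambda_max * ``lambda_min_ratio`` with warm starts.  The winning pair
    minimizes mean cross-validated squared error (equivalently, maximizes the
    CV performance value; unlike the squared-correlation metric, squared
    error can prefer the empty model when no predictor helps); ties break to
    the largest lambda (sparser model), then the largest alpha.  The returned
    fit carries the winning pair's mean cv-R^2 and its per-fold distribution.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    alphas = [float(a) for a in alpha_grid]
    if not alphas or n_lambda < 1:
        raise ValueError("alpha_grid and lambda path must be non-empty")
    if len(alphas) * n_lambda < 2:
        raise ValueError("need at least 2 candidate hyperparameter points")
    n_folds_total = fold_plan.repeats * fold_plan.k
    results = {}   # (alpha, lam) -> per-fold r2 array
    losses = {}    # (alpha, lam) -> per-fold mse array
    for alpha in alphas:
        path = _lambda_path(x, y, alpha, n_lambda, lambda_min_ratio)
        fold_r2 = np.empty((n_lambda, n_folds_total))
        fold_mse = np.empty((n_lambda, n_folds_total))
        for i, (_r, _f, tr, va) in enumerate(fold_plan.folds()):
            beta = None
            for li, lam in enumerate(path):
                fit = enet_fit(x[tr], y[tr], alpha, lam, tol=tol,
                               max_sweeps=max_sweeps, beta0=beta)
                beta = fit.coef
                yhat = fit.predict(x[va])
                fold_r2[li, i] = _r2(y[va], yhat, r2_convention)
                fold_mse[li, i] = float(np.mean((y[va] - yhat) ** 2))
        for li, lam in enumerate(path):
            results[(alpha, float(lam))] = fold_r2[li]
            losses[(alpha, float(lam))] = fold_mse[li]

    mean_mse = {key: v.mean() for key, v in losses.items()}
    best_loss = min(mean_mse.values())
    # ties: largest lambda, then largest alpha
    best_alpha, best_lam = max(
        (k for k, v in mean_mse.items() if v == best_loss), key=lambda k: (k[1], k[0])
    )
    # warm-started refit on all rows down the path to the winner
    path = _lambda_path(x, y, best_alpha, n_lambda, lambda_min_ratio)
    beta = None
    final = None
    for lam in path:
        final = enet_fit(x, y, best_alpha, lam, tol=tol, max_sweeps=max_sweeps, beta0=beta)
        beta = final.coef
        if lam <= best_lam:
            break
    final.alpha = best_alpha
    final.lam = float(best_lam)
    final.cv_r2_mean = float(results[(best_alpha, best_lam)].mean())
    final.cv_r2_distribution = results[(best_alpha, best_lam)]
    return final
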
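"""Weighted Poisson density model with LASSO selection and post-selection refit.

The estimating model is a Poisson pseudo-likelihood for village population
density (a continuous response):

    log E[y_v | X_v, Z_v] = alpha + beta . X_v + gamma . Z_v,

maximized with observation weights w_v (uniform, 1/pop_v, or the
selection-corrected 1/(pop_v * p_hat_v)).  Variable selection minimizes

    sum_v u_v (exp(eta_v) - y_v eta_v)  +  lambda * sum_{j in penalized} |tau_j|,

where u_v = w_v / sum(w_v) are mean-normalized unit weights (so the 1/N
log-likelihood scaling and the lambda scale are comparable across weight
schemes).  Penalized covariates are standardized to zero weighted mean and
unit weighted variance before soft-thresholding; forced columns (urban,
log area, district effects) and the intercept are never penalized.  The
path is solved by proximal Newton: iteratively reweighted least squares
with an inner cyclic coordinate descent, warm-started down a decreasing
lambda grid.  lambda is chosen by K-fold cross-validation on response-scale
RMSE, and the final model is an unpenalized refit on the selected support
(removing LASSO shrinkage from the predictions).

A probit selection model fitted on the LASSO-selected covariates supplies
predicted sampling probabilities for the balance-corrected weight scheme.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .design import DesignMatrix, SchemaError

logger = logging.getLogger(__name__)

DEFAULT_P_FLOOR = 0.01


class FitError(RuntimeError):
    """Raised when an estimation routine fails (non-convergence, rank loss)."""


class UsageError(ValueError):
    """Raised when an operation is called with inconsistent arguments."""


# ---------------------------------------------------------------------------
# Weights
# ---------------------------------------------------------------------------

@dataclass
class WeightVector:
    village_id: np.ndarray
    w: np.ndarray
    scheme: str                       # uniform | inverse_pop | balance_corrected
    n_floored: int = 0                # probabilities clipped at p_floor

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if not np.all(np.isfinite(self.w)) or np.any(self.w <= 0):
            raise UsageError("weights must be positive and finite")

    def align(self, village_ids: np.ndarray) -> np.ndarray:
        s = pd.Series(self.w, index=self.village_id)
        out = s.reindex(np.asarray(village_ids))
        if out.isna().any():
            raise KeyError("weight vector missing some requested villages")
        return out.to_numpy()


def compute_weights(
    pop: pd.Series,
    scheme: str,
    selection: "SelectionModel | None" = None,
    p_floor: float = DEFAULT_P_FLOOR,
) -> WeightVector:
    """Observation weights per village: uniform, 1/pop, or 1/(pop * p_hat)."""
    pop = pop.astype(float)
    if (pop <= 0).any():
        raise UsageError("village populations must be positive for weighting")
    if scheme == "uniform":
        w = np.ones(len(pop))
        n_floored = 0
    elif scheme == "inverse_pop":
        w = 1.0 / pop.to_numpy()
        n_floored = 0
    elif scheme == "balance_corrected":
        if selection is None:
            raise UsageError("balance_corrected weights require a fitted selection model")
        probs = selection.probabilities.reindex(pop.index)
        if probs.isna().any():
            raise KeyError("selection model lacks probabilities for some villages")
        p = probs.to_numpy()
        n_floored = int((p < p_floor).sum())
        p = np.clip(p, p_floor, 1.0 - 1e-12)
        w = 1.0 / (pop.to_numpy() * p)
    else:
        raise UsageError(f"unknown weight scheme {scheme!r}")
    return WeightVector(village_id=pop.index.to_numpy(), w=w, scheme=scheme, n_floored=n_floored)


# ---------------------------------------------------------------------------
# Unpenalized weighted Poisson (IRLS)
# ---------------------------------------------------------------------------

@dataclass
class PoissonFit:
    columns: list[str]                # includes "intercept" first
    coef: np.ndarray
    objective: float                  # sum u (mu - y*eta), unit-weight scale
    n_iter: int
    objective_trace: list[float]
    cov: pd.DataFrame | None = None   # cluster-robust, if requested

    def coef_series(self) -> pd.Series:
        return pd.Series(self.coef, index=self.columns)


def _check_rank(Xa: np.ndarray, columns: list[str]) -> None:
    """Raise naming (nearly) collinear columns if Xa is rank deficient."""
    _, R, piv = _qr_pivot(Xa)
    diag = np.abs(np.diag(R))
    tol = max(Xa.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int((diag > tol).sum())
    if rank < Xa.shape[1]:
        bad = [columns[j] for j in piv[rank:]]
        raise FitError(f"design is rank deficient; collinear columns: {bad}")


def _qr_pivot(A: np.ndarray):
    from scipy.linalg import qr

    Q, R, piv = qr(A, mode="economic", pivoting=True)
    return Q, R, piv


def _unit_weights(weights: np.ndarray | None, n: int) -> np.ndarray:
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise UsageError("weights must be positive and finite")
    return w / w.sum()


def _objective(u: np.ndarray, y: np.ndarray, eta: np.ndarray) -> float:
    return float(np.sum(u * (np.exp(eta) - y * eta)))


def fit_poisson_irls(
    design: DesignMatrix,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    clusters: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> PoissonFit:
    """Maximize the weighted Poisson pseudo-log-likelihood by Newton/IRLS.

    ``y`` may be continuous (density).  If ``clusters`` is given, a
    cluster-robust sandwich covariance (with a G/(G-1) correction) is
    attached; pass the sub-district labels to mirror the study's clustering.
    """
    X = design.data
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise UsageError("response must be nonnegative")
    n, p = X.shape
    u = _unit_weights(weights, n)
    Xa = np.column_stack([np.ones(n), X])
    cols = ["intercept"] + list(design.columns)
    _check_rank(np.sqrt(u)[:, None] * Xa, cols)

    ybar = float(np.sum(u * y))
    beta = np.zeros(p + 1)
    beta[0] = np.log(max(ybar, 1e-12))
    eta = Xa @ beta
    obj = _objective(u, y, eta)
    trace = [obj]
    for it in range(1, max_iter + 1):
        mu = np.exp(eta)
        a = u * mu
        z = eta + (y - mu) / mu
        WX = Xa * a[:, None]
        H = Xa.T @ WX
        g = WX.T @ z
        try:
            new_beta = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"singular IRLS system at iteration {it}") from exc
        # step halving to guarantee descent of the pseudo-deviance
        step = 1.0
        for _ in range(40):
            cand = beta + step * (new_beta - beta)
            cand_eta = Xa @ cand
            if np.max(np.abs(cand_eta)) > 500:
                step /= 2.0
                continue
            cand_obj = _objective(u, y, cand_eta)
            if cand_obj <= obj + 1e-14:
                break
            step /= 2.0
        else:
            raise FitError(
                f"IRLS failed to find a descent step; objective trace: {trace[-5:]}"
            )
        beta, eta = cand, cand_eta
        rel = abs(obj - cand_obj) / max(abs(obj), 1e-12)
        obj = cand_obj
        trace.append(obj)
        if rel < tol:
            break
    else:
        raise FitError(
            f"IRLS did not converge in {max_iter} iterations; "
            f"objective trace tail: {trace[-5:]}"
        )

    cov = None
    if clusters is not None:
        cov = _cluster_cov(Xa, y, eta, u, np.asarray(clusters), cols)
    return PoissonFit(
        columns=cols, coef=beta, objective=obj, n_iter=it, objective_trace=trace, cov=cov
    )


def _cluster_cov(
    Xa: np.ndarray,
    y: np.ndarray,
    eta: np.ndarray,
    u: np.ndarray,
    clusters: np.ndarray,
    cols: list[str],
) -> pd.DataFrame:
    """Cluster-robust sandwich covariance A^-1 B A^-1 with G/(G-1) correction."""
    mu = np.exp(eta)
    A = Xa.T @ (Xa * (u * mu)[:, None])
    S = Xa * (u * (y - mu))[:, None]
    df = pd.DataFrame(S)
    df["_g"] = clusters
    G = df["_g"].nunique()
    if G < 2:
        raise UsageError("need >= 2 clusters for a cluster-robust covariance")
    sums = df.groupby("_g").sum().to_numpy()
    B = sums.T @ sums * (G / (G - 1))
    Ainv = np.linalg.inv(A)
    V = Ainv @ B @ Ainv
    return pd.DataFrame(V, index=cols, columns=cols)


# ---------------------------------------------------------------------------
# LASSO path (proximal Newton + cyclic coordinate descent)
# ---------------------------------------------------------------------------

@dataclass
class GridSpec:
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4

    def grid(self, lambda_max: float) -> np.ndarray:
        return np.geomspace(lambda_max, lambda_max * self.lambda_min_ratio, self.n_lambda)


@dataclass
class LassoPath:
    lambda_grid: np.ndarray                   # decreasing
    coefficients: pd.DataFrame                # grid x columns, original scale
    intercepts: np.ndarray
    deviance: np.ndarray                      # sum u (mu - y eta) per lambda
    objective: np.ndarray                     # deviance + penalty, standardized scale
    kkt_violation: np.ndarray                 # max subgradient violation per lambda
    columns: list[str]
    penalized: np.ndarray
    standardize_mean: np.ndarray              # over penalized columns
    standardize_scale: np.ndarray

    def coef_at(self, lam: float) -> tuple[float, pd.Series]:
        i = int(np.argmin(np.abs(self.lambda_grid - lam)))
        if not np.isclose(self.lambda_grid[i], lam, rtol=1e-9, atol=0):
            raise UsageError(f"lambda {lam} is not on the computed path")
        return self.intercepts[i], self.coefficients.iloc[i]

    def selected_at(self, lam: float) -> list[str]:
        _, coefs = self.coef_at(lam)
        pen = dict(zip(self.columns, self.penalized))
        return [c for c in self.columns if pen[c] and coefs[c] != 0.0]


def _standardize(X: np.ndarray, penalized: np.ndarray, u: np.ndarray):
    Xs = X.copy()
    means = np.zeros(X.shape[1])
    scales = np.ones(X.shape[1])
    for j in np.flatnonzero(penalized):
        m = float(np.sum(u * X[:, j]))
        s = float(np.sqrt(np.sum(u * (X[:, j] - m) ** 2)))
        if s <= 0:
            raise FitError(f"penalized column {j} has zero weighted variance")
        Xs[:, j] = (X[:, j] - m) / s
        means[j], scales[j] = m, s
    return Xs, means, scales


def _soft(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


def _cd_solve(
    Xs: np.ndarray,
    a: np.ndarray,
    z: np.ndarray,
    alpha: float,
    theta: np.ndarray,
    lam: float,
    pen: np.ndarray,
    tol: float,
    max_sweeps: int,
) -> tuple[float, np.ndarray, int]:
    """Cyclic coordinate descent for the penalized weighted least squares
    subproblem  min 0.5 sum a (z - alpha - Xs theta)^2 + lam sum_pen |theta_j|.

    The intercept is profiled out exactly (weighted centering) and the
    sweeps run on the Gram matrix ("covariance updates"), so each
    coordinate update costs O(p) after one O(n p^2) setup.
    """
    n, p = Xs.shape
    asum = a.sum()
    xbar = (a @ Xs) / asum
    zbar = float(a @ z) / asum
    Xc = Xs - xbar
    zc = z - zbar
    G = Xc.T @ (Xc * a[:, None])
    c = Xc.T @ (a * zc)
    Gd = np.diag(G).copy()
    if np.any(Gd <= 0):
        j = int(np.flatnonzero(Gd <= 0)[0])
        raise FitError(f"column {j} is constant within the working sample")
    q = G @ theta
    sweep = 0
    for sweep in range(1, max_sweeps + 1):
        delta_max = 0.0
        for j in range(p):
            old = theta[j]
            num = c[j] - q[j] + Gd[j] * old
            if pen[j]:
                new = _soft(num, lam) / Gd[j]
            else:
                new = num / Gd[j]
            if new != old:
                q += G[:, j] * (new - old)
                theta[j] = new
                d = abs(new - old)
                if d > delta_max:
                    delta_max = d
        if delta_max < tol:
            break
    alpha = zbar - float(xbar @ theta)
    return alpha, theta, sweep


def lasso_path(
    design: DesignMatrix,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    grid_spec: GridSpec | None = None,
    lambda_grid: np.ndarray | None = None,
    outer_tol: float = 1e-8,
    cd_tol: float = 1e-10,
    max_outer: int = 100,
    max_sweeps: int = 1000,
) -> LassoPath:
    """Solve the penalized weighted Poisson objective down a lambda grid.

    The grid starts at lambda_max (the smallest lambda at which every
    penalized coefficient is zero, computed from the forced-only score) and
    warm-starts downward.  Coefficients are returned on the original
    covariate scale; the KKT subgradient violation is recorded per lambda.
    """
    if grid_spec is None:
        grid_spec = GridSpec()
    X = design.data
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    u = _unit_weights(weights, n)
    pen = design.penalized
    Xs, means, scales = _standardize(X, pen, u)

    # forced-only fit gives the lambda_max score and the warm start
    forced = design.take_columns(design.forced_columns)
    base = fit_poisson_irls(forced, y, weights=weights)
    theta = np.zeros(p)
    fidx = [design.columns.index(c) for c in design.forced_columns]
    theta[fidx] = base.coef[1:]
    alpha = float(base.coef[0])
    eta = alpha + Xs @ theta  # forced cols unstandardized: identical to base eta
    mu = np.exp(eta)
    score = Xs.T @ (u * (y - mu))
    lambda_max = float(np.max(np.abs(score[pen])))

    if lambda_grid is None:
        grid = grid_spec.grid(lambda_max)
    else:
        grid = np.asarray(lambda_grid, dtype=float)
        if np.any(grid <= 0):
            raise UsageError("lambda grid must be strictly positive")
        if np.any(np.diff(grid) >= 0):
            raise UsageError("lambda grid must be strictly decreasing")

    coefs = np.zeros((len(grid), p))
    intercepts = np.zeros(len(grid))
    deviance = np.zeros(len(grid))
    objective = np.zeros(len(grid))
    kkt = np.zeros(len(grid))

    def _kkt_violation(theta_: np.ndarray, eta_: np.ndarray, lam: float) -> float:
        mu_ = np.exp(np.clip(eta_, -500, 500))
        score = Xs.T @ (u * (y - mu_))
        viol = 0.0
        for j in np.flatnonzero(pen):
            if theta_[j] != 0.0:
                viol = max(viol, abs(score[j] - lam * np.sign(theta_[j])))
            else:
                viol = max(viol, max(0.0, abs(score[j]) - lam))
        return viol

    base_theta, base_alpha = theta.copy(), alpha

    kkt_tol = 1e-6 * max(1.0, lambda_max)
    for i, lam in enumerate(grid):
        if lam >= lambda_max * (1.0 - 1e-12):
            # the all-zero penalized solution is exact for lam >= lambda_max
            theta, alpha = base_theta.copy(), base_alpha
            eta = alpha + Xs @ theta
            obj = _objective(u, y, eta)
            kkt[i] = _kkt_violation(theta, eta, lam)
            deviance[i] = obj
            objective[i] = obj
            intercepts[i] = alpha
            coefs[i] = theta
            continue
        obj = _objective(u, y, eta) + lam * np.sum(np.abs(theta[pen]))
        for _ in range(max_outer):
            mu = np.exp(np.clip(eta, -500, 500))
            a = u * mu
            z = eta + (y - mu) / mu
            new_alpha, new_theta, _ = _cd_solve(
                Xs, a, z, alpha, theta.copy(), lam, pen, cd_tol, max_sweeps
            )
            new_eta = new_alpha + Xs @ new_theta
            new_obj = _objective(u, y, new_eta) + lam * np.sum(np.abs(new_theta[pen]))
            # proximal-Newton step halving toward the previous iterate
            step = 1.0
            while new_obj > obj + 1e-14 and step > 1e-10:
                step /= 2.0
                new_alpha = alpha + step * (new_alpha - alpha)
                new_theta = theta + step * (new_theta - theta)
                new_eta = new_alpha + Xs @ new_theta
                new_obj = _objective(u, y, new_eta) + lam * np.sum(np.abs(new_theta[pen]))
            rel = abs(obj - new_obj) / max(abs(obj), 1e-12)
            alpha, theta, eta, obj = new_alpha, new_theta, new_eta, new_obj
            if rel < outer_tol and _kkt_violation(theta, eta, lam) < kkt_tol:
                break
        kkt[i] = _kkt_violation(theta, eta, lam)
        deviance[i] = _objective(u, y, eta)
        objective[i] = obj
        intercepts[i] = alpha - float(np.sum(theta[pen] * means[pen] / scales[pen]))
        orig = theta.copy()
        orig[pen] = theta[pen] / scales[pen]
        coefs[i] = orig

    return LassoPath(
        lambda_grid=grid,
        coefficients=pd.DataFrame(coefs, columns=design.columns),
        intercepts=intercepts,
        deviance=deviance,
        objective=objective,
        kkt_violation=kkt,
        columns=list(design.columns),
        penalized=pen.copy(),
        standardize_mean=means,
        standardize_scale=scales,
    )


def penalized_objective(
    design: DesignMatrix,
    y: np.ndarray,
    weights: np.ndarray | None,
    lam: float,
    intercept: float,
    coef: pd.Series,
) -> float:
    """Evaluate the path objective (standardized-penalty scale) at a point.

    The L1 penalty applies to standardized coefficients, i.e. original
    coefficients multiplied by the weighted sd of their column -- the same
    scale on which the path solves.
    """
    X = design.data
    u = _unit_weights(weights, design.n)
    pen = design.penalized
    beta = coef.reindex(design.columns).to_numpy(dtype=float)
    eta = intercept + X @ beta
    penalty = 0.0
    for j in np.flatnonzero(pen):
        m = float(np.sum(u * X[:, j]))
        s = float(np.sqrt(np.sum(u * (X[:, j] - m) ** 2)))
        penalty += abs(beta[j]) * s
    return _objective(u, y, eta) + lam * penalty


# ---------------------------------------------------------------------------
# Cross-validated lambda selection
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    lambda_star: float
    lambda_grid: np.ndarray
    cv_rmse: np.ndarray          # mean over folds, per lambda
    fold_rmse: np.ndarray        # k x n_lambda
    seed: int
    k: int
    path: LassoPath              # path on the full data


def _fold_assignments(n: int, k: int, seed: int) -> np.ndarray:
    order = np.random.default_rng(seed).permutation(n)
    folds = np.empty(n, dtype=int)
    folds[order] = np.arange(n) % k
    return folds


def _drop_degenerate_columns(dm: DesignMatrix) -> DesignMatrix:
    keep = [c for j, c in enumerate(dm.columns) if np.ptp(dm.data[:, j]) > 0]
    dropped = sorted(set(dm.columns) - set(keep))
    if dropped:
        logger.warning("dropping constant columns in training fold: %s", dropped)
    return dm.take_columns(keep)


def select_lambda_cv(
    design: DesignMatrix,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    grid_spec: GridSpec | None = None,
    k: int = 5,
    seed: int = 0,
) -> CVResult:
    """Choose lambda minimizing mean fold response-scale RMSE (K-fold CV).

    Folds come from a seeded permutation of rows, so permutation-invariant
    inputs give the same lambda.  Ties break toward the larger (sparser)
    lambda.  Training folds that lose a district reuse the remaining
    columns (the missing dummy's coefficient is treated as zero out of fold).
    """
    y = np.asarray(y, dtype=float)
    n = design.n
    if n < 2 * k:
        raise UsageError(f"need n >= 2k for {k}-fold CV, have n={n}")
    full_path = lasso_path(design, y, weights, grid_spec=grid_spec)
    grid = full_path.lambda_grid
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)

    folds = _fold_assignments(n, k, seed)
    fold_rmse = np.zeros((k, len(grid)))
    for f in range(k):
        test = folds == f
        train = ~test
        dm_tr = _drop_degenerate_columns(design.take_rows(np.flatnonzero(train)))
        path_f = lasso_path(dm_tr, y[train], w[train], lambda_grid=grid)
        dm_te = design.take_rows(np.flatnonzero(test)).take_columns(dm_tr.columns)
        for i in range(len(grid)):
            eta = path_f.intercepts[i] + dm_te.data @ path_f.coefficients.iloc[i].to_numpy()
            pred = np.exp(eta)
            fold_rmse[f, i] = float(np.sqrt(np.mean((pred - y[test]) ** 2)))
    cv_rmse = fold_rmse.mean(axis=0)
    best = cv_rmse.min()
    # grid is decreasing; first index achieving the min is the largest lambda
    i_star = int(np.flatnonzero(cv_rmse == best)[0])
    return CVResult(
        lambda_star=float(grid[i_star]),
        lambda_grid=grid,
        cv_rmse=cv_rmse,
        fold_rmse=fold_rmse,
        seed=seed,
        k=k,
        path=full_path,
    )


# ---------------------------------------------------------------------------
# Post-LASSO refit and prediction
# ---------------------------------------------------------------------------

@dataclass
class FittedDensityModel:
    selected: list[str]                   # penalized columns kept at lambda*
    lambda_star: float
    columns: list[str]                    # support incl. forced, excl. intercept
    coefficients: pd.Series               # intercept + support, post-LASSO
    scheme: str = "uniform"
    seed: int | None = None
    cov: pd.DataFrame | None = None       # cluster-robust (sub-district)
    reference_district: str | None = None

    def to_json(self, path=None) -> str:
        payload = {
            "selected": self.selected,
            "lambda_star": self.lambda_star,
            "columns": self.columns,
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "scheme": self.scheme,
            "seed": self.seed,
            "reference_district": self.reference_district,
            "cov": None
            if self.cov is None
            else {"index": list(self.cov.index), "values": self.cov.to_numpy().tolist()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FittedDensityModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        cov = None
        if payload.get("cov") is not None:
            cov = pd.DataFrame(
                payload["cov"]["values"],
                index=payload["cov"]["index"],
                columns=payload["cov"]["index"],
            )
        return cls(
            selected=payload["selected"],
            lambda_star=payload["lambda_star"],
            columns=payload["columns"],
            coefficients=pd.Series(payload["coefficients"]),
            scheme=payload["scheme"],
            seed=payload.get("seed"),
            cov=cov,
            reference_district=payload.get("reference_district"),
        )


def post_lasso_fit(
    design: DesignMatrix,
    y: np.ndarray,
    weights: np.ndarray | None,
    lambda_star: float,
    path: LassoPath,
    scheme: str = "uniform",
    seed: int | None = None,
    clusters: np.ndarray | None = None,
) -> FittedDensityModel:
    """Unpenalized refit on the LASSO-selected support plus forced columns."""
    selected = path.selected_at(lambda_star)
    if not selected:
        logger.info("LASSO selected no covariates; refitting forced-only model")
    support = selected + [c for c in design.columns if c in design.forced_columns]
    dm = design.take_columns(support)
    if clusters is None:
        clusters = design.sub_district_ids
    fit = fit_poisson_irls(dm, y, weights=weights, clusters=clusters)
    return FittedDensityModel(
        selected=selected,
        lambda_star=float(lambda_star),
        columns=support,
        coefficients=fit.coef_series(),
        scheme=scheme,
        seed=seed,
        cov=fit.cov,
        reference_district=design.reference_district,
    )


def fit_density_model(
    design: DesignMatrix,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    grid_spec: GridSpec | None = None,
    k: int = 5,
    seed: int = 0,
    scheme: str = "uniform",
) -> tuple[FittedDensityModel, CVResult]:
    """Full two-step procedure: path -> CV lambda -> post-LASSO refit."""
    cv = select_lambda_cv(design, y, weights, grid_spec=grid_spec, k=k, seed=seed)
    model = post_lasso_fit(
        design, y, weights, cv.lambda_star, cv.path, scheme=scheme, seed=seed
    )
    return model, cv


def predict_density(model: FittedDensityModel, design_new: DesignMatrix) -> np.ndarray:
    """exp(alpha + beta.X + gamma.Z) for every row of ``design_new``."""
    missing = [c for c in model.columns if c not in design_new.columns]
    if missing:
        raise SchemaError(f"design lacks support columns: {missing}")
    dm = design_new.take_columns(model.columns)
    beta = model.coefficients.reindex(["intercept"] + model.columns).to_numpy()
    eta = beta[0] + dm.data @ beta[1:]
    return np.exp(eta)


# ---------------------------------------------------------------------------
# Probit selection model
# ---------------------------------------------------------------------------

@dataclass
class SelectionModel:
    eta0: float
    eta1: pd.Series                      # coefficients on the selected covariates
    probabilities: pd.Series             # fitted P(sampled) per village
    columns: list[str] = field(default_factory=list)


def fit_selection_probit(
    covars_selected: pd.DataFrame,
    in_survey: np.ndarray,
) -> SelectionModel:
    """ML probit of survey membership on the LASSO-selected covariates.

    ``covars_selected`` must be indexed by village_id and contain exactly
    the covariates to enter the selection equation; probabilities are
    returned for every village in the table.
    """
    y = np.asarray(in_survey, dtype=float)
    if len(y) != len(covars_selected):
        raise UsageError("in_survey length does not match covariate table")
    classes = np.unique(y)
    if len(classes) < 2:
        raise FitError("selection outcome has a single class; probit undefined")
    X = sm.add_constant(covars_selected.to_numpy(dtype=float), has_constant="add")
    try:
        res = sm.Probit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise FitError(
            "probit failed (possible complete separation); consider the "
            "p_floor fallback on clipped probabilities"
        ) from exc
    if not res.mle_retvals.get("converged", True):
        raise FitError("probit did not converge")
    params = np.asarray(res.params)
    probs = res.predict(X)
    probs = np.clip(probs, 1e-12, 1 - 1e-12)
    return SelectionModel(
        eta0=float(params[0]),
        eta1=pd.Series(params[1:], index=list(covars_selected.columns)),
        probabilities=pd.Series(probs, index=covars_selected.index),
        columns=list(covars_selected.columns),
    )
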
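"""Accuracy metrics and the direct-vs-model precision (CV) comparison.

``accuracy_report`` mirrors the study's headline accuracy surface: R^2
(squared Pearson correlation by default; 1 - SSE/SST also stored),
Spearman rank correlation, MAE, RMSE, and mean/median relative error
|pred - truth| / truth over positive-truth villages.  Relative errors are
identical for densities and counts of the same villages because the two
differ only by the village-area factor.

The precision comparison contrasts, per sub-district, the coefficient of
variation (100 * SE / estimate) of

* the *direct* survey estimator -- a design-weighted mean of village
  densities with a with-replacement Horvitz-Thompson variance
  approximation, and
* the *model-based* estimator -- the mean of predicted densities with a
  delta-method variance driven by the cluster-robust coefficient
  covariance of the fitted Poisson model.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignMatrix
from .model import (
    FittedDensityModel,
    GridSpec,
    UsageError,
    fit_density_model,
    predict_density,
)
from .survey_density import InsufficientDataError


class UndefinedMetricError(ValueError):
    """Raised when a correlation is undefined (zero variance input)."""


@dataclass
class AccuracyReport:
    r2: float                  # squared Pearson correlation (default definition)
    r2_sse: float              # 1 - SSE/SST alternative
    spearman: float
    mae: float
    rmse: float
    mean_re: float
    median_re: float
    n: int
    n_zero_truth_excluded: int
    scale: str

    def to_dict(self) -> dict:
        return asdict(self)


def accuracy_report(y_true, y_pred, scale: str = "density") -> AccuracyReport:
    """Accuracy of predictions against truth on the density or count scale."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise UsageError("y_true and y_pred must have equal length")
    n = len(y_true)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 observations, have {n}")
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        raise UndefinedMetricError("zero variance input: correlations undefined")
    r = float(np.corrcoef(y_true, y_pred)[0, 1])
    sse = float(np.sum((y_pred - y_true) ** 2))
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    src = float(stats.spearmanr(y_true, y_pred).statistic)
    err = np.abs(y_pred - y_true)
    pos = y_true > 0
    re = err[pos] / y_true[pos]
    return AccuracyReport(
        r2=r * r,
        r2_sse=1.0 - sse / sst,
        spearman=src,
        mae=float(err.mean()),
        rmse=float(np.sqrt(np.mean(err**2))),
        mean_re=float(re.mean()),
        median_re=float(np.median(re)),
        n=n,
        n_zero_truth_excluded=int((~pos).sum()),
        scale=scale,
    )


def density_to_count(density_pred, frame: pd.DataFrame, village_ids=None) -> np.ndarray:
    """Population counts = density * village area, aligned on village ids."""
    density_pred = np.asarray(density_pred, dtype=float)
    if (density_pred < 0).any():
        raise UsageError("densities must be nonnegative")
    area = frame.set_index("village_id")["area_km2"]
    if village_ids is None:
        if len(density_pred) != len(area):
            raise KeyError("pass village_ids when predictions do not cover the frame")
        return density_pred * area.to_numpy()
    a = area.reindex(np.asarray(village_ids))
    if a.isna().any():
        raise KeyError("villages missing area in frame")
    return density_pred * a.to_numpy()


def crossfold_r2(
    design: DesignMatrix,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    grid_spec: GridSpec | None = None,
    k: int = 5,
    seed: int = 0,
) -> float:
    """Out-of-sample R^2 from K-fold CV of the *full* two-step procedure.

    Each training fold runs path -> lambda* -> post-LASSO refit; held-out
    predictions are pooled and their squared Pearson correlation with the
    truth is returned.
    """
    y = np.asarray(y, dtype=float)
    n = design.n
    if n < 2 * k:
        raise UsageError(f"need n >= 2k for {k}-fold CV, have n={n}")
    rng_folds = np.random.default_rng(seed).permutation(n)
    folds = np.empty(n, dtype=int)
    folds[rng_folds] = np.arange(n) % k
    w = None if weights is None else np.asarray(weights, dtype=float)
    pooled = np.empty(n)
    from .model import _drop_degenerate_columns  # shared fold-degeneracy policy

    for f in range(k):
        test = np.flatnonzero(folds == f)
        train = np.flatnonzero(folds != f)
        dm_tr = _drop_degenerate_columns(design.take_rows(train))
        model, _ = fit_density_model(
            dm_tr,
            y[train],
            None if w is None else w[train],
            grid_spec=grid_spec,
            k=k,
            seed=seed + 1000 + f,
        )
        dm_te = design.take_rows(test)
        pooled[test] = predict_density(model, dm_te)
    r = float(np.corrcoef(y, pooled)[0, 1])
    return r * r


# ---------------------------------------------------------------------------
# Coefficient-of-variation comparison
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    table: pd.DataFrame        # per sub-district: estimate, variance, cv, n, defined
    mean_cv: float             # over sub-districts with a defined CV
    n_defined: int
    n_subdistricts: int
    kind: str                  # "direct" | "model"


def direct_cv(
    estimates: pd.DataFrame,
    frame: pd.DataFrame,
    weights: pd.Series,
) -> CVReport:
    """Direct survey estimate and CV of mean density per sub-district.

    ``estimates`` is the survey density table (included single-PSU villages
    are used); ``weights`` maps village_id -> design weight (inverse village
    inclusion probability).  The estimator is the weighted mean; its
    variance uses the with-replacement approximation for a weighted ratio
    mean: var = n/(n-1) * sum_i [w_i (y_i - ybar) / sum w]^2, which allows
    intra-sub-district correlation across villages.  Sub-districts with one
    sampled village (or a zero estimate) are flagged undefined and excluded
    from the summary mean.
    """
    inc = estimates.loc[estimates["included"], ["village_id", "hies_density"]].copy()
    sub = frame.set_index("village_id")["sub_district_id"]
    inc["sub_district_id"] = sub.reindex(inc["village_id"]).to_numpy()
    if inc["sub_district_id"].isna().any():
        raise KeyError("estimate villages missing from frame")
    inc["w"] = pd.Series(weights).reindex(inc["village_id"]).to_numpy()
    if inc["w"].isna().any() or (inc["w"] <= 0).any():
        raise UsageError("positive weights required for every included village")

    rows = []
    for sid, grp in inc.groupby("sub_district_id"):
        y = grp["hies_density"].to_numpy()
        w = grp["w"].to_numpy()
        n = len(grp)
        est = float(np.sum(w * y) / np.sum(w))
        if n < 2 or est == 0:
            rows.append((sid, est, np.nan, np.nan, n, False))
            continue
        resid = w * (y - est) / np.sum(w)
        var = n / (n - 1) * float(np.sum(resid**2))
        cv = 100.0 * np.sqrt(var) / abs(est)
        rows.append((sid, est, var, cv, n, True))
    table = pd.DataFrame(
        rows, columns=["sub_district_id", "estimate", "variance", "cv", "n", "defined"]
    )
    defined = table.loc[table["defined"], "cv"]
    return CVReport(
        table=table,
        mean_cv=float(defined.mean()) if len(defined) else float("nan"),
        n_defined=int(table["defined"].sum()),
        n_subdistricts=len(table),
        kind="direct",
    )


def model_cv(
    model: FittedDensityModel,
    design_all: DesignMatrix,
    frame: pd.DataFrame | None = None,
) -> CVReport:
    """Delta-method CV of the model-based mean density per sub-district.

    For sub-district s with design rows X_s, the estimate is
    g = mean(exp(X_s theta)) and the variance is grad' V grad with
    grad = mean(exp(X_s theta) * X_s) and V the cluster-robust coefficient
    covariance carried by the fitted model.
    """
    if model.cov is None:
        raise UsageError("model carries no coefficient covariance; refit with clusters")
    cols = ["intercept"] + model.columns
    V = model.cov.loc[cols, cols].to_numpy()
    dm = design_all.take_columns(model.columns)
    Xa = np.column_stack([np.ones(dm.n), dm.data])
    beta = model.coefficients.reindex(cols).to_numpy()
    pred = np.exp(Xa @ beta)

    rows = []
    subs = pd.Series(dm.sub_district_ids)
    for sid, idx in subs.groupby(subs).groups.items():
        idx = np.asarray(idx)
        p = pred[idx]
        g = float(p.mean())
        grad = (Xa[idx] * p[:, None]).mean(axis=0)
        var = float(grad @ V @ grad)
        cv = 100.0 * np.sqrt(max(var, 0.0)) / abs(g) if g != 0 else np.nan
        rows.append((sid, g, var, cv, len(idx), g != 0))
    table = pd.DataFrame(
        rows, columns=["sub_district_id", "estimate", "variance", "cv", "n", "defined"]
    )
    defined = table.loc[table["defined"], "cv"]
    return CVReport(
        table=table,
        mean_cv=float(defined.mean()) if len(defined) else float("nan"),
        n_defined=int(table["defined"].sum()),
        n_subdistricts=len(table),
        kind="model",
    )
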
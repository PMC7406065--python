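"""Independent oracles used by the solver tests.

The penalized weighted Poisson objective is minimized by a generic smooth
optimizer (SLSQP after the standard positive/negative-part split of the
penalized coefficients, which turns the L1 term into a linear function
under bound constraints).  This path shares no code with the coordinate
descent solver it certifies.
"""

import numpy as np
from scipy.optimize import minimize

from popdensity.design import DesignMatrix


def weighted_standardization(dm: DesignMatrix, weights):
    n = dm.n
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    u = w / w.sum()
    means = np.zeros(len(dm.columns))
    scales = np.ones(len(dm.columns))
    for j in np.flatnonzero(dm.penalized):
        m = float(np.sum(u * dm.data[:, j]))
        s = float(np.sqrt(np.sum(u * (dm.data[:, j] - m) ** 2)))
        means[j], scales[j] = m, s
    return u, means, scales


def penalized_poisson_minimum(dm: DesignMatrix, y, weights, lam) -> float:
    """Minimum of the path objective found by SLSQP on the split problem."""
    u, means, scales = weighted_standardization(dm, weights)
    y = np.asarray(y, float)
    pen_idx = np.flatnonzero(dm.penalized)
    forced_idx = np.flatnonzero(~dm.penalized)
    p_pen, p_forced = len(pen_idx), len(forced_idx)

    Xs = dm.data.copy()
    for j in pen_idx:
        Xs[:, j] = (Xs[:, j] - means[j]) / scales[j]

    def objective(params):
        alpha = params[0]
        tpos = params[1 : 1 + p_pen]
        tneg = params[1 + p_pen : 1 + 2 * p_pen]
        gam = params[1 + 2 * p_pen :]
        theta = np.zeros(len(dm.columns))
        theta[pen_idx] = tpos - tneg
        theta[forced_idx] = gam
        eta = alpha + Xs @ theta
        return float(np.sum(u * (np.exp(eta) - y * eta)) + lam * np.sum(tpos + tneg))

    x0 = np.zeros(1 + 2 * p_pen + p_forced)
    x0[0] = np.log(max(np.sum(u * y), 1e-8))
    bounds = [(None, None)] + [(0, None)] * (2 * p_pen) + [(None, None)] * p_forced
    best = np.inf
    for start_scale in (0.0, 0.1):
        x = x0.copy()
        if start_scale:
            x[1:] += start_scale
        res = minimize(
            objective, x, method="SLSQP", bounds=bounds,
            options={"maxiter": 1000, "ftol": 1e-14},
        )
        best = min(best, float(res.fun))
    return best
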
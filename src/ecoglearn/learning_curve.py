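"""Power-law learning-curve fitting.

Performance as a function of training-set size ``l`` is modeled as

    CS(l; a, b, c) = a - b * l**(-c)

with ``a`` the asymptotic performance (bounded to [-1, 1]), ``b`` the
learning rate and ``c`` the decay rate (both positive).  Fitting uses
bounded non-linear least squares (Trust Region Reflective) with multi-start
initialization over a coarse (b, c) grid, because the objective is multimodal
in those parameters.  ``c`` is unit-sensitive, so the size unit is recorded
in the fit object (minutes throughout this package).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

_B_LO = 1e-9
_C_LO = 1e-9


@dataclass
class LearningCurveFit:
    a: float
    b: float
    c: float
    residuals: np.ndarray
    covariance: np.ndarray | None
    converged: bool
    degenerate: bool = False
    unit: str = "minutes"
    sse: float = field(default=np.nan)

    def predict(self, l):
        return predict_cs(self, l)


def _model(params, l):
    a, b, c = params
    return a - b * np.power(l, -c)


def predict_cs(fit: LearningCurveFit, l) -> float | np.ndarray:
    """Evaluate the fitted curve a - b*l^(-c) at size ``l`` (> 0)."""
    l = np.asarray(l, dtype=float)
    if np.any(l <= 0):
        raise ValueError("dataset size must be positive")
    out = _model((fit.a, fit.b, fit.c), l)
    return float(out) if out.ndim == 0 else out


def fit_power_law(sizes, cs_values, b_grid=None, c_grid=None) -> LearningCurveFit:
    """Fit CS(l) = a - b*l^(-c) by bounded TRF least squares with multi-start.

    Requires at least four distinct positive sizes.  A flat response is fit
    with ``a`` at the mean and ``b`` pinned at its lower bound, flagged
    degenerate.
    """
    l = np.asarray(sizes, dtype=float)
    y = np.asarray(cs_values, dtype=float)
    if np.any(l <= 0):
        raise ValueError("dataset sizes must be positive")
    if np.unique(l).size < 4:
        raise ValueError("need at least 4 distinct sizes to fit 3 parameters")
    if b_grid is None:
        b_grid = (0.01, 0.1, 0.3, 1.0, 3.0)
    if c_grid is None:
        c_grid = (0.1, 0.25, 0.5, 1.0, 2.0)

    if np.ptp(y) == 0.0:
        a = float(y[0])
        return LearningCurveFit(a=a, b=_B_LO, c=1.0,
                                residuals=np.zeros_like(y), covariance=None,
                                converged=True, degenerate=True, sse=0.0)

    bounds = ([-1.0, _B_LO, _C_LO], [1.0, np.inf, np.inf])
    best = None
    a0 = float(np.clip(np.max(y), -1.0, 1.0))
    for b0 in b_grid:
        for c0 in c_grid:
            x0 = np.array([a0, b0, c0])
            try:
                res = least_squares(lambda p: _model(p, l) - y, x0,
                                    bounds=bounds, method="trf")
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
    if best is None:
        raise RuntimeError("all power-law fits failed")
    a, b, c = best.x
    resid = best.fun
    # covariance from the Jacobian at the optimum (Gauss-Newton approximation)
    cov = None
    dof = l.size - 3
    if dof > 0:
        try:
            jtj = best.jac.T @ best.jac
            cov = np.linalg.pinv(jtj) * (2 * best.cost / dof)
        except np.linalg.LinAlgError:
            cov = None
    return LearningCurveFit(a=float(a), b=float(b), c=float(c),
                            residuals=resid, covariance=cov,
                            converged=bool(best.success),
                            degenerate=bool(b <= 10 * _B_LO),
                            sse=float(2 * best.cost))


def grid_search_power_law(sizes, cs_values, n_a: int = 61, n_b: int = 61,
                          n_c: int = 61) -> tuple[float, float, float, float]:
    """Coarse brute-force grid minimizer of the same SSE objective.

    A slow, independent cross-check for the TRF fit: returns
    ``(a, b, c, sse)`` of the best grid point.
    """
    l = np.asarray(sizes, dtype=float)
    y = np.asarray(cs_values, dtype=float)
    a_grid = np.linspace(-1, 1, n_a)
    b_grid = np.geomspace(1e-3, 10, n_b)
    c_grid = np.geomspace(1e-2, 5, n_c)
    best = (np.nan, np.nan, np.nan, np.inf)
    for a in a_grid:
        for b in b_grid:
            pred = a - b * np.power(l[None, :], -c_grid[:, None])
            sse = np.sum((pred - y[None, :]) ** 2, axis=1)
            k = int(np.argmin(sse))
            if sse[k] < best[3]:
                best = (float(a), float(b), float(c_grid[k]), float(sse[k]))
    return best
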
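"""Least-absolute-deviation regression estimators used for target inference.

Two scikit-learn style regressors form the core of the package:

``LADRegressor``
    Linear regression under the L1 (sum of absolute residuals) loss with
    sign-constrained slopes, solved exactly as a linear program.

``HingeLADRegressor``
    Piecewise-linear (hinge) regression under the same loss.  Each predictor
    contributes ``min(0, beta_i * x_i + gamma_i)`` with ``beta_i <= 0``: no
    effect below the implied breakpoint ``b_i = -gamma_i / beta_i`` and a
    linear repressive effect above it, continuous at the breakpoint.  The
    fit is a mixed-integer linear program: one binary per (predictor,
    sample) records which side of the breakpoint the sample lies on, and a
    big-M construction links the binaries to the hinge value.  Because the
    slopes are non-positive, the hinge argument is monotone in x, so the
    binaries must follow a threshold pattern in sorted-x order; the solver
    is given those ordering constraints explicitly, which prunes the search
    space from 2^S patterns to S+1 per predictor.

Both solve to proven global optimality with the HiGHS backend shipped in
SciPy.  ``fit_hinge_grid`` is an independent single-predictor oracle that
enumerates candidate breakpoints and solves one LP per breakpoint; it is
used to cross-check the MILP.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, linprog, milp
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = ["LADRegressor", "HingeLADRegressor", "fit_hinge_grid"]

#: slope magnitude below which a predictor is considered inactive
SLOPE_TOL = 1e-6


def _solve_lad_lp(X: np.ndarray, y: np.ndarray, bound: float,
                  nonpositive: bool) -> tuple[float, np.ndarray, np.ndarray]:
    """Exact LAD fit: min sum |y - alpha - X beta| as an LP.

    Variables: alpha, beta (n_features), eps+ (S), eps- (S).
    Returns (alpha, beta, residuals).
    """
    S, K = X.shape
    n = 1 + K + 2 * S
    c = np.zeros(n)
    c[1 + K:] = 1.0
    A = np.zeros((S, n))
    A[:, 0] = 1.0
    A[:, 1:1 + K] = X
    A[:, 1 + K:1 + K + S] = np.eye(S)
    A[:, 1 + K + S:] = -np.eye(S)
    beta_hi = 0.0 if nonpositive else bound
    bounds = (
        [(-bound, bound)]
        + [(-bound, beta_hi)] * K
        + [(0.0, None)] * (2 * S)
    )
    res = linprog(c, A_eq=A, b_eq=y, bounds=bounds, method="highs")
    if res.status != 0:
        raise RuntimeError(f"LAD linear program failed: {res.message}")
    alpha = float(res.x[0])
    beta = res.x[1:1 + K].copy()
    residuals = y - (alpha + X @ beta)
    return alpha, beta, residuals


class LADRegressor(RegressorMixin, BaseEstimator):
    """Linear least-absolute-deviation regression with non-positive slopes.

    Parameters
    ----------
    bound : float, default 10.0
        Box bound B on |intercept| and |slopes|; generous for z-scored data.
    nonpositive : bool, default True
        Constrain every slope to be <= 0 (repression only).

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray of shape (n_features,)
    residuals_ : ndarray of shape (n_samples,)
    sae_ : float
        Sum of absolute residuals at the optimum.
    """

    def __init__(self, bound: float = 10.0, nonpositive: bool = True):
        self.bound = bound
        self.nonpositive = nonpositive

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        self.intercept_, self.coef_, self.residuals_ = _solve_lad_lp(
            X, y, self.bound, self.nonpositive
        )
        self.sae_ = float(np.abs(self.residuals_).sum())
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return self.intercept_ + X @ self.coef_


class HingeLADRegressor(RegressorMixin, BaseEstimator):
    """Piecewise-linear LAD regression solved as a mixed-integer program.

    The model is ``y = alpha + sum_i min(0, beta_i x_i + gamma_i)`` with
    ``beta_i <= 0``: each predictor is inert below its breakpoint
    ``b_i = -gamma_i / beta_i`` and linearly repressive above it.

    Parameters
    ----------
    bound : float, default 10.0
        Box bound B on |alpha| and |beta_i|; |gamma_i| is bounded by
        B * (1 + max_s |x_is|).
    time_limit : float, default 60.0
        Solver wall-clock limit in seconds.  A fit that is not proven
        optimal within the limit sets ``optimal_ = False``.
    mip_gap : float, default 1e-6
        Relative optimality gap tolerance.

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray (n_features,)         -- slopes beta_i <= 0
    offsets_ : ndarray (n_features,)      -- offsets gamma_i
    breakpoints_ : ndarray (n_features,)  -- -gamma_i/beta_i, NaN if beta_i ~ 0
    below_threshold_ : ndarray (n_samples, n_features) of bool
        Solver's per-sample segment indicators (True = inert segment).
    big_m_ : ndarray (n_features,)        -- per-predictor big-M constants
    residuals_ : ndarray (n_samples,)
    sae_ : float
    optimal_ : bool
    status_ : str
    """

    def __init__(self, bound: float = 10.0, time_limit: float = 60.0,
                 mip_gap: float = 1e-6):
        self.bound = bound
        self.time_limit = time_limit
        self.mip_gap = mip_gap

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        S, K = X.shape
        B = float(self.bound)
        nu = K * S
        # variable layout: alpha | beta (K) | gamma (K) | u (K*S) | z (K*S)
        #                  | eps+ (S) | eps- (S)
        ia, ib, ig = 0, 1, 1 + K
        iu, iz = 1 + 2 * K, 1 + 2 * K + nu
        ie, if_ = iz + nu, iz + nu + S
        n = if_ + S

        absX = np.abs(X)
        gamma_bound = B * (1.0 + absX.max(axis=0))
        big_m = B * (1.0 + 2.0 * absX.max(axis=0)) + B
        # per-cell M, never exceeding the per-predictor constant
        M = np.minimum(big_m[None, :], B * absX + gamma_bound[None, :])

        c = np.zeros(n)
        c[ie:] = 1.0

        # equality: y_s = alpha + sum_i u_is + eps+_s - eps-_s
        Aeq = np.zeros((S, n))
        Aeq[:, ia] = 1.0
        for i in range(K):
            Aeq[np.arange(S), iu + i * S + np.arange(S)] = 1.0
        Aeq[:, ie:ie + S] = np.eye(S)
        Aeq[:, if_:] = -np.eye(S)
        constraints = [LinearConstraint(Aeq, y, y)]

        rows: list[int] = []
        cols: list[int] = []
        vals: list[float] = []
        ub: list[float] = []
        r = 0

        def add(entries, rhs):
            nonlocal r
            for col, v in entries:
                rows.append(r)
                cols.append(col)
                vals.append(v)
            ub.append(rhs)
            r += 1

        for i in range(K):
            for s in range(S):
                u = iu + i * S + s
                z = iz + i * S + s
                xs = X[s, i]
                m = M[s, i]
                # l_is = beta_i x_is + gamma_i
                add([(u, 1.0), (ib + i, -xs), (ig + i, -1.0)], 0.0)   # u <= l
                add([(u, -1.0), (ib + i, xs), (ig + i, 1.0), (z, -m)], 0.0)  # u >= l - M z
                add([(u, -1.0), (z, m)], m)                            # u >= -M (1 - z)
                add([(ib + i, xs), (ig + i, 1.0), (z, -m)], 0.0)       # l <= M z
                add([(ib + i, -xs), (ig + i, -1.0), (z, m)], m)        # l >= -M (1 - z)
            # beta <= 0 makes l monotone non-increasing in x, so the inert
            # segment is a lower set in x-order: z non-increasing along
            # ascending x (threshold pattern).
            order = np.argsort(X[:, i], kind="stable")
            for j in range(S - 1):
                add([(iz + i * S + order[j + 1], 1.0),
                     (iz + i * S + order[j], -1.0)], 0.0)

        Aub = sp.csr_matrix((vals, (rows, cols)), shape=(r, n))
        constraints.append(LinearConstraint(Aub, -np.inf, np.asarray(ub)))

        lb = np.full(n, -np.inf)
        hb = np.full(n, np.inf)
        lb[ia], hb[ia] = -B, B
        lb[ib:ib + K], hb[ib:ib + K] = -B, 0.0
        lb[ig:ig + K], hb[ig:ig + K] = -gamma_bound, gamma_bound
        lb[iu:iu + nu] = -(M.T).reshape(-1)
        hb[iu:iu + nu] = 0.0
        lb[iz:iz + nu], hb[iz:iz + nu] = 0.0, 1.0
        lb[ie:] = 0.0

        integrality = np.zeros(n)
        integrality[iz:iz + nu] = 1.0

        res = milp(
            c,
            constraints=constraints,
            bounds=Bounds(lb, hb),
            integrality=integrality,
            options={"time_limit": float(self.time_limit),
                     "mip_rel_gap": float(self.mip_gap)},
        )
        if res.x is None:
            raise RuntimeError(f"hinge MILP failed: {res.message}")

        self.intercept_ = float(res.x[ia])
        self.coef_ = res.x[ib:ib + K].copy()
        self.offsets_ = res.x[ig:ig + K].copy()
        with np.errstate(divide="ignore", invalid="ignore"):
            bp = -self.offsets_ / self.coef_
        bp[np.abs(self.coef_) < SLOPE_TOL] = np.nan
        self.breakpoints_ = bp
        self.below_threshold_ = (
            res.x[iz:iz + nu].reshape(K, S).T > 0.5
        )
        self.big_m_ = big_m
        self.residuals_ = y - self.predict(X)
        self.sae_ = float(np.abs(self.residuals_).sum())
        self.optimal_ = bool(res.status == 0)
        self.status_ = str(res.message)
        self.n_features_in_ = K
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = check_array(X)
        hinge = np.minimum(0.0, X * self.coef_[None, :] + self.offsets_[None, :])
        return self.intercept_ + hinge.sum(axis=1)


def fit_hinge_grid(x: np.ndarray, y: np.ndarray, bound: float = 10.0) -> dict:
    """Single-predictor hinge-LAD oracle by segment-pattern enumeration.

    Because the slope is non-positive, the inert segment of an optimal
    hinge is always a lower set of the sorted unique x values, so only
    m+1 segment patterns exist (m = number of unique x values), from
    "hinge active everywhere" (the nested linear model) to "inert
    everywhere" (the constant model).  For each pattern the fit is an
    exact LP in (alpha, beta, gamma): inert samples see ``y ~ alpha``,
    active samples ``y ~ alpha + beta x + gamma``, with boundary sign
    constraints pinning the breakpoint -gamma/beta inside the pattern's
    x-gap.  Returns the minimum-SAE solution over all patterns.

    This routine shares no code with :class:`HingeLADRegressor` beyond the
    generic LP backend and serves as its independent cross-check.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    S = len(x)
    ux = np.unique(x)
    gamma_bound = bound * (1.0 + np.abs(x).max())
    best = None
    for t in range(len(ux) + 1):
        # samples taking the t smallest unique values are inert
        inert = x <= (ux[t - 1] if t > 0 else -np.inf)
        active = ~inert
        # variables: alpha, beta, gamma, eps+ (S), eps- (S)
        n = 3 + 2 * S
        c = np.zeros(n)
        c[3:] = 1.0
        A_eq = np.zeros((S, n))
        A_eq[:, 0] = 1.0
        A_eq[active, 1] = x[active]
        A_eq[active, 2] = 1.0
        A_eq[:, 3:3 + S] = np.eye(S)
        A_eq[:, 3 + S:] = -np.eye(S)
        # boundary sign constraints: beta*x + gamma >= 0 on the largest
        # inert x, <= 0 on the smallest active x (monotone in between)
        A_ub, b_ub = [], []
        if t > 0:
            A_ub.append([0.0, -ux[t - 1], -1.0] + [0.0] * (2 * S))
            b_ub.append(0.0)
        if t < len(ux):
            A_ub.append([0.0, ux[t], 1.0] + [0.0] * (2 * S))
            b_ub.append(0.0)
        bounds = ([(-bound, bound), (-bound, 0.0),
                   (-gamma_bound, gamma_bound)] + [(0.0, None)] * (2 * S))
        res = linprog(c, A_eq=A_eq, b_eq=y,
                      A_ub=np.array(A_ub) if A_ub else None,
                      b_ub=np.array(b_ub) if b_ub else None,
                      bounds=bounds, method="highs")
        if res.status != 0:
            raise RuntimeError(f"hinge oracle LP failed: {res.message}")
        sae = float(res.fun)
        if best is None or sae < best["sae"]:
            beta_v = float(res.x[1])
            gamma_v = float(res.x[2])
            best = {
                "sae": sae,
                "alpha": float(res.x[0]),
                "beta": beta_v,
                "gamma": gamma_v,
                "breakpoint": (-gamma_v / beta_v
                               if abs(beta_v) >= SLOPE_TOL else np.nan),
                "n_patterns": len(ux) + 1,
            }
    return best
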
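"""Independent oracles used only by the test suite.

Each oracle solves the same problem as the implementation by a different,
brute-force route: dense search over rotation space for superposition,
exhaustive vertex enumeration for the weight LP, grid-plus-polish search for
the SVC objective, penalized IRLS for the logistic fit, and pair counting
for ROC.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def brute_force_min_residual(S, T, weights, n_grid: int = 20) -> float:
    """Minimum weighted sum of squared distances over all rigid motions,
    by dense rotation sampling followed by local polish."""
    S = np.asarray(S, float)
    T = np.asarray(T, float)
    w = np.asarray(weights, float)
    w = w / w.sum()
    s_bar = w @ S
    t_bar = w @ T
    S0, T0 = S - s_bar, T - t_bar

    def residual_for(R):
        diff = S0 @ R.T - T0
        return float(w @ np.einsum("ij,ij->i", diff, diff))

    angles = np.linspace(0.0, 2 * np.pi, n_grid, endpoint=False)
    best = np.inf
    best_rotvec = np.zeros(3)
    # Dense Euler-angle grid (z-y-z covers SO(3))
    grid = np.array(list(itertools.product(angles, angles / 2, angles)))
    rots = Rotation.from_euler("zyz", grid)
    mats = rots.as_matrix()
    diffs = np.einsum("kij,nj->kni", mats, S0) - T0[None]
    residuals = np.einsum("n,kni,kni->k", w, diffs, diffs)
    k = int(np.argmin(residuals))
    best = residuals[k]
    best_rotvec = rots[k].as_rotvec()

    def objective(rv):
        return residual_for(Rotation.from_rotvec(rv).as_matrix())

    for method in ("BFGS", "Nelder-Mead"):
        res = minimize(objective, best_rotvec, method=method,
                       options={"maxiter": 5000})
        best = min(best, float(res.fun))
        best_rotvec = res.x if res.fun <= best else best_rotvec
    return float(best)


def lp_vertex_enum_objective(F, labels, costs, epsilon, upper=None) -> float:
    """Exact optimum of the weight LP by vertex enumeration.

    Variables x = [beta (m), theta, xi (n)].  The equality sum(beta) = 1 is
    always active; every vertex is defined by dim-1 additional active
    inequality constraints.  Feasible vertices are enumerated exhaustively.
    """
    F = np.asarray(F, float)
    y = np.asarray(labels)
    c_vec = np.asarray(costs, float)
    n, m = F.shape
    if upper is None:
        upper = 2.0 / m
    dim = m + 1 + n
    obj = np.concatenate([np.zeros(m + 1), c_vec])

    rows = []
    rhs = []
    for j in range(n):  # hinge constraints (as <=)
        row = np.zeros(dim)
        if y[j] == 1:
            row[:m] = F[j]
            row[m] = -1.0
        else:
            row[:m] = -F[j]
            row[m] = 1.0
        row[m + 1 + j] = -1.0
        rows.append(row)
        rhs.append(-epsilon)
    for i in range(m):  # beta bounds
        row = np.zeros(dim)
        row[i] = -1.0
        rows.append(row)
        rhs.append(0.0)
        row = np.zeros(dim)
        row[i] = 1.0
        rows.append(row)
        rhs.append(upper)
    for j in range(n):  # xi >= 0
        row = np.zeros(dim)
        row[m + 1 + j] = -1.0
        rows.append(row)
        rhs.append(0.0)
    A = np.array(rows)
    b = np.array(rhs)
    eq_row = np.zeros(dim)
    eq_row[:m] = 1.0

    best = np.inf
    n_ineq = A.shape[0]
    for combo in itertools.combinations(range(n_ineq), dim - 1):
        M = np.vstack([eq_row, A[list(combo)]])
        v = np.concatenate([[1.0], b[list(combo)]])
        if abs(np.linalg.det(M)) < 1e-12:
            continue
        x = np.linalg.solve(M, v)
        if np.all(A @ x <= b + 1e-9):
            best = min(best, float(obj @ x))
    return best


def svc_min_objective(X, labels, costs, epsilon: float = 1.0,
                      n_grid: int = 41, span: float = 50.0) -> float:
    """Minimum of 0.5||w||^2 + sum C_j hinge over (w, theta) by coarse grid
    plus Nelder-Mead polish (the objective is convex)."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(labels):
        X = X.T
    y = np.asarray(labels)
    c = np.asarray(costs, float)
    d = X.shape[1]

    def objective(params):
        w = params[:d]
        theta = params[d]
        margins = X @ w
        loss = np.where(y == 1,
                        np.maximum(0.0, (theta + epsilon) - margins),
                        np.maximum(0.0, margins - (theta - epsilon)))
        return 0.5 * w @ w + c @ loss

    axes = [np.linspace(-span, span, n_grid)] * (d + 1)
    points = np.array(list(itertools.product(*axes)))
    values = np.array([objective(p) for p in points])
    order = np.argsort(values)
    best = float(values[order[0]])
    starts = [points[k] for k in order[:8]] + [np.zeros(d + 1)]
    for start in starts:
        for method, opts in (
                ("Nelder-Mead", {"xatol": 1e-11, "fatol": 1e-13,
                                 "maxiter": 50000, "maxfev": 50000,
                                 "adaptive": True}),
                ("Powell", {"xtol": 1e-12, "ftol": 1e-14,
                            "maxiter": 50000})):
            res = minimize(objective, start, method=method, options=opts)
            best = min(best, float(res.fun))
    return best


def irls_logistic(scores, labels, ridge: float = 1e-6, tol: float = 1e-12,
                  max_iter: int = 500) -> tuple[float, float]:
    """Penalized logistic MLE by Newton (IRLS); ridge on the slope only,
    matching an L2-regularized fit with unpenalized intercept."""
    x = np.asarray(scores, float)
    t = (np.asarray(labels) == 1).astype(float)
    X = np.column_stack([x, np.ones_like(x)])
    beta = np.zeros(2)
    P = np.diag([ridge, 0.0])
    for _ in range(max_iter):
        z = X @ beta
        p = 1.0 / (1.0 + np.exp(-z))
        grad = X.T @ (p - t) + P @ beta
        W = p * (1 - p)
        H = X.T @ (X * W[:, None]) + P
        step = np.linalg.solve(H, grad)
        beta = beta - step
        if np.max(np.abs(step)) < tol:
            break
    return float(beta[0]), float(beta[1])


def roc_pair_count(scores, labels) -> float:
    """ROC AUC as the Mann-Whitney pair statistic with half-credit ties."""
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == -1]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((wins + 0.5 * ties) / (pos.size * neg.size))
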
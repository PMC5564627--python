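"""Independent reference solvers used to cross-check the package.

Everything here is deliberately written without reusing the package's
update routines: a plain (non-accelerated) projected-gradient solver for
X, per-column least squares for B1, scikit-learn's Lasso for the
lasso-penalized B2 subproblem, cyclic row-wise block coordinate descent
with the group soft-threshold for the row-sparse B2 subproblem, and
per-coordinate 1-D numerical minimization for the mixed-penalty B2
subproblem.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.linear_model import Lasso


def pg_update_x(Y, B, X0, n_iter=3000, tol=1e-14):
    """Long-run plain projected gradient for min ||Y - XB||^2, unit columns."""
    G = B @ B.T
    C = Y @ B.T
    L = np.linalg.norm(G, 2)
    if L < 1e-300:
        return X0.copy()
    mu = 1.0 / (2.0 * L)
    X = X0.copy()
    f_old = np.inf
    for _ in range(n_iter):
        X = X - mu * 2.0 * (X @ G - C)
        nrm = np.linalg.norm(X, axis=0)
        over = nrm > 1
        X[:, over] /= nrm[over]
        f = ((Y - X @ B) ** 2).sum()
        if abs(f_old - f) <= tol * max(1.0, f):
            break
        f_old = f
    return X


def b1_restricted_ols(Y1, X, H1):
    """Per-gene least squares on the H1 support via explicit lstsq."""
    K, G1 = H1.shape
    B1 = np.zeros((K, G1))
    for q in range(G1):
        s = H1[:, q] > 0
        if s.any():
            B1[np.ix_(s, [q])] = np.linalg.lstsq(X[:, s], Y1[:, [q]],
                                                 rcond=None)[0]
    return B1


def b2_subproblem_objective(ds, X, B2, prior, l1, l2):
    """Exact B2 sub-objective: masked RSS + mixed penalty with the H2 split."""
    R = ds.Y2 - X @ B2
    rss = float((R * R)[ds.mask2].sum())
    unk = prior.H2 == 0
    pen = l1 * np.abs(np.where(unk, B2, 0.0)).sum()
    pen += l2 * np.sqrt((np.where(unk, B2, 0.0) ** 2).sum(axis=1)).sum()
    pen += l2 * (B2[~unk] ** 2).sum()
    return rss + float(pen)


def b2_coordinate_oracle(ds, X, prior, l1, l2, n_sweeps=4000, tol=1e-12):
    """Cyclic per-coordinate exact minimization of the B2 subproblem.

    Each coordinate solve is a 1-D convex problem
    a t^2 - 2 r t + l1 |t| + l2 sqrt(t^2 + c^2), minimized numerically
    (with an explicit check of t = 0, the only non-smooth point).
    """
    K, G2 = prior.n_pathways, ds.n_drugs
    B = np.zeros((K, G2))
    unk = prior.H2 == 0
    for _ in range(n_sweeps):
        delta = 0.0
        for q in range(G2):
            rows = ds.mask2[:, q]
            Xq = X[rows]
            yq = ds.Y2[rows, q]
            for i in range(K):
                xi = Xq[:, i]
                a = float(xi @ xi)
                resid = yq - Xq @ B[:, q] + xi * B[i, q]
                r = float(xi @ resid)
                c2 = float((np.where(unk[i], B[i], 0.0) ** 2).sum()
                           - (B[i, q] ** 2 if unk[i, q] else 0.0))
                c2 = max(c2, 0.0)
                if not unk[i, q]:
                    t = r / (a + l2) if (a + l2) > 0 else 0.0
                else:
                    def f(t):
                        return (a * t * t - 2 * r * t + l1 * abs(t)
                                + l2 * np.sqrt(t * t + c2))
                    M = (abs(r) + l1 + l2) / max(a, 1e-12) + abs(B[i, q]) + 1.0
                    res = minimize_scalar(f, bounds=(-M, M), method="bounded",
                                          options={"xatol": 1e-14})
                    t = float(res.x) if f(float(res.x)) < f(0.0) else 0.0
                delta = max(delta, abs(t - B[i, q]))
                B[i, q] = t
        if delta < tol:
            break
    return B


def ipad_reference(ds, prior, lam, X0, n_outer=3000, tol=1e-11):
    """Independent lasso-penalized joint decomposition (complete data).

    B2 columns are fitted with scikit-learn's Lasso (coordinate descent),
    matching ||y - Xb||^2 + lam ||b||_1 via alpha = lam / (2N).
    """
    X = X0.copy()
    B1 = prior.H1.astype(float)
    B2 = np.zeros((prior.n_pathways, ds.n_drugs))
    n = ds.n_samples
    obj_old = np.inf
    obj = np.inf
    for _ in range(n_outer):
        Y = np.hstack([ds.Y1, ds.Y2])
        B = np.hstack([B1, B2])
        X = pg_update_x(Y, B, X)
        B1 = b1_restricted_ols(ds.Y1, X, prior.H1)
        las = Lasso(alpha=lam / (2 * n), fit_intercept=False, tol=1e-14,
                    max_iter=100000)
        las.fit(X, ds.Y2)
        B2 = las.coef_.T.copy()
        obj = (((ds.Y1 - X @ B1) ** 2).sum() + ((ds.Y2 - X @ B2) ** 2).sum()
               + lam * np.abs(B2).sum())
        if abs(obj_old - obj) <= tol * max(1.0, obj):
            break
        obj_old = obj
    return X, B1, B2, float(obj)


def l21_reference(ds, prior, lam, X0, n_outer=3000, tol=1e-11,
                  max_sweeps=10000):
    """Independent row-sparse joint decomposition (complete data).

    The B2 subproblem is solved by cyclic block coordinate descent over
    pathway rows with the closed-form group soft-threshold
    b_i = (x_i' R) (1 - lam / (2 ||x_i' R||))_+ / (x_i' x_i).
    """
    X = X0.copy()
    B1 = prior.H1.astype(float)
    K = prior.n_pathways
    B2 = np.zeros((K, ds.n_drugs))
    obj_old = np.inf
    obj = np.inf
    for _ in range(n_outer):
        Y = np.hstack([ds.Y1, ds.Y2])
        B = np.hstack([B1, B2])
        X = pg_update_x(Y, B, X)
        B1 = b1_restricted_ols(ds.Y1, X, prior.H1)
        for _sweep in range(max_sweeps):
            delta = 0.0
            for i in range(K):
                xi = X[:, i]
                a = float(xi @ xi)
                R = ds.Y2 - X @ B2 + np.outer(xi, B2[i])
                c = xi @ R
                nc = np.linalg.norm(c)
                if a > 0 and 2 * nc > lam:
                    new = c * (1 - lam / (2 * nc)) / a
                else:
                    new = np.zeros_like(c)
                delta = max(delta, float(np.abs(new - B2[i]).max(initial=0.0)))
                B2[i] = new
            if delta < 1e-13:
                break
        obj = (((ds.Y1 - X @ B1) ** 2).sum() + ((ds.Y2 - X @ B2) ** 2).sum()
               + lam * np.linalg.norm(B2, axis=1).sum())
        if abs(obj_old - obj) <= tol * max(1.0, obj):
            break
        obj_old = obj
    return X, B1, B2, float(obj)
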
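"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from first principles (explicit
per-window least squares, SVD-based PLS, direct leave-one-out loops) and
never calls the code paths it checks.
"""

from __future__ import annotations

import numpy as np


def savgol_bruteforce(y: np.ndarray, x: np.ndarray, window: int, polyorder: int,
                      deriv: int = 0) -> np.ndarray:
    """Per-point polynomial fit on the physical axis, polynomial-extension edges.

    For each interior point, fit a degree-``polyorder`` polynomial to the
    centred window by least squares and evaluate its ``deriv``-th derivative
    at the point.  Edge points reuse the polynomial fitted to the first/last
    full window.
    """
    n = y.size
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        if i < half:
            sel = slice(0, window)
        elif i >= n - half:
            sel = slice(n - window, n)
        else:
            sel = slice(i - half, i + half + 1)
        # centre the abscissa for conditioning
        xi = x[sel] - x[i]
        coeffs = np.polyfit(xi, y[sel], polyorder)  # highest power first
        poly = np.polynomial.Polynomial(coeffs[::-1])
        out[i] = poly.deriv(deriv)(0.0) if deriv else poly(0.0)
    return out


def svd_pls1(X: np.ndarray, y: np.ndarray, F: int):
    """PLS1 via per-component SVD of the cross-covariance, with deflation.

    Returns (predict_fn, coefficient vector).  Predictions are built by
    accumulating score regressions, a different composition than the
    W (P'W)^-1 q route.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    Ws, Ps, qs = [], [], []
    Xd, yd = Xc.copy(), yc.copy()
    for _ in range(F):
        cov = (Xd.T @ yd).reshape(-1, 1)
        U, s, _ = np.linalg.svd(cov, full_matrices=False)
        if s[0] < 1e-13:
            break
        w = U[:, 0]
        t = Xd @ w
        tt = t @ t
        p = Xd.T @ t / tt
        q = yd @ t / tt
        Xd = Xd - np.outer(t, p)
        yd = yd - q * t
        Ws.append(w); Ps.append(p); qs.append(q)
    W = np.column_stack(Ws)
    P = np.column_stack(Ps)
    q = np.array(qs)

    def predict_fn(Xnew: np.ndarray) -> np.ndarray:
        Xn = np.atleast_2d(Xnew) - x_mean
        yhat = np.full(Xn.shape[0], y_mean)
        Xd = Xn.copy()
        for f in range(W.shape[1]):
            t = Xd @ W[:, f]
            yhat = yhat + q[f] * t
            Xd = Xd - np.outer(t, P[:, f])
        return yhat

    b = W @ np.linalg.solve(P.T @ W, q)
    return predict_fn, b


def ols_coefficients(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Centred ordinary least squares via the normal equations."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    return np.linalg.solve(Xc.T @ Xc, Xc.T @ yc)


def loo_rmse_path(X: np.ndarray, y: np.ndarray, max_F: int) -> np.ndarray:
    """Direct leave-one-out CV of PLS1 using the SVD oracle, per factor count."""
    n = X.shape[0]
    errs = np.empty((n, max_F))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        for F in range(1, max_F + 1):
            pred, _ = svd_pls1(X[mask], y[mask], F)
            errs[i, F - 1] = pred(X[i:i + 1])[0] - y[i]
    return np.sqrt((errs ** 2).mean(axis=0))
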
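"""PLS1 regression by NIPALS, segmented cross-validation, parsimonious factor
selection and Martens' jackknife uncertainty test for variable selection.

The model is a single-response (PLS1) latent-factor regression.  With centred
design X and response y, each factor extracts

    w = X'y / ||X'y||        (weight)
    t = X w                  (score)
    p = X't / t't            (X loading)
    q = y't / t't            (y loading)

followed by deflation X <- X - t p', y <- y - q t.  The absorbance-space
regression coefficients are b = W (P'W)^-1 q so that yhat = y_mean +
(x - x_mean) . b.  Centring is done internally and stored on the model.

Cross-validation is leave-one-segment-out over seeded random, equally sized
contiguous blocks.  Martens' uncertainty test forms the jackknife variance of
each coefficient over the segment submodels and keeps a wavenumber only when
its full-model coefficient is significantly nonzero under a two-sided t test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import stats

__all__ = [
    "PLSModel",
    "CVResult",
    "fit_pls1",
    "predict",
    "segmented_cv",
    "select_factors",
    "martens_uncertainty",
]


@dataclass
class PLSModel:
    """Fitted PLS1 model.

    ``b`` maps *centred* selected variables to the centred response; the
    ``selected`` mask records which of the ``n_vars_full`` original variables
    entered the fit (``b_full`` scatters b back onto the full axis with zeros
    elsewhere).  ``score_var`` holds the training score variances (ddof=1)
    used by the Hotelling T-squared diagnostic.
    """

    F: int
    W: np.ndarray
    P: np.ndarray
    q: np.ndarray
    b: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    score_var: np.ndarray
    selected: np.ndarray
    response_name: str = ""
    n_train: int = 0

    @property
    def n_vars_full(self) -> int:
        return self.selected.size

    @property
    def b_full(self) -> np.ndarray:
        out = np.zeros(self.selected.size)
        out[self.selected] = self.b
        return out

    @property
    def x_mean_full(self) -> np.ndarray:
        out = np.zeros(self.selected.size)
        out[self.selected] = self.x_mean
        return out

    def rotation(self) -> np.ndarray:
        """R = W (P'W)^-1 : projects centred X onto scores, t = Xc R."""
        return self.W @ np.linalg.inv(self.P.T @ self.W)

    def to_json(self, path, grid: np.ndarray | None = None, extra: dict | None = None) -> None:
        doc = {
            "F": int(self.F),
            "response_name": self.response_name,
            "n_train": int(self.n_train),
            "W": self.W.tolist(), "P": self.P.tolist(), "q": self.q.tolist(),
            "b": self.b.tolist(), "x_mean": self.x_mean.tolist(),
            "y_mean": float(self.y_mean), "score_var": self.score_var.tolist(),
            "selected": self.selected.astype(int).tolist(),
        }
        if grid is not None:
            doc["grid"] = np.asarray(grid).tolist()
        if extra:
            doc.update(extra)
        with open(path, "w") as fh:
            json.dump(doc, fh)


def _nipals(Xc: np.ndarray, yc: np.ndarray, F: int):
    """Raw NIPALS PLS1 on centred data; returns W, P, q, scores (n x F)."""
    n, p = Xc.shape
    W = np.empty((p, F))
    P = np.empty((p, F))
    q = np.empty(F)
    T = np.empty((n, F))
    X = Xc.copy()
    y = yc.copy()
    used = 0
    for f in range(F):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < 1e-13 * max(1.0, np.linalg.norm(Xc)):
            break  # rank exhausted
        w /= nw
        t = X @ w
        tt = t @ t
        if tt <= 0:
            break
        p_f = X.T @ t / tt
        q_f = y @ t / tt
        X -= np.outer(t, p_f)
        y = y - q_f * t
        W[:, f], P[:, f], q[f], T[:, f] = w, p_f, q_f, t
        used += 1
    if used == 0:
        raise ValueError("no PLS factor could be extracted (zero covariance)")
    return W[:, :used], P[:, :used], q[:used], T[:, :used]


def fit_pls1(X: np.ndarray, y: np.ndarray, F: int,
             selected: np.ndarray | None = None,
             response_name: str = "") -> PLSModel:
    """Fit a PLS1 model with ``F`` factors.

    ``X`` holds raw (preprocessed) absorbances; centring is internal.  An
    optional boolean ``selected`` mask restricts the fit to a variable
    subset while keeping the full-axis bookkeeping on the model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p_full = X.shape
    if y.size != n:
        raise ValueError("X and y disagree on the number of samples")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite entries in X or y")
    if np.var(y) == 0:
        raise ValueError("zero-variance response")
    if F < 1:
        raise ValueError("F must be >= 1")
    if F >= n:
        raise ValueError(f"F={F} requires more than {n} samples")
    if selected is None:
        selected = np.ones(p_full, dtype=bool)
    else:
        selected = np.asarray(selected, dtype=bool)
        if selected.size != p_full:
            raise ValueError("selected mask length must equal n_vars")
        if not selected.any():
            raise ValueError("selected mask excludes every variable")
    Xs = X[:, selected]
    x_mean = Xs.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, T = _nipals(Xs - x_mean, y - y_mean, F)
    b = W @ np.linalg.solve(P.T @ W, q)
    return PLSModel(F=W.shape[1], W=W, P=P, q=q, b=b, x_mean=x_mean,
                    y_mean=y_mean, score_var=T.var(axis=0, ddof=1),
                    selected=selected, response_name=response_name, n_train=n)


def predict(m: PLSModel, X: np.ndarray) -> np.ndarray:
    """Predict the response: yhat = y_mean + (x - x_mean) . b on selected vars."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != m.n_vars_full:
        raise ValueError(
            f"X has {X.shape[1]} variables; model expects {m.n_vars_full}")
    return m.y_mean + (X[:, m.selected] - m.x_mean) @ m.b


def _coef_path(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Coefficient vectors b_F for every truncation F=1..F_max; (p, F_max)."""
    Fmax = W.shape[1]
    out = np.empty((W.shape[0], Fmax))
    for f in range(1, Fmax + 1):
        out[:, f - 1] = W[:, :f] @ np.linalg.solve(P[:, :f].T @ W[:, :f], q[:f])
    return out


@dataclass
class CVResult:
    """Leave-one-segment-out cross-validation over a factor-count path.

    ``rmsecv``/``r2cv`` are indexed by factor count (position f-1 holds F=f);
    ``predictions`` is (n_samples, max_F) of out-of-segment predictions;
    ``segment_of`` assigns each sample to its held-out segment;
    ``segment_coefs`` is (M, n_vars, max_F): submodel coefficient vectors.
    """

    rmsecv: np.ndarray
    r2cv: np.ndarray
    predictions: np.ndarray
    segment_of: np.ndarray
    segment_coefs: np.ndarray
    seed: int | None = None
    settings: dict = dc_field(default_factory=dict)

    @property
    def n_segments(self) -> int:
        return self.segment_coefs.shape[0]

    @property
    def max_F(self) -> int:
        return self.rmsecv.size


def make_segments(n: int, n_segments: int, seed: int | None) -> np.ndarray:
    """Seeded shuffle, then contiguous blocks as equal as possible."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    seg = np.empty(n, dtype=int)
    for k, block in enumerate(np.array_split(order, n_segments)):
        seg[block] = k
    return seg


def segmented_cv(X: np.ndarray, y: np.ndarray, n_segments: int = 10,
                 max_F: int = 20, seed: int | None = None,
                 segments: np.ndarray | None = None,
                 selected: np.ndarray | None = None) -> CVResult:
    """Leave-one-segment-out CV, reporting RMSECV(F) for F = 1..max_F.

    Pass ``segments`` to reuse a fixed assignment (e.g. when re-running after
    variable selection on identical folds).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p_full = X.shape
    if segments is None:
        if not 2 <= n_segments <= n:
            raise ValueError("need 2 <= n_segments <= n_samples")
        segments = make_segments(n, n_segments, seed)
    else:
        segments = np.asarray(segments, dtype=int)
        n_segments = int(segments.max()) + 1
    if selected is None:
        selected = np.ones(p_full, dtype=bool)
    smallest_train = n - max(np.bincount(segments))
    if max_F >= smallest_train:
        raise ValueError(f"max_F={max_F} too large for a training fold of "
                         f"{smallest_train} samples")

    preds = np.empty((n, max_F))
    seg_coefs = np.zeros((n_segments, p_full, max_F))
    p_sel = int(selected.sum())
    for k in range(n_segments):
        hold = segments == k
        Xtr, ytr = X[~hold][:, selected], y[~hold]
        x_mean = Xtr.mean(axis=0)
        y_mean = ytr.mean()
        W, P, q, _ = _nipals(Xtr - x_mean, ytr - y_mean, min(max_F, p_sel))
        bpath = _coef_path(W, P, q)
        if bpath.shape[1] < max_F:  # rank exhausted: extend flat
            bpath = np.hstack([bpath] +
                              [bpath[:, -1:]] * (max_F - bpath.shape[1]))
        seg_coefs[k][selected] = bpath
        preds[hold] = y_mean + (X[hold][:, selected] - x_mean) @ bpath

    resid = preds - y[:, None]
    rmsecv = np.sqrt((resid ** 2).mean(axis=0))
    sst = np.sum((y - y.mean()) ** 2)
    r2cv = 1.0 - (resid ** 2).sum(axis=0) / sst
    return CVResult(rmsecv=rmsecv, r2cv=r2cv, predictions=preds,
                    segment_of=segments, segment_coefs=seg_coefs, seed=seed,
                    settings={"n_segments": n_segments, "max_F": max_F})


def select_factors(cv: CVResult, tol: float = 0.02) -> int:
    """Parsimony rule: smallest F with RMSECV(F) <= (1 + tol) * min RMSECV."""
    thresh = (1.0 + tol) * cv.rmsecv.min()
    return int(np.argmax(cv.rmsecv <= thresh)) + 1


def martens_uncertainty(X: np.ndarray, y: np.ndarray, F: int, cv: CVResult,
                        alpha: float = 0.05,
                        response_name: str = "") -> tuple[np.ndarray, PLSModel]:
    """Jackknife significance screening of regression coefficients.

    For M cross-validation segments, the jackknife variance of coefficient j
    is  s_j^2 = (M-1)/M * sum_k (b_j^(k) - b_j)^2  with b_j the full-model
    coefficient.  Variable j is kept iff |b_j| / s_j exceeds the two-sided t
    critical value at ``alpha`` with M-1 degrees of freedom (a coefficient
    with zero jackknife variance is kept whenever it is nonzero).  The model
    is refit on the kept variables at the same factor count.
    """
    if not 1 <= F <= cv.max_F:
        raise ValueError(f"F={F} outside the CV factor path 1..{cv.max_F}")
    full = fit_pls1(X, y, F, response_name=response_name)
    b = full.b_full
    M = cv.n_segments
    bk = cv.segment_coefs[:, :, F - 1]
    s2 = ((bk - b) ** 2).sum(axis=0) * (M - 1) / M
    s = np.sqrt(s2)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, M - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.abs(b) / s
    keep = np.where(s == 0, b != 0, tstat > tcrit)
    if not keep.any():
        raise ValueError("Martens' test rejected every variable; "
                         "consider a larger alpha")
    F_refit = min(F, int(keep.sum()))
    refit = fit_pls1(X, y, F_refit, selected=keep, response_name=response_name)
    return keep, refit
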
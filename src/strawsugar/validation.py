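"""Calibration / external-validation splitting and figures of merit.

Merit functions follow standard chemometric practice for sugar-release
calibrations (all in g g^-1 dry matter):

    R^2   = 1 - sum (y_i - f_i)^2 / sum (y_i - ybar)^2
    RMSE  = sqrt( sum (f_i - y_i)^2 / n )
    SDL   = sqrt( sum_j sum_i (y_ij - ybar_j)^2 / (m n - 1) )

SDL, the standard deviation of the laboratory reference method, is estimated
from m assay replicates of n samples; it is the floor on achievable
prediction error, and RMSE_EV / SDL close to 1 signals a calibration limited
only by reference precision.  The default SDL denominator (m*n - 1) is kept
for comparability with calibration-transfer reports; ``denominator="pooled"``
gives the unbiased within-sample estimator with n*(m - 1) degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import ResponseTable, SpectrumSet

__all__ = [
    "ValidationReport",
    "split_calibration",
    "r_squared",
    "rmse",
    "sdl",
    "rmse_sdl_ratio",
]


def r_squared(y: np.ndarray, f: np.ndarray) -> float:
    """Coefficient of determination, 1 - SSE/SST."""
    y = np.asarray(y, dtype=float).ravel()
    f = np.asarray(f, dtype=float).ravel()
    if y.size != f.size or y.size < 2:
        raise ValueError("need two equally long vectors of length >= 2")
    sst = np.sum((y - y.mean()) ** 2)
    if sst == 0:
        raise ValueError("zero-variance observations")
    return float(1.0 - np.sum((y - f) ** 2) / sst)


def rmse(y: np.ndarray, f: np.ndarray) -> float:
    """Root-mean-square error between observed y and predicted f."""
    y = np.asarray(y, dtype=float).ravel()
    f = np.asarray(f, dtype=float).ravel()
    if y.size != f.size or y.size < 1:
        raise ValueError("need two equally long non-empty vectors")
    return float(np.sqrt(np.mean((f - y) ** 2)))


def sdl(replicates: np.ndarray | pd.DataFrame, denominator: str = "printed") -> float:
    """Standard deviation of the laboratory method from an (n x m) replicate table.

    Rows are samples, columns replicates.  ``denominator="printed"`` uses
    m*n - 1; ``"pooled"`` uses n*(m - 1) (unbiased for the within-sample
    variance).
    """
    Y = np.asarray(replicates, dtype=float)
    if Y.ndim != 2:
        raise ValueError("replicate table must be 2-D (samples x replicates)")
    n, m = Y.shape
    if m < 2:
        raise ValueError("need at least 2 replicates per sample")
    ss = np.sum((Y - Y.mean(axis=1, keepdims=True)) ** 2)
    if denominator == "printed":
        dof = m * n - 1
    elif denominator == "pooled":
        dof = n * (m - 1)
    else:
        raise ValueError("denominator must be 'printed' or 'pooled'")
    return float(np.sqrt(ss / dof))


def sdl_from_table(r: ResponseTable, response: str,
                   denominator: str = "printed") -> float:
    """SDL for one response from a ResponseTable's replicate records."""
    if r.replicates is None:
        raise ValueError("response table has no replicate records")
    wide = (r.replicates[response]
            .groupby(level=0, sort=False)
            .apply(lambda s: pd.Series(s.to_numpy()))
            .unstack())
    return sdl(wide.to_numpy(), denominator=denominator)


def rmse_sdl_ratio(rmse_ev: float, sdl_value: float) -> float:
    """RMSE_EV / SDL; values near 1 mean the model is reference-limited."""
    if sdl_value <= 0:
        raise ValueError("SDL must be positive")
    return float(rmse_ev) / float(sdl_value)


def split_calibration(s: SpectrumSet, r: ResponseTable, frac: float = 2 / 3,
                      seed: int | None = None,
                      stratify_by: tuple[str, ...] | None = ("variety", "site"),
                      ) -> tuple[tuple[SpectrumSet, ResponseTable],
                                 tuple[SpectrumSet, ResponseTable]]:
    """Seeded random calibration / external-validation split.

    When metadata carries the stratification keys, allocation is per stratum
    with largest-remainder rounding towards a total calibration size of
    round(frac * n); every stratum with at least two samples is represented
    in both sets when possible.  Without usable keys the split is plain
    random.
    """
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    ids = np.array(s.sample_ids)
    n = ids.size
    rng = np.random.default_rng(seed)

    keys: pd.Series | None = None
    if stratify_by and s.metadata is not None:
        avail = [k for k in stratify_by if k in s.metadata.columns]
        if avail:
            keys = s.metadata.loc[list(ids), avail].astype(str).agg("|".join, axis=1)

    target_cal = int(round(frac * n))
    cal_ids: list[str] = []
    if keys is None:
        order = rng.permutation(n)
        cal_ids = list(ids[order[:target_cal]])
    else:
        strata = list(keys.groupby(keys).groups.items())
        sizes = np.array([len(v) for _, v in strata])
        exact = frac * sizes
        base = np.floor(exact).astype(int)
        # representation guard: strata with >= 2 samples keep one on each side
        base = np.where(sizes >= 2, np.clip(base, 1, sizes - 1), base)
        rem = target_cal - base.sum()
        frac_part = exact - np.floor(exact)
        order = np.argsort(-(frac_part + 1e-9 * rng.random(len(strata))))
        for idx in order:
            if rem <= 0:
                break
            if base[idx] < (sizes[idx] - 1 if sizes[idx] >= 2 else sizes[idx]):
                base[idx] += 1
                rem -= 1
        for (key, members), k in zip(strata, base):
            members = np.array(members)
            pick = rng.permutation(members.size)[:k]
            cal_ids.extend(members[pick])
    cal_set = set(cal_ids)
    ev_ids = [i for i in ids if i not in cal_set]
    cal_ids = [i for i in ids if i in cal_set]  # restore input order
    return ((s.select(cal_ids), r.select(cal_ids)),
            (s.select(ev_ids), r.select(ev_ids)))


@dataclass
class ValidationReport:
    """One row of the preprocessing-by-response evaluation table."""

    response_name: str
    preprocessing: str
    F: int
    r2_cv: float
    r2_ev: float
    rmse_cv: float
    rmse_ev: float
    sdl: float | None = None
    n_cal: int = 0
    n_ev: int = 0
    n_outliers: int = 0
    n_selected_vars: int | None = None

    @property
    def ratio(self) -> float | None:
        if self.sdl is None or self.sdl <= 0:
            return None
        return self.rmse_ev / self.sdl

    def to_dict(self) -> dict:
        d = {
            "response": self.response_name,
            "preprocessing": self.preprocessing,
            "F": self.F,
            "R2_CV": self.r2_cv, "R2_EV": self.r2_ev,
            "RMSE_CV": self.rmse_cv, "RMSE_EV": self.rmse_ev,
            "SDL": self.sdl, "RMSE_EV/SDL": self.ratio,
            "n_cal": self.n_cal, "n_ev": self.n_ev,
            "n_outliers": self.n_outliers,
            "n_selected_vars": self.n_selected_vars,
        }
        return d


def report_frame(reports: list[ValidationReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in reports])
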
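"""Influence diagnostics for PLS calibrations: Hotelling T-squared over the
score space and the Q residual (squared distance off the model plane).

Samples extreme in either statistic sit in the corners of the classical
influence plot and are screened out before the final calibration.  T-squared
limits come from the F-distribution-based Hotelling limit for fitted samples;
Q limits are empirical training quantiles, which avoids the fragility of
moment-based approximations at moderate n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pls import PLSModel, predict  # noqa: F401  (predict re-exported for reports)

__all__ = ["OutlierReport", "influence_stats", "flag_outliers"]


@dataclass
class OutlierReport:
    """Per-sample T-squared and Q with (optionally) flags and thresholds."""

    t2: np.ndarray
    q: np.ndarray
    sample_ids: list[str]
    F: int
    n_train: int
    t2_crit: float | None = None
    q_crit: float | None = None
    flags: np.ndarray | None = None

    @property
    def n_flagged(self) -> int:
        return 0 if self.flags is None else int(self.flags.sum())

    def flagged_ids(self) -> list[str]:
        if self.flags is None:
            return []
        return [s for s, f in zip(self.sample_ids, self.flags) if f]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sample_id": self.sample_ids, "T2": self.t2, "Q": self.q})
        if self.flags is not None:
            df["flagged"] = self.flags
        return df


def influence_stats(m: PLSModel, X: np.ndarray,
                    sample_ids: list[str] | None = None) -> OutlierReport:
    """Compute T-squared and Q for each row of ``X`` under model ``m``.

    Scores are t = (x - x_mean) W (P'W)^-1;  T2 = sum_f t_f^2 / var(t_f)
    with the training score variances;  Q = ||(x - x_mean) - t P'||^2 over
    the model's selected variables.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != m.n_vars_full:
        raise ValueError(f"X has {X.shape[1]} variables; model expects "
                         f"{m.n_vars_full}")
    Xc = X[:, m.selected] - m.x_mean
    T = Xc @ m.rotation()
    var = m.score_var.copy()
    safe = np.where(var > 0, var, np.inf)  # zero-variance factor contributes 0
    t2 = (T ** 2 / safe).sum(axis=1)
    resid = Xc - T @ m.P.T
    q = (resid ** 2).sum(axis=1)
    ids = sample_ids if sample_ids is not None else [str(i) for i in range(X.shape[0])]
    return OutlierReport(t2=t2, q=q, sample_ids=list(ids), F=m.F, n_train=m.n_train)


def hotelling_t2_limit(F: int, n: int, quantile: float = 0.975) -> float:
    """F-distribution-based Hotelling limit for calibration samples:
    T2_crit = F (n - 1) / (n - F) * F_ppf(quantile; F, n - F)."""
    if n <= F:
        return np.inf
    return F * (n - 1) / (n - F) * stats.f.ppf(quantile, F, n - F)


def flag_outliers(r: OutlierReport, t2_quantile: float = 0.975,
                  q_quantile: float = 0.975,
                  exclude_ids: list[str] | None = None,
                  reference: OutlierReport | None = None) -> OutlierReport:
    """Set flags = (T2 > T2_crit) OR (Q > Q_crit) on a stats report.

    Thresholds come from ``reference`` (default: ``r`` itself).  When the
    screened set is also the threshold source, the empirical Q quantile can
    flag at most about (1 - q_quantile) of it, so heavy contamination partly
    masks itself; passing a report from a trusted population as ``reference``
    restores full power.  ``exclude_ids`` force-flags named samples,
    emulating manually curated exclusion lists.  Degenerate data with zero
    spread produce no flags.
    """
    ref = reference if reference is not None else r
    t2_crit = hotelling_t2_limit(ref.F, ref.n_train, t2_quantile)
    q_crit = float(np.quantile(ref.q, q_quantile)) if ref.q.size else 0.0
    if r.t2.max(initial=0.0) == 0.0 and r.q.max(initial=0.0) == 0.0:
        flags = np.zeros(r.t2.size, dtype=bool)  # zero spread: nothing to flag
    else:
        flags = (r.t2 > t2_crit) | (r.q > q_crit)
    if exclude_ids:
        excl = set(exclude_ids)
        flags = flags | np.array([s in excl for s in r.sample_ids])
    return OutlierReport(t2=r.t2, q=r.q, sample_ids=r.sample_ids, F=r.F,
                         n_train=r.n_train, t2_crit=t2_crit, q_crit=q_crit,
                         flags=flags)
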
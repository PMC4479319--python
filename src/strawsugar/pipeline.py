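"""End-to-end calibration workflow.

One call runs the full study design for a response and a preprocessing
variant: preprocess -> stratified calibration/validation split -> influence
screening (Hotelling T2 / Q residual) -> segmented cross-validation and
parsimonious factor choice -> Martens' uncertainty variable selection and
refit -> frozen-model evaluation on the untouched external-validation set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .outliers import flag_outliers, influence_stats
from .pls import (PLSModel, fit_pls1, martens_uncertainty, predict,
                  segmented_cv, select_factors)
from .preprocess import PIPELINES, PreprocessSpec, apply_pipeline
from .spectra import ResponseTable, SpectrumSet
from .validation import (ValidationReport, r_squared, rmse, rmse_sdl_ratio,
                         sdl_from_table, split_calibration)

__all__ = ["CalibrationSettings", "CalibrationRun", "run_calibration",
           "build_report"]


@dataclass
class CalibrationSettings:
    """Knobs of the calibration workflow with the study-design defaults."""

    n_segments: int = 10
    max_F: int = 15
    factor_tol: float = 0.02
    alpha: float = 0.05
    t2_quantile: float = 0.975
    q_quantile: float = 0.975
    split_frac: float = 2 / 3
    stratify_by: tuple[str, ...] = ("variety", "site")
    exclude_ids: tuple[str, ...] = ()
    martens: bool = True
    screen: bool = True


@dataclass
class CalibrationRun:
    """Everything produced by one calibration: model, report, diagnostics."""

    model: PLSModel
    report: ValidationReport
    selected_mask: np.ndarray
    outlier_ids: list[str]
    cal_ids: list[str]
    ev_ids: list[str]
    y_ev: np.ndarray = field(default_factory=lambda: np.empty(0))
    yhat_ev: np.ndarray = field(default_factory=lambda: np.empty(0))


def run_calibration(spectra: SpectrumSet, responses: ResponseTable,
                    response_name: str = "total",
                    preprocess: PreprocessSpec | str = "smooth_norm",
                    settings: CalibrationSettings | None = None,
                    seed: int | None = None) -> CalibrationRun:
    """Run the full calibration workflow for one response and one pipeline."""
    st = settings or CalibrationSettings()
    spec = PIPELINES[preprocess] if isinstance(preprocess, str) else preprocess
    pp = apply_pipeline(spectra, spec)

    (cal_s, cal_r), (ev_s, ev_r) = split_calibration(
        pp, responses, frac=st.split_frac, seed=seed,
        stratify_by=st.stratify_by or None)

    Xcal = cal_s.absorbance
    ycal = cal_r.response(response_name)

    outlier_ids: list[str] = []
    if st.screen:
        cv0 = segmented_cv(Xcal, ycal, n_segments=st.n_segments,
                           max_F=st.max_F, seed=seed)
        F0 = select_factors(cv0, st.factor_tol)
        m0 = fit_pls1(Xcal, ycal, F0, response_name=response_name)
        rep = influence_stats(m0, Xcal, cal_s.sample_ids)
        rep = flag_outliers(rep, st.t2_quantile, st.q_quantile,
                            exclude_ids=list(st.exclude_ids) or None)
        outlier_ids = rep.flagged_ids()
        if outlier_ids:
            keep = [s for s in cal_s.sample_ids if s not in set(outlier_ids)]
            cal_s, cal_r = cal_s.select(keep), cal_r.select(keep)
            Xcal = cal_s.absorbance
            ycal = cal_r.response(response_name)

    cv = segmented_cv(Xcal, ycal, n_segments=st.n_segments, max_F=st.max_F,
                      seed=seed)
    F = select_factors(cv, st.factor_tol)

    if st.martens:
        mask, model = martens_uncertainty(Xcal, ycal, F, cv, alpha=st.alpha,
                                          response_name=response_name)
        cv_final = segmented_cv(Xcal, ycal, segments=cv.segment_of,
                                max_F=model.F, selected=mask)
        F_final = model.F
    else:
        mask = np.ones(Xcal.shape[1], dtype=bool)
        model = fit_pls1(Xcal, ycal, F, response_name=response_name)
        cv_final, F_final = cv, F

    cv_pred = cv_final.predictions[:, F_final - 1]
    y_ev = ev_r.response(response_name)
    yhat_ev = predict(model, ev_s.absorbance)

    sdl_value = None
    if responses.replicates is not None:
        sdl_value = sdl_from_table(responses, response_name)

    report = ValidationReport(
        response_name=response_name,
        preprocessing=spec.label or "custom",
        F=F_final,
        r2_cv=r_squared(ycal, cv_pred),
        r2_ev=r_squared(y_ev, yhat_ev),
        rmse_cv=rmse(ycal, cv_pred),
        rmse_ev=rmse(y_ev, yhat_ev),
        sdl=sdl_value,
        n_cal=len(cal_s.sample_ids),
        n_ev=len(ev_s.sample_ids),
        n_outliers=len(outlier_ids),
        n_selected_vars=int(mask.sum()),
    )
    return CalibrationRun(model=model, report=report, selected_mask=mask,
                          outlier_ids=outlier_ids,
                          cal_ids=list(cal_s.sample_ids),
                          ev_ids=list(ev_s.sample_ids),
                          y_ev=y_ev, yhat_ev=yhat_ev)


def build_report(spectra: SpectrumSet, responses: ResponseTable,
                 response_names: tuple[str, ...] = ("total", "glucose", "xylose"),
                 preprocess_labels: tuple[str, ...] = ("smooth_norm", "sg1",
                                                       "sg2", "smooth_snv"),
                 settings: CalibrationSettings | None = None,
                 seed: int | None = None) -> list[ValidationReport]:
    """Evaluate every response under every preprocessing variant (shared split)."""
    out = []
    for label in preprocess_labels:
        for resp in response_names:
            run = run_calibration(spectra, responses, resp, label,
                                  settings=settings, seed=seed)
            out.append(run.report)
    return out
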
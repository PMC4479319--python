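"""Spectral preprocessing: Savitzky-Golay smoothing/derivatives, mean
normalisation and the standard normal variate (SNV) transform.

All operators are per-sample (row-local).  Savitzky-Golay edges use the
polynomial-extension mode (the window polynomial fitted at the boundary is
evaluated off-centre), so output length equals input length.  Derivatives are
taken with respect to the physical, *ascending* wavenumber axis and then
re-ordered back to the descending storage grid.

Four named pipelines cover the preprocessing variants commonly compared for
lignocellulose calibrations:

=============  ==================================================
label          steps
=============  ==================================================
smooth_norm    SG smoothing (7 pts, degree 0) then mean normalise
sg1            SG first derivative (7 pts, degree 2)
sg2            SG second derivative (7 pts, degree 2)
smooth_snv     SG smoothing (7 pts, degree 0) then SNV
=============  ==================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.signal import savgol_filter

from .spectra import SpectrumSet

__all__ = [
    "PreprocessSpec",
    "PIPELINES",
    "sg_smooth",
    "sg_derivative",
    "normalize_mean",
    "snv",
    "apply_pipeline",
]


def _check_sg(window: int, polyorder: int, deriv: int, n_points: int) -> None:
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if window > n_points:
        raise ValueError(f"window {window} exceeds {n_points} grid points")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if deriv > polyorder:
        raise ValueError("derivative order must be <= polyorder")


def sg_smooth(s: SpectrumSet, window: int = 7, polyorder: int = 0) -> SpectrumSet:
    """Savitzky-Golay smoothing; degree 0 is a centred moving average."""
    _check_sg(window, polyorder, 0, s.n_points)
    sm = savgol_filter(s.absorbance, window, polyorder, axis=1, mode="interp")
    return s.copy_with(sm, f"sg_smooth(window={window}, polyorder={polyorder})")


def sg_derivative(s: SpectrumSet, window: int = 7, polyorder: int = 2,
                  deriv_order: int = 1) -> SpectrumSet:
    """Savitzky-Golay derivative w.r.t. wavenumber (absorbance per cm^-1).

    Requires a uniformly spaced grid; the sign convention follows the
    ascending wavenumber axis.
    """
    if deriv_order not in (1, 2):
        raise ValueError("deriv_order must be 1 or 2")
    _check_sg(window, polyorder, deriv_order, s.n_points)
    steps = np.diff(s.grid)
    if not np.allclose(steps, steps[0], rtol=0, atol=1e-8 * abs(steps[0])):
        raise ValueError("non-uniform grid: regrid() onto a uniform grid first")
    delta = abs(steps[0])
    asc = s.absorbance[:, ::-1]  # differentiate on the ascending axis
    der = savgol_filter(asc, window, polyorder, deriv=deriv_order, delta=delta,
                        axis=1, mode="interp")
    return s.copy_with(der[:, ::-1],
                       f"sg_derivative(window={window}, polyorder={polyorder}, "
                       f"deriv_order={deriv_order})")


def normalize_mean(s: SpectrumSet) -> SpectrumSet:
    """Divide every spectrum by its own mean absorbance (per-spectrum mean -> 1)."""
    mu = s.absorbance.mean(axis=1, keepdims=True)
    if np.any(np.abs(mu) < 1e-300):
        bad = s.sample_ids[int(np.argmin(np.abs(mu)))]
        raise ValueError(f"zero-mean spectrum {bad!r} cannot be mean-normalised")
    return s.copy_with(s.absorbance / mu, "normalize_mean")


def snv(s: SpectrumSet) -> SpectrumSet:
    """Standard normal variate: per-spectrum centre and scale to unit sd (n-1)."""
    mu = s.absorbance.mean(axis=1, keepdims=True)
    sd = s.absorbance.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd <= 0):
        bad = s.sample_ids[int(np.argmin(sd))]
        raise ValueError(f"constant spectrum {bad!r} cannot be SNV-transformed")
    return s.copy_with((s.absorbance - mu) / sd, "snv")


@dataclass
class PreprocessSpec:
    """Ordered list of preprocessing steps.

    Each step is a ``(name, kwargs)`` pair with name in
    {sg_smooth, sg_derivative, normalize_mean, snv}.
    """

    steps: list[tuple[str, dict]] = dc_field(default_factory=list)
    label: str = ""

    _OPS = {
        "sg_smooth": sg_smooth,
        "sg_derivative": sg_derivative,
        "normalize_mean": normalize_mean,
        "snv": snv,
    }

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("preprocessing pipeline must have at least one step")
        for name, kwargs in self.steps:
            if name not in self._OPS:
                raise ValueError(f"unknown preprocessing step {name!r}")
            w = kwargs.get("window")
            if w is not None:
                p = kwargs.get("polyorder", 0 if name == "sg_smooth" else 2)
                _check_sg(w, p, kwargs.get("deriv_order", 0) if name == "sg_derivative" else 0,
                          n_points=max(w, 3))

    def to_dict(self) -> dict:
        return {"label": self.label,
                "steps": [{"name": n, **kw} for n, kw in self.steps]}

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessSpec":
        steps = [(s["name"], {k: v for k, v in s.items() if k != "name"})
                 for s in d["steps"]]
        return cls(steps=steps, label=d.get("label", ""))


def apply_pipeline(s: SpectrumSet, spec: PreprocessSpec) -> SpectrumSet:
    """Apply the steps in order; applied steps are recorded in provenance."""
    out = s
    for name, kwargs in spec.steps:
        out = PreprocessSpec._OPS[name](out, **kwargs)
    return out


PIPELINES: dict[str, PreprocessSpec] = {
    "smooth_norm": PreprocessSpec(
        steps=[("sg_smooth", {"window": 7, "polyorder": 0}), ("normalize_mean", {})],
        label="SG smoothing (7 pts) + mean normalisation"),
    "sg1": PreprocessSpec(
        steps=[("sg_derivative", {"window": 7, "polyorder": 2, "deriv_order": 1})],
        label="SG first derivative (deg 2, 7 pts)"),
    "sg2": PreprocessSpec(
        steps=[("sg_derivative", {"window": 7, "polyorder": 2, "deriv_order": 2})],
        label="SG second derivative (deg 2, 7 pts)"),
    "smooth_snv": PreprocessSpec(
        steps=[("sg_smooth", {"window": 7, "polyorder": 0}), ("snv", {})],
        label="SG smoothing (7 pts) + SNV"),
}
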
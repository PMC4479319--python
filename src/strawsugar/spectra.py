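"""Containers and I/O for mid-infrared spectral matrices and sugar-release tables.

Spectra live on a shared wavenumber grid stored strictly *descending*
(4000 -> 600 cm^-1), the conventional orientation of mid-IR plots.  All
downstream operators assume that convention; files with ascending headers
are re-ordered on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpectrumSet",
    "ResponseTable",
    "default_grid",
    "read_spectra",
    "write_spectra",
    "read_responses",
    "regrid",
]


def default_grid(start: float = 4000.0, stop: float = 600.0, step: float = 4.0) -> np.ndarray:
    """Canonical acquisition grid: 4000..600 cm^-1 inclusive at 4 cm^-1 (851 points)."""
    n = int(round((start - stop) / step)) + 1
    return start - step * np.arange(n)


@dataclass
class SpectrumSet:
    """Sample-indexed absorbance matrix on a shared descending wavenumber grid.

    Parameters
    ----------
    grid : array of wavenumbers in cm^-1, strictly monotone descending.
    absorbance : (n_samples, n_points) matrix of photoacoustic absorbance
        (dimensionless).
    sample_ids : unique sample identifiers.
    metadata : optional per-sample frame (site, variety, year, ...) indexed
        like ``sample_ids``.
    """

    grid: np.ndarray
    absorbance: np.ndarray
    sample_ids: list[str]
    metadata: pd.DataFrame | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.grid.ndim != 1 or self.grid.size < 2:
            raise ValueError("grid must be 1-D with at least 2 points")
        d = np.diff(self.grid)
        if not np.all(d < 0):
            raise ValueError("grid must be strictly monotone descending")
        if self.absorbance.shape != (len(self.sample_ids), self.grid.size):
            raise ValueError(
                f"absorbance shape {self.absorbance.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.grid.size} grid points"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            seen: set[str] = set()
            dup = next(s for s in self.sample_ids if s in seen or seen.add(s))
            raise ValueError(f"duplicate sample_id {dup!r}")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_points(self) -> int:
        return self.grid.size

    def copy_with(self, absorbance: np.ndarray, step: str | None = None) -> "SpectrumSet":
        """New set sharing grid/ids/metadata, with ``step`` appended to provenance."""
        prov = list(self.provenance) + ([step] if step else [])
        return SpectrumSet(self.grid.copy(), absorbance, list(self.sample_ids),
                           self.metadata, prov)

    def select(self, ids: list[str]) -> "SpectrumSet":
        """Subset (and reorder) by sample id."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        meta = self.metadata.loc[ids] if self.metadata is not None else None
        return SpectrumSet(self.grid.copy(), self.absorbance[idx], list(ids),
                           meta, list(self.provenance))


@dataclass
class ResponseTable:
    """Per-sample glucose, xylose and total sugar release in g g^-1 dry matter.

    ``values`` has columns glucose, xylose, total indexed by sample_id, with
    total = glucose + xylose by construction.  ``replicates``, when present,
    holds the replicate-level assay values (one row per sample x replicate,
    columns glucose/xylose/total) from which the laboratory standard
    deviation is estimated; every sample carries the same replicate count m.
    """

    values: pd.DataFrame
    replicates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        req = {"glucose", "xylose", "total"}
        if not req.issubset(self.values.columns):
            raise ValueError(f"response table must have columns {sorted(req)}")
        v = self.values
        if (v[["glucose", "xylose", "total"]].to_numpy() < 0).any():
            raise ValueError("negative sugar release")
        if (v[["glucose", "xylose", "total"]].to_numpy() > 1).any():
            raise ValueError("sugar release above 1 g per g dry matter")
        if not np.allclose(v["total"], v["glucose"] + v["xylose"], atol=1e-9):
            raise ValueError("total differs from glucose + xylose")
        if self.replicates is not None:
            counts = self.replicates.groupby(level=0).size()
            if counts.nunique() != 1 or counts.iloc[0] < 2:
                raise ValueError("replicate table must have a constant m >= 2")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.index]

    @property
    def m_replicates(self) -> int | None:
        if self.replicates is None:
            return None
        return int(self.replicates.groupby(level=0).size().iloc[0])

    def response(self, name: str) -> np.ndarray:
        if name not in ("glucose", "xylose", "total"):
            raise KeyError(f"unknown response {name!r}")
        return self.values[name].to_numpy(dtype=float)

    def select(self, ids: list[str]) -> "ResponseTable":
        reps = self.replicates.loc[self.replicates.index.isin(ids)] if self.replicates is not None else None
        return ResponseTable(self.values.loc[ids].copy(), reps)


# ---------------------------------------------------------------------------
# I/O — wide CSV dialect: header "sample_id,<wn1>,<wn2>,...", one row/sample.
# ---------------------------------------------------------------------------

def read_spectra(path, dialect: str = "wide_csv") -> SpectrumSet:
    """Read a wide-format spectral matrix.

    The first header cell is ``sample_id``; the remaining header cells are
    wavenumbers.  An ascending header is accepted and re-ordered to the
    descending storage convention (columns reversed with it).
    """
    if dialect != "wide_csv":
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, dtype={0: str})
    id_col = df.columns[0]
    ids = df[id_col].tolist()
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(s for s in ids if s in seen or seen.add(s))
        raise ValueError(f"duplicate sample_id {dup!r} in {path}")
    try:
        grid = np.array([float(c) for c in df.columns[1:]])
    except ValueError as e:
        raise ValueError(f"non-numeric wavenumber in header of {path}: {e}") from e
    mat = df.iloc[:, 1:]
    num = mat.apply(pd.to_numeric, errors="coerce")
    bad = num.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric absorbance at sample {ids[i]!r}, wavenumber {df.columns[1 + j]}"
        )
    X = num.to_numpy(dtype=float)
    d = np.diff(grid)
    if np.all(d > 0):  # ascending header -> flip to descending
        grid = grid[::-1]
        X = X[:, ::-1]
    elif not np.all(d < 0):
        raise ValueError(f"wavenumber header of {path} is not monotone")
    return SpectrumSet(grid, X, ids)


def write_spectra(s: SpectrumSet, path) -> None:
    """Write the wide CSV dialect at full float precision (17 significant digits)."""
    df = pd.DataFrame(s.absorbance, columns=[repr(float(w)) for w in s.grid])
    df.insert(0, "sample_id", s.sample_ids)
    df.to_csv(path, index=False, float_format="%.17g")


def read_responses(path) -> ResponseTable:
    """Read a response CSV: ``sample_id,glucose,xylose[,total][,replicate]``.

    With a ``replicate`` column the file is replicate-level; per-sample values
    are the replicate means and the raw table is kept for SDL estimation.
    A ``total`` column inconsistent with glucose + xylose (beyond 1e-6) is
    recomputed with a warning; a missing one is filled in.
    """
    import warnings

    df = pd.read_csv(path, dtype={"sample_id": str})
    for col in ("sample_id", "glucose", "xylose"):
        if col not in df.columns:
            raise ValueError(f"response file missing column {col!r}")
    if (df[["glucose", "xylose"]].to_numpy() < 0).any():
        raise ValueError("negative sugar release in response file")
    if "total" in df.columns:
        if not np.allclose(df["total"], df["glucose"] + df["xylose"], atol=1e-6):
            warnings.warn("total column inconsistent with glucose + xylose; recomputed",
                          stacklevel=2)
        df["total"] = df["glucose"] + df["xylose"]
    else:
        df["total"] = df["glucose"] + df["xylose"]

    if "replicate" in df.columns:
        reps = df.set_index("sample_id")[["glucose", "xylose", "total"]]
        means = reps.groupby(level=0, sort=False).mean()
        return ResponseTable(means, replicates=reps)
    return ResponseTable(df.set_index("sample_id")[["glucose", "xylose", "total"]])


def write_responses(r: ResponseTable, path, replicate_level: bool = False) -> None:
    if replicate_level:
        if r.replicates is None:
            raise ValueError("no replicate table to write")
        df = r.replicates.copy()
        df.insert(0, "replicate", df.groupby(level=0).cumcount() + 1)
        df.reset_index(names="sample_id").to_csv(path, index=False, float_format="%.17g")
    else:
        r.values.reset_index(names="sample_id").to_csv(path, index=False,
                                                       float_format="%.17g")


def regrid(s: SpectrumSet, target_grid: np.ndarray) -> SpectrumSet:
    """Linear interpolation of every spectrum onto ``target_grid`` (descending).

    Extrapolation is refused: the target must lie within the source range.
    """
    tg = np.asarray(target_grid, dtype=float)
    if np.all(np.diff(tg) > 0):
        tg = tg[::-1]
    if tg.min() < s.grid.min() - 1e-9 or tg.max() > s.grid.max() + 1e-9:
        raise ValueError("target grid extends beyond the source grid (extrapolation)")
    asc = s.grid[::-1]
    out = np.empty((s.n_samples, tg.size))
    for i in range(s.n_samples):
        out[i] = np.interp(tg[::-1], asc, s.absorbance[i, ::-1])[::-1]
    return SpectrumSet(tg, out, list(s.sample_ids), s.metadata,
                       list(s.provenance) + ["regrid"])
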
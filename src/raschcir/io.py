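"""CSV interchange for response matrices and estimation results.

Fixed dialect: comma separator, UTF-8, decimal point, a header row of item
names, and a first column of person/unit identifiers.  Empty cells are
missing responses.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .core import FitResult, RescaledMatrix, ResidualSet
from .fitstats import FitStatistics
from .matrix import ResponseMatrix

__all__ = [
    "read_response_csv",
    "write_response_csv",
    "write_fit_csv",
    "load_fit_dir",
]


def _resolve_bounds(bounds, item_ids):
    l = len(item_ids)
    if bounds is None:
        return None
    if isinstance(bounds, dict):
        missing = [i for i in item_ids if i not in bounds]
        if missing:
            raise ValueError(f"bounds missing for items: {missing}")
        pairs = [bounds[i] for i in item_ids]
    elif isinstance(bounds, tuple) and len(bounds) == 2 and np.isscalar(bounds[0]):
        pairs = [bounds] * l
    else:
        pairs = list(bounds)
        if len(pairs) == 1:
            pairs = pairs * l
        if len(pairs) != l:
            raise ValueError(f"expected {l} bound pairs, got {len(pairs)}")
    lo = np.array([float(p[0]) for p in pairs])
    hi = np.array([float(p[1]) for p in pairs])
    return lo, hi


def read_response_csv(path, bounds=None) -> ResponseMatrix:
    """Read a persons x items response matrix.

    ``bounds`` may be a single ``(min, max)`` pair applied to every item, a
    sequence of per-item pairs in column order, or a mapping from item name
    to pair.  When absent, each item's observed minimum and maximum are used
    and a warning is emitted, because the rescaling is meant to use the
    instrument's known bounds, not the sample range.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""],
                      skipinitialspace=True)
    if raw.shape[1] < 3:
        raise ValueError("expected an identifier column plus at least 2 items")
    person_ids = raw.iloc[:, 0].tolist()
    if len(set(person_ids)) != len(person_ids):
        dup = sorted({p for p in person_ids if person_ids.count(p) > 1})
        raise ValueError(f"duplicate person identifiers: {dup}")
    item_ids = list(raw.columns[1:])
    values = np.full((len(person_ids), len(item_ids)), np.nan)
    for j, col in enumerate(item_ids):
        series = raw[col]
        for i, cell in enumerate(series):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                continue
            try:
                # float() is correctly rounded, so a written value
                # survives the round trip bit-exactly
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric value {cell!r} at row "
                    f"{person_ids[i]!r}, column {col!r}"
                ) from None

    resolved = _resolve_bounds(bounds, item_ids)
    if resolved is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            lo = np.nanmin(values, axis=0)
            hi = np.nanmax(values, axis=0)
        flat = np.nonzero(~(lo < hi))[0]
        if flat.size:
            raise ValueError(
                "cannot infer bounds for constant or empty items: "
                f"{[item_ids[j] for j in flat]}"
            )
        warnings.warn(
            "item bounds not supplied; defaulting to the observed per-item "
            "minimum/maximum (prefer the instrument's known bounds)",
            UserWarning,
            stacklevel=2,
        )
    else:
        lo, hi = resolved
    return ResponseMatrix(person_ids=person_ids, item_ids=item_ids,
                          values=values, item_min=lo, item_max=hi)


def write_response_csv(matrix: ResponseMatrix, path) -> Path:
    """Write a matrix back out; non-missing values survive a round trip exactly."""
    path = Path(path)
    df = pd.DataFrame(matrix.values, columns=matrix.item_ids)
    df.insert(0, "unit", matrix.person_ids)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def _flags(extreme, misfit):
    out = []
    for e, m in zip(extreme, misfit):
        tags = [t for t, on in (("extreme", e), ("misfit", m)) if on]
        out.append("+".join(tags))
    return out


def write_fit_csv(result: FitResult, stats: FitStatistics, outdir) -> Path:
    """Write persons.csv, items.csv, cells.csv and meta.json under ``outdir``.

    Deterministic layout: fixed column order, 6-decimal rounding.  The cells
    table holds one row per observed cell with the rescaled response,
    expectation, residual, variance and standardized residual, which is
    enough to rebuild every diagnostic display.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    persons = pd.DataFrame({
        "person": result.person_ids,
        "measure": result.theta,
        "se": result.theta_se,
        "infit": stats.person_infit,
        "outfit": stats.person_outfit,
        "flag": _flags(result.extreme_person_flags, stats.person_misfit_flags),
    })
    items = pd.DataFrame({
        "item": result.item_ids,
        "difficulty": result.delta,
        "se": result.delta_se,
        "infit": stats.item_infit,
        "outfit": stats.item_outfit,
        "flag": _flags(result.extreme_item_flags, stats.item_misfit_flags),
    })
    obs = result.observed_mask
    ii, jj = np.nonzero(obs)
    cells = pd.DataFrame({
        "person": [result.person_ids[i] for i in ii],
        "item": [result.item_ids[j] for j in jj],
        "x": result.rescaled.values[ii, jj],
        "expected": result.expected[ii, jj],
        "residual": result.residuals.R[ii, jj],
        "variance": result.residuals.Var[ii, jj],
        "z": result.residuals.Z[ii, jj],
    })
    for name, df in (("persons", persons), ("items", items), ("cells", cells)):
        df.to_csv(outdir / f"{name}.csv", index=False, float_format="%.6f")
    meta = {
        "n_iter": int(result.n_iter),
        "converged": bool(result.converged),
        "r_squared": None if np.isnan(stats.r_squared) else float(stats.r_squared),
        "normalized_mnsq": bool(stats.normalized),
        "sum_abs_residual_trace": [float(v) for v in result.sum_abs_residual_trace],
    }
    (outdir / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return outdir


def load_fit_dir(fitdir) -> FitResult:
    """Rebuild a :class:`FitResult` from a directory written by
    :func:`write_fit_csv` (values carry that file's 6-decimal rounding)."""
    fitdir = Path(fitdir)
    persons = pd.read_csv(fitdir / "persons.csv", dtype={"person": str},
                          keep_default_na=False, na_values=[""])
    items = pd.read_csv(fitdir / "items.csv", dtype={"item": str},
                        keep_default_na=False, na_values=[""])
    cells = pd.read_csv(fitdir / "cells.csv",
                        dtype={"person": str, "item": str})
    meta = json.loads((fitdir / "meta.json").read_text())
    person_ids = persons["person"].tolist()
    item_ids = items["item"].tolist()
    pidx = {p: i for i, p in enumerate(person_ids)}
    iidx = {i: j for j, i in enumerate(item_ids)}
    shape = (len(person_ids), len(item_ids))
    grids = {k: np.full(shape, np.nan)
             for k in ("x", "expected", "residual", "variance", "z")}
    rows = [pidx[p] for p in cells["person"]]
    cols = [iidx[i] for i in cells["item"]]
    for key, grid in grids.items():
        grid[rows, cols] = cells[key].to_numpy(dtype=float)
    mask = np.isnan(grids["x"])
    flag_p = persons["flag"].astype(str)
    flag_i = items["flag"].astype(str)
    return FitResult(
        person_ids=person_ids,
        item_ids=item_ids,
        theta=persons["measure"].to_numpy(dtype=float),
        delta=items["difficulty"].to_numpy(dtype=float),
        theta_se=persons["se"].to_numpy(dtype=float),
        delta_se=items["se"].to_numpy(dtype=float),
        expected=np.where(mask, 0.5, grids["expected"]),
        residuals=ResidualSet(R=grids["residual"], Var=grids["variance"],
                              Z=grids["z"]),
        n_iter=int(meta["n_iter"]),
        converged=bool(meta["converged"]),
        sum_abs_residual_trace=np.asarray(meta["sum_abs_residual_trace"]),
        extreme_person_flags=flag_p.str.contains("extreme").to_numpy(),
        extreme_item_flags=flag_i.str.contains("extreme").to_numpy(),
        rescaled=RescaledMatrix(values=grids["x"], missing_mask=mask),
        config=RunConfig(),
    )
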
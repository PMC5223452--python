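"""Rasch fit statistics: standardized residuals, INFIT/OUTFIT mean squares,
misfit flags, model R-squared, and the item-difficulty t-test.

OUTFIT is the unweighted mean of squared standardized residuals along a row
(person) or column (item): sensitive to unexpected responses far from a
parameter's location.  INFIT weights by the cell variance, ``sum R**2 / sum
Var``: sensitive to misfit near the location.  Both have expectation 1 under
the model.  Conventional screening rules: item INFIT below 1.5 supports a
single underlying construct; person OUTFIT below 2.0 indicates responses
free of aberrant or careless patterns; a single cell with |Z| below 2.0 is a
non-significant deviation from the model expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import FitResult, ResidualSet

__all__ = [
    "FitStatistics",
    "standardized_residuals",
    "outfit_mnsq",
    "infit_mnsq",
    "misfit_flags",
    "normalize_mnsq",
    "model_r_squared",
    "model_f_test",
    "item_difficulty_ttest",
    "compute_fit_statistics",
]

ITEM_INFIT_THRESHOLD = 1.5
PERSON_OUTFIT_THRESHOLD = 2.0
CELL_Z_THRESHOLD = 2.0


@dataclass
class FitStatistics:
    """Per-person and per-item mean-square fit statistics with misfit flags.

    Flags use closed thresholds: item INFIT >= 1.5, person OUTFIT >= 2.0,
    |Z| >= 2.0.  ``normalized`` records whether the mean squares were rescaled
    to mean 1.0 per set.
    """

    person_outfit: np.ndarray
    person_infit: np.ndarray
    item_outfit: np.ndarray
    item_infit: np.ndarray
    person_misfit_flags: np.ndarray
    item_misfit_flags: np.ndarray
    cell_z_flags: np.ndarray
    r_squared: float
    normalized: bool = False


def standardized_residuals(res: ResidualSet) -> np.ndarray:
    """Signed standardized residuals ``Z = R / sqrt(Var)``.

    The sign carries the direction of the misfit (a response above or below
    the model expectation); ``Z**2`` is the squared standardized residual
    entering the mean squares.
    """
    return res.R / np.sqrt(res.Var)


def _axis_of(axis) -> int:
    if axis in ("person", 1):
        return 1
    if axis in ("item", 0):
        return 0
    raise ValueError("axis must be 'person' or 'item'")


def outfit_mnsq(z: np.ndarray, axis="person") -> np.ndarray:
    """Unweighted mean square: mean of Z**2 over a row or column.

    Missing cells (NaN) are excluded and the denominator is the observed
    count, not the nominal row/column length.
    """
    ax = _axis_of(axis)
    with np.errstate(invalid="ignore"):
        return np.nanmean(np.square(z), axis=ax)


def infit_mnsq(res: ResidualSet, axis="person") -> np.ndarray:
    """Information-weighted mean square: ``sum R**2 / sum Var`` per row/column."""
    ax = _axis_of(axis)
    return np.nansum(np.square(res.R), axis=ax) / np.nansum(res.Var, axis=ax)


def misfit_flags(person_outfit, item_infit, z):
    """Closed-threshold misfit flags for persons, items and single cells."""
    person = np.asarray(person_outfit) >= PERSON_OUTFIT_THRESHOLD
    item = np.asarray(item_infit) >= ITEM_INFIT_THRESHOLD
    with np.errstate(invalid="ignore"):
        cell = np.abs(np.asarray(z)) >= CELL_Z_THRESHOLD
    cell = np.where(np.isnan(z), False, cell)
    return person, item, cell


def normalize_mnsq(values: np.ndarray) -> np.ndarray:
    """Rescale a set of mean squares so its mean is exactly 1.0.

    Continuous responses produce much smaller cell residuals than the
    quasi-binomial variance anticipates, so raw mean squares sit far below 1;
    dividing by the set mean restores the conventional interpretive scale.
    """
    values = np.asarray(values, dtype=float)
    m = values.mean()
    if not m > 0:
        raise ValueError("cannot normalize mean squares with non-positive mean")
    return values / m


def model_r_squared(expected, observed, center: str = "grand") -> float:
    """Variance-explained ratio ``sum (E - Xbar)**2 / sum (X - Xbar)**2``.

    ``Xbar`` is the grand mean of the observed unit-interval responses
    (``center='item'`` uses per-item means instead).  Missing cells are
    excluded.  Returns NaN when the observed responses have zero variance.
    """
    e = np.asarray(expected, dtype=float)
    x = np.asarray(observed, dtype=float)
    obs = ~np.isnan(x)
    if obs.sum() < 2:
        raise ValueError("need at least 2 observed cells")
    if center == "grand":
        xbar = np.nanmean(x)
    elif center == "item":
        xbar = np.nanmean(x, axis=0, keepdims=True)
    else:
        raise ValueError("center must be 'grand' or 'item'")
    denom = np.nansum(np.square(np.where(obs, x - xbar, np.nan)))
    if denom == 0:
        return float("nan")
    numer = np.nansum(np.square(np.where(obs, e - xbar, np.nan)))
    return float(numer / denom)


def model_f_test(r_squared: float, n_cells: int):
    """F statistic for the expected-vs-observed regression, df (1, n_cells - 2)."""
    if n_cells < 3:
        raise ValueError("need at least 3 cells for an F test")
    if not 0 <= r_squared < 1:
        raise ValueError("r_squared must lie in [0, 1) for the F test")
    df2 = n_cells - 2
    f = r_squared / (1.0 - r_squared) * df2
    p = float(sps.f.sf(f, 1, df2))
    return float(f), p


def item_difficulty_ttest(delta_a: float, delta_b: float,
                          sumvar_a: float, sumvar_b: float):
    """Two-item difficulty comparison on the logit scale.

    ``t = (delta_a - delta_b) / sqrt(1/sum Var_a + 1/sum Var_b)`` where each
    ``sum Var`` is the item's total cell variance (the reciprocal of its
    squared standard error); the p-value is the two-sided standard-normal
    tail probability.
    """
    if sumvar_a <= 0 or sumvar_b <= 0:
        raise ValueError("variance sums must be strictly positive")
    t = (delta_a - delta_b) / np.sqrt(1.0 / sumvar_a + 1.0 / sumvar_b)
    p = 2.0 * sps.norm.sf(abs(t))
    return float(t), float(p)


def compute_fit_statistics(result: FitResult, normalize: bool | None = None,
                           r2_center: str = "grand") -> FitStatistics:
    """Assemble the full fit-statistic set for a converged estimation.

    ``normalize=None`` defers to ``result.config.normalize_mnsq``.
    """
    if normalize is None:
        normalize = result.config.normalize_mnsq
    res = result.residuals
    z = standardized_residuals(res)
    person_outfit = outfit_mnsq(z, "person")
    item_outfit = outfit_mnsq(z, "item")
    person_infit = infit_mnsq(res, "person")
    item_infit = infit_mnsq(res, "item")
    if normalize:
        person_outfit = normalize_mnsq(person_outfit)
        person_infit = normalize_mnsq(person_infit)
        item_outfit = normalize_mnsq(item_outfit)
        item_infit = normalize_mnsq(item_infit)
    pflag, iflag, cflag = misfit_flags(person_outfit, item_infit, z)
    r2 = model_r_squared(result.expected, result.rescaled.values,
                         center=r2_center)
    return FitStatistics(
        person_outfit=person_outfit,
        person_infit=person_infit,
        item_outfit=item_outfit,
        item_infit=item_infit,
        person_misfit_flags=pflag,
        item_misfit_flags=iflag,
        cell_z_flags=cflag,
        r_squared=r2,
        normalized=bool(normalize),
    )
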
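"""Joint estimation of the one-parameter Rasch model for continuous responses.

Responses are first rescaled affinely to the unit interval.  Each rescaled
cell ``x_nj`` is then treated as a fractional success whose model expectation
is the Rasch probability ``p_nj = exp(theta_n - delta_j) / (1 + exp(theta_n -
delta_j))`` with working variance ``p_nj (1 - p_nj)`` (a quasi-binomial
reading of a bounded continuous response).  Person measures ``theta`` and item
difficulties ``delta`` are estimated jointly by alternating damped
Newton-Raphson updates:

* persons:  ``theta <- theta + sum_j R_nj / sum_j Var_nj``
* items:    ``delta <- delta - sum_n R_nj / sum_n Var_nj``

with ``R_nj = x_nj - p_nj``, followed by re-centering the item difficulties
to mean zero (the identification constraint of the logit scale).  On binary
{0,1} data this is exactly the classical dichotomous joint-maximum-likelihood
step.  Extreme response strings (all cells at a scale bound) have divergent
maximum-likelihood estimates; they are flagged, clamped and excluded from the
centering constraint.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .config import RunConfig
from .matrix import ResponseMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RescaledMatrix",
    "ResidualSet",
    "FitResult",
    "rescale",
    "rasch_probability",
    "residual_and_variance",
    "newton_step_persons",
    "newton_step_items",
    "center_items",
    "fit",
]


@dataclass
class RescaledMatrix:
    """Unit-interval responses with the missing mask carried through."""

    values: np.ndarray
    missing_mask: np.ndarray

    def observed_mask(self) -> np.ndarray:
        return ~self.missing_mask


@dataclass
class ResidualSet:
    """Per-cell residuals, working variances and standardized residuals.

    ``Z = R / sqrt(Var)`` keeps the sign of the residual so diagnostics can
    show the direction of an unexpected response; ``Z**2 = R**2 / Var``
    always.  Missing cells hold NaN.
    """

    R: np.ndarray
    Var: np.ndarray
    Z: np.ndarray


@dataclass
class FitResult:
    """Converged person measures and item difficulties with diagnostics."""

    person_ids: list
    item_ids: list
    theta: np.ndarray
    delta: np.ndarray
    theta_se: np.ndarray
    delta_se: np.ndarray
    expected: np.ndarray
    residuals: ResidualSet
    n_iter: int
    converged: bool
    sum_abs_residual_trace: np.ndarray
    extreme_person_flags: np.ndarray
    extreme_item_flags: np.ndarray
    rescaled: RescaledMatrix
    config: RunConfig = field(default_factory=RunConfig)

    @property
    def observed_mask(self) -> np.ndarray:
        return ~self.rescaled.missing_mask

    def person_index(self, person_id) -> int:
        try:
            return self.person_ids.index(person_id)
        except ValueError:
            raise KeyError(f"unknown person identifier {person_id!r}") from None


def rescale(raw: ResponseMatrix) -> RescaledMatrix:
    """Affinely map each item's responses onto [0, 1].

    ``x = (observed - item_min) / (item_max - item_min)`` per item; missing
    cells stay missing.  Values outside the declared bounds were already
    rejected by :class:`~raschcir.matrix.ResponseMatrix`.
    """
    span = raw.item_max - raw.item_min
    x = (raw.values - raw.item_min[None, :]) / span[None, :]
    obs = raw.observed_mask()
    if np.any(obs & ((x < 0) | (x > 1))):
        i, j = np.argwhere(obs & ((x < 0) | (x > 1)))[0]
        raise ValueError(
            f"cell ({raw.person_ids[i]!r}, {raw.item_ids[j]!r}) rescales "
            f"outside [0, 1]"
        )
    return RescaledMatrix(values=np.where(obs, x, np.nan),
                          missing_mask=raw.missing_mask.copy())


def rasch_probability(theta, delta):
    """Rasch expectation ``exp(theta - delta) / (1 + exp(theta - delta))``.

    Accepts scalars or broadcastable arrays of logits.  Computed through the
    numerically stable logistic, so it is reliable far beyond |theta - delta|
    = 30.  At ``theta == delta`` the value is exactly 0.5.
    """
    theta = np.asarray(theta, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(delta))):
        raise ValueError("rasch_probability requires finite logit inputs")
    p = expit(theta - delta)
    if p.ndim == 0:
        return float(p)
    return p


def residual_and_variance(x, p, variance_floor: float = 1e-6):
    """Residual ``R = x - p`` and working variance ``Var = max(p(1-p), floor)``."""
    x = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("model probabilities must lie strictly in (0, 1)")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("responses must lie in [0, 1] after rescaling")
    r = x - p
    var = np.maximum(p * (1.0 - p), variance_floor)
    if r.ndim == 0:
        return float(r), float(var)
    return r, var


def _masked_rv(x, theta, delta, mask, variance_floor):
    """Residual and variance grids with zeros at missing cells."""
    p = expit(theta[:, None] - delta[None, :])
    r = np.where(mask, x - p, 0.0)
    v = np.where(mask, np.maximum(p * (1.0 - p), variance_floor), 0.0)
    return r, v


def newton_step_persons(theta, delta, x, mask=None, *, max_step=1.0,
                        theta_clamp=10.0, variance_floor=1e-6):
    """One damped Newton update of every person measure.

    ``theta_new = theta + (sum_j R_nj) / (sum_j Var_nj)`` over the person's
    observed cells, with the raw step capped at ``max_step`` logits and the
    result clamped to ``[-theta_clamp, theta_clamp]``.
    """
    theta = np.asarray(theta, dtype=float)
    delta = np.asarray(delta, dtype=float)
    x = np.asarray(x, dtype=float)
    if mask is None:
        mask = ~np.isnan(x)
    if np.any(mask.sum(axis=1) == 0):
        raise ValueError("every person needs at least one observed response")
    r, v = _masked_rv(x, theta, delta, mask, variance_floor)
    step = r.sum(axis=1) / v.sum(axis=1)
    step = np.clip(step, -max_step, max_step)
    return np.clip(theta + step, -theta_clamp, theta_clamp)


def newton_step_items(theta, delta, x, mask=None, *, max_step=1.0,
                      theta_clamp=10.0, variance_floor=1e-6,
                      free_items=None, center=True):
    """One damped Newton update of every item difficulty, then re-centering.

    ``delta_new = delta - (sum_n R_nj) / (sum_n Var_nj)`` over the item's
    observed cells, capped and clamped as for persons; difficulties of
    non-extreme items are then shifted to mean zero.
    """
    theta = np.asarray(theta, dtype=float)
    delta = np.asarray(delta, dtype=float)
    x = np.asarray(x, dtype=float)
    if mask is None:
        mask = ~np.isnan(x)
    if np.any(mask.sum(axis=0) == 0):
        raise ValueError("every item needs at least one observed response")
    r, v = _masked_rv(x, theta, delta, mask, variance_floor)
    step = -r.sum(axis=0) / v.sum(axis=0)
    step = np.clip(step, -max_step, max_step)
    new = np.clip(delta + step, -theta_clamp, theta_clamp)
    if center:
        new = center_items(new, free_items)
    return new


def center_items(delta, free_items=None):
    """Shift item difficulties so the mean over non-extreme items is zero."""
    delta = np.array(delta, dtype=float)
    if free_items is None:
        free_items = np.ones(delta.shape, dtype=bool)
    free_items = np.asarray(free_items, dtype=bool)
    if free_items.any():
        delta[free_items] -= delta[free_items].mean()
    return delta


def _extreme_rows(x, mask, axis):
    """Rows (axis=1) or columns (axis=0) whose observed cells all sit at 0 or 1."""
    at_hi = np.where(mask, x == 1.0, True).all(axis=axis)
    at_lo = np.where(mask, x == 0.0, True).all(axis=axis)
    return at_hi | at_lo


def fit(data: ResponseMatrix, config: RunConfig | None = None) -> FitResult:
    """Jointly estimate person measures and item difficulties.

    All measures start at 0 logits (every person provisionally equal, every
    item provisionally equally difficult).  Each outer iteration performs a
    person half-step, refreshes the expectations, performs an item half-step
    with re-centering, and refreshes again.  Iteration stops when the total
    absolute residual ``sum |O - E|`` drops below ``convergence_tol``, when
    the largest parameter change drops below ``change_tol``, or at
    ``max_iter`` (the last yields ``converged=False`` and a warning).

    Standard errors are the usual Rasch asymptotics ``1 / sqrt(sum Var)``
    over a person's (item's) observed cells.
    """
    cfg = config or RunConfig()
    resc = rescale(data)
    x = resc.values
    mask = resc.observed_mask()
    if np.any(mask.sum(axis=1) == 0):
        bad = [data.person_ids[i] for i in np.nonzero(mask.sum(axis=1) == 0)[0]]
        raise ValueError(f"persons with no observed responses: {bad}")
    if np.any(mask.sum(axis=0) == 0):
        bad = [data.item_ids[j] for j in np.nonzero(mask.sum(axis=0) == 0)[0]]
        raise ValueError(f"items with no observed responses: {bad}")

    n, l = x.shape
    extreme_p = _extreme_rows(x, mask, axis=1)
    extreme_i = _extreme_rows(x, mask, axis=0)
    free_items = ~extreme_i

    theta = np.zeros(n)
    delta = np.zeros(l)
    trace = []
    converged = False
    n_iter = 0
    step_kw = dict(max_step=cfg.max_step, theta_clamp=cfg.theta_clamp,
                   variance_floor=cfg.variance_floor)

    for n_iter in range(1, cfg.max_iter + 1):
        theta_new = newton_step_persons(theta, delta, x, mask, **step_kw)
        delta_new = newton_step_items(theta_new, delta, x, mask,
                                      free_items=free_items, **step_kw)
        p = expit(theta_new[:, None] - delta_new[None, :])
        total = float(np.abs(np.where(mask, x - p, 0.0)).sum())
        trace.append(total)
        change = max(np.max(np.abs(theta_new - theta)),
                     np.max(np.abs(delta_new - delta)))
        theta, delta = theta_new, delta_new
        logger.debug("iteration %d: sum|O-E| = %.6f, max change = %.2e",
                     n_iter, total, change)
        if total < cfg.convergence_tol or change < cfg.change_tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"estimation did not converge in {cfg.max_iter} iterations "
            f"(last total |O-E| = {trace[-1]:.4f})",
            RuntimeWarning,
            stacklevel=2,
        )

    p = expit(theta[:, None] - delta[None, :])
    var = np.maximum(p * (1.0 - p), cfg.variance_floor)
    r = x - p
    z = r / np.sqrt(var)
    nanfill = np.where(mask, 1.0, np.nan)
    residuals = ResidualSet(R=r * nanfill, Var=var * nanfill, Z=z * nanfill)
    var0 = np.where(mask, var, 0.0)
    theta_se = 1.0 / np.sqrt(var0.sum(axis=1))
    delta_se = 1.0 / np.sqrt(var0.sum(axis=0))

    return FitResult(
        person_ids=list(data.person_ids),
        item_ids=list(data.item_ids),
        theta=theta,
        delta=delta,
        theta_se=theta_se,
        delta_se=delta_se,
        expected=p,
        residuals=residuals,
        n_iter=n_iter,
        converged=converged,
        sum_abs_residual_trace=np.asarray(trace),
        extreme_person_flags=extreme_p,
        extreme_item_flags=extreme_i,
        rescaled=resc,
        config=cfg,
    )
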
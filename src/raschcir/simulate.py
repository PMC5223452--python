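"""Synthetic response matrices under the continuous-response Rasch model,
simulated adaptive-testing respondents, and a derivative-free estimation
oracle used as an independent cross-check of the Newton-Raphson fit.

The generator draws person measures from a normal distribution, places item
difficulties explicitly or on an equally spaced, mean-centered grid, computes
the Rasch expectation ``p_nj`` per cell, and emits responses in one of three
noise modes:

* ``exact``  — the cell equals its expectation (noiseless identifiability);
* ``beta``   — ``x ~ Beta(p * nu, (1 - p) * nu)``: mean exactly ``p``,
  variance ``p (1 - p) / (nu + 1)``, support strictly inside (0, 1).  The
  precision ``nu`` controls how tightly bounded continuous measurements
  scatter around the model curve;
* ``binary`` — ``x ~ Bernoulli(p)``: classical dichotomous Rasch data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .matrix import ResponseMatrix

__all__ = [
    "SimulationSpec",
    "simulate_matrix",
    "oracle_binary_jmle",
    "Respondent",
    "simulate_respondent",
    "strip_extremes",
]


@dataclass
class SimulationSpec:
    """Conditions for one simulated persons x items study."""

    n_persons: int
    n_items: int
    theta_mean: float = 0.0
    theta_sd: float = 1.0
    delta_values: np.ndarray | None = None  # default: equally spaced in [-1, 1]
    noise_mode: str = "beta"
    beta_precision: float = 12.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_persons < 2 or self.n_items < 2:
            raise ValueError("need at least 2 persons and 2 items")
        if self.noise_mode not in ("exact", "beta", "binary"):
            raise ValueError("noise_mode must be exact, beta or binary")
        if self.noise_mode == "beta" and not self.beta_precision > 0:
            raise ValueError("beta_precision must be strictly positive")
        if self.theta_sd < 0:
            raise ValueError("theta_sd must be non-negative")
        if self.delta_values is None:
            self.delta_values = np.linspace(-1.0, 1.0, self.n_items)
        self.delta_values = np.asarray(self.delta_values, dtype=float)
        if self.delta_values.shape != (self.n_items,):
            raise ValueError("delta_values must have length n_items")
        self.delta_values = self.delta_values - self.delta_values.mean()


def simulate_matrix(spec: SimulationSpec):
    """Draw one response matrix; returns ``(matrix, truth)``.

    ``truth`` maps ``"theta"`` and ``"delta"`` to the generating parameters
    so recovery can be scored.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    theta = rng.normal(spec.theta_mean, spec.theta_sd, spec.n_persons)
    delta = spec.delta_values
    p = expit(theta[:, None] - delta[None, :])
    if spec.noise_mode == "exact":
        x = p.copy()
    elif spec.noise_mode == "beta":
        nu = spec.beta_precision
        x = rng.beta(p * nu, (1.0 - p) * nu)
    else:
        x = rng.binomial(1, p).astype(float)
    matrix = ResponseMatrix(
        person_ids=[f"P{i + 1}" for i in range(spec.n_persons)],
        item_ids=[f"I{j + 1}" for j in range(spec.n_items)],
        values=x,
        item_min=np.zeros(spec.n_items),
        item_max=np.ones(spec.n_items),
    )
    return matrix, {"theta": theta, "delta": delta.copy()}


def strip_extremes(matrix: ResponseMatrix) -> ResponseMatrix:
    """Drop extreme rows/columns (all observed cells at a bound) until none remain.

    Extreme response strings have divergent maximum-likelihood estimates, so
    comparisons between estimators are made on the reduced matrix.
    """
    x = matrix.values
    lo = matrix.item_min[None, :]
    hi = matrix.item_max[None, :]
    keep_p = np.ones(matrix.n_persons, dtype=bool)
    keep_i = np.ones(matrix.n_items, dtype=bool)
    changed = True
    while changed:
        changed = False
        sub = x[np.ix_(keep_p, keep_i)]
        sub_lo = lo[:, keep_i]
        sub_hi = hi[:, keep_i]
        obs = ~np.isnan(sub)
        at_hi = np.where(obs, sub == sub_hi, True)
        at_lo = np.where(obs, sub == sub_lo, True)
        row_ext = at_hi.all(axis=1) | at_lo.all(axis=1)
        col_ext = at_hi.all(axis=0) | at_lo.all(axis=0)
        if row_ext.any():
            keep_p[np.nonzero(keep_p)[0][row_ext]] = False
            changed = True
        if col_ext.any():
            keep_i[np.nonzero(keep_i)[0][col_ext]] = False
            changed = True
    return ResponseMatrix(
        person_ids=[p for p, k in zip(matrix.person_ids, keep_p) if k],
        item_ids=[i for i, k in zip(matrix.item_ids, keep_i) if k],
        values=x[np.ix_(keep_p, keep_i)],
        item_min=matrix.item_min[keep_i],
        item_max=matrix.item_max[keep_i],
        missing_mask=matrix.missing_mask[np.ix_(keep_p, keep_i)],
    )


# --- independent oracle -----------------------------------------------------

_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0


def _golden_max(f, lo: float, hi: float, tol: float = 1e-8) -> float:
    """Golden-section maximization of a unimodal scalar function on [lo, hi]."""
    a, b = lo, hi
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - _INVPHI * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _INVPHI * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def _row_loglik(x_row, eta):
    """Fractional-success log-likelihood of one row at linear predictor eta."""
    # log p = -log(1 + e^-eta), log(1-p) = -log(1 + e^eta), stable both ways
    return float(np.sum(-x_row * np.logaddexp(0.0, -eta)
                        - (1.0 - x_row) * np.logaddexp(0.0, eta)))


def oracle_binary_jmle(matrix: ResponseMatrix, tol: float = 1e-6,
                       max_sweeps: int = 2000, bound: float = 12.0):
    """Estimate theta and delta by golden-section coordinate ascent.

    A deliberately independent check on the Newton-Raphson fit: it profiles
    the joint fractional-success log-likelihood one parameter at a time with
    a derivative-free golden-section search, recentering the item
    difficulties (and compensating the person measures, which leaves every
    ``theta - delta`` untouched) after each sweep, until the largest
    parameter change in a sweep falls below ``tol``.

    Requires binary {0, 1} responses with no extreme rows or columns
    (use :func:`strip_extremes` first).
    """
    from .core import rescale  # deferred to keep the module graphs disjoint

    resc = rescale(matrix)
    x = resc.values
    if np.any(np.isnan(x)):
        raise ValueError("the oracle does not handle missing cells")
    if not np.all(np.isin(x, (0.0, 1.0))):
        raise ValueError("the oracle requires binary {0, 1} responses")
    row_sum = x.sum(axis=1)
    col_sum = x.sum(axis=0)
    n, l = x.shape
    if np.any((row_sum == 0) | (row_sum == l)) or np.any((col_sum == 0) | (col_sum == n)):
        raise ValueError("extreme rows/columns present; strip them first")

    theta = np.zeros(n)
    delta = np.zeros(l)
    for _ in range(max_sweeps):
        prev_t = theta.copy()
        prev_d = delta.copy()
        for i in range(n):
            row = x[i]
            theta[i] = _golden_max(lambda t: _row_loglik(row, t - delta),
                                   -bound, bound)
        for j in range(l):
            col = x[:, j]
            delta[j] = _golden_max(lambda d: _row_loglik(col, theta - d),
                                   -bound, bound)
        shift = delta.mean()
        delta -= shift
        theta -= shift
        if max(np.max(np.abs(theta - prev_t)), np.max(np.abs(delta - prev_d))) < tol:
            break
    return theta, delta


# --- simulated CAT respondents ----------------------------------------------

class Respondent:
    """A simulated examinee producing unit-interval responses item by item."""

    def __init__(self, true_theta: float, mode: str = "exact",
                 beta_precision: float = 12.0, seed: int | None = None):
        if mode not in ("exact", "beta"):
            raise ValueError("mode must be exact or beta")
        self.true_theta = float(true_theta)
        self.mode = mode
        self.beta_precision = float(beta_precision)
        self._rng = np.random.default_rng(seed)

    def respond(self, difficulty: float) -> float:
        p = float(expit(self.true_theta - difficulty))
        if self.mode == "exact":
            return p
        nu = self.beta_precision
        return float(self._rng.beta(p * nu, (1.0 - p) * nu))


def simulate_respondent(true_theta: float, difficulties, mode: str = "exact",
                        beta_precision: float = 12.0,
                        seed: int | None = None) -> list[float]:
    """Pre-draw a response stream for the given difficulty sequence."""
    r = Respondent(true_theta, mode=mode, beta_precision=beta_precision,
                   seed=seed)
    return [r.respond(d) for d in np.asarray(difficulties, dtype=float)]
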
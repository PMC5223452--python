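"""Computerized adaptive testing over a calibrated Rasch item bank.

The engine administers items one at a time: each step picks the unused item
with maximal Rasch information at the current provisional measure, records
the unit-interval response, re-solves the fractional-success score equation
for the measure, and updates three session diagnostics:

* ``mse``  — the measurement standard error ``1 / sqrt(sum p_i (1 - p_i))``
  over the administered items;
* ``resi`` — the mean of the last three absolute changes in the provisional
  measure (defined once four estimates exist);
* ``corr`` — the Pearson correlation between the last three provisional
  measures and their step numbers, a display-only flatness indicator.

The session stops when ``resi`` drops strictly below 0.05 (a stable
estimate), when the bank is exhausted, or at a configured item maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "ItemBank",
    "CATState",
    "select_next_item",
    "update_theta",
    "standard_error",
    "convergence_residual",
    "convergence_corr",
    "stop_reason_for",
    "step",
    "run_session",
]

RESIDUAL_STOP = 0.05


@dataclass
class ItemBank:
    """Calibrated item difficulties on the logit scale (discrimination = 1)."""

    item_ids: list
    difficulties: np.ndarray

    def __post_init__(self) -> None:
        self.difficulties = np.asarray(self.difficulties, dtype=float)
        if self.difficulties.ndim != 1 or len(self.item_ids) != self.difficulties.size:
            raise ValueError("item_ids and difficulties must align")
        if len(set(map(str, self.item_ids))) != len(self.item_ids):
            raise ValueError("duplicate item identifiers in bank")
        if not np.all(np.isfinite(self.difficulties)):
            raise ValueError("difficulties must be finite")

    @property
    def size(self) -> int:
        return self.difficulties.size

    def index_of(self, item_id) -> int:
        return self.item_ids.index(item_id)


@dataclass
class CATState:
    """Running state of one adaptive session."""

    responses: list = field(default_factory=list)  # (item_id, x) pairs
    theta_trail: list = field(default_factory=list)
    theta: float = 0.0
    mse: float | None = None
    resi: float | None = None
    corr: float | None = None
    corr_flat: bool = False
    stopped: bool = False
    stop_reason: str | None = None
    extreme: bool = False
    max_items: int | None = None

    @property
    def administered_ids(self) -> list:
        return [item for item, _ in self.responses]

    @property
    def n_administered(self) -> int:
        return len(self.responses)


def select_next_item(state: CATState, bank: ItemBank):
    """Unadministered item with maximal information ``p(1-p)`` at the
    current provisional measure — equivalently, minimal ``|theta - delta|``;
    ties go to the lowest bank index."""
    used = set(state.administered_ids)
    best = None
    best_gap = np.inf
    for idx, (item_id, d) in enumerate(zip(bank.item_ids, bank.difficulties)):
        if item_id in used:
            continue
        gap = abs(state.theta - d)
        if gap < best_gap:
            best, best_gap = item_id, gap
    if best is None:
        raise LookupError("item bank exhausted; the session must stop")
    return best


def update_theta(state: CATState, bank: ItemBank, *, max_step: float = 1.0,
                 theta_clamp: float = 10.0, variance_floor: float = 1e-6,
                 tol: float = 1e-10, max_iter: int = 500) -> float:
    """Solve the score equation ``sum_i (x_i - p_i) = 0`` over administered
    items by damped Newton iteration from the previous provisional measure.

    All-bound response strings diverge; the measure is clamped at
    ``theta_clamp`` and the state flagged extreme.
    """
    if not state.responses:
        raise ValueError("no responses recorded yet")
    deltas = np.array([bank.difficulties[bank.index_of(i)]
                       for i, _ in state.responses])
    xs = np.array([x for _, x in state.responses])
    theta = state.theta
    for _ in range(max_iter):
        p = expit(theta - deltas)
        var = np.maximum(p * (1.0 - p), variance_floor)
        raw = np.sum(xs - p) / np.sum(var)
        stepped = float(np.clip(raw, -max_step, max_step))
        new = float(np.clip(theta + stepped, -theta_clamp, theta_clamp))
        done = abs(new - theta) < tol
        theta = new
        if done:
            break
    state.extreme = bool(np.all(xs == 1.0) or np.all(xs == 0.0)) and \
        abs(theta) >= theta_clamp - 1e-9
    return theta


def standard_error(state: CATState, bank: ItemBank,
                   variance_floor: float = 1e-6) -> float:
    """Measurement standard error ``1 / sqrt(sum_i p_i (1 - p_i))`` at the
    current provisional measure, over the administered items."""
    if not state.responses:
        raise ValueError("no responses recorded yet")
    deltas = np.array([bank.difficulties[bank.index_of(i)]
                       for i, _ in state.responses])
    p = expit(state.theta - deltas)
    var = np.maximum(p * (1.0 - p), variance_floor)
    return float(1.0 / np.sqrt(var.sum()))


def convergence_residual(state: CATState) -> float | None:
    """Mean of the last three absolute changes of the provisional measure.

    Undefined (None) until four estimates exist; the stop rule is inactive
    while undefined.
    """
    trail = state.theta_trail
    if len(trail) < 4:
        return None
    diffs = np.abs(np.diff(np.asarray(trail[-4:])))
    return float(diffs.mean())


def convergence_corr(state: CATState):
    """Pearson correlation of the last three provisional measures with their
    step numbers; returns ``(corr, flat)`` where a zero-variance triple is
    reported as (0.0, True).  Display-only: the flatter the trend, the more
    settled the measure."""
    trail = state.theta_trail
    if len(trail) < 3:
        return None, False
    y = np.asarray(trail[-3:], dtype=float)
    if np.ptp(y) == 0.0:
        return 0.0, True
    r = np.corrcoef(np.arange(3.0), y)[0, 1]
    if np.isnan(r):
        return 0.0, True
    return float(r), False


def stop_reason_for(resi: float | None, n_administered: int,
                    n_remaining: int, max_items: int | None) -> str | None:
    """Stop decision after a step: stable-estimate rule first (strictly
    ``resi < 0.05``), then bank exhaustion, then the item cap."""
    if resi is not None and resi < RESIDUAL_STOP:
        return "residual"
    if n_remaining == 0:
        return "bank_exhausted"
    if max_items is not None and n_administered >= max_items:
        return "max_items"
    return None


def step(state: CATState, bank: ItemBank, response: float,
         item_id=None, **theta_kwargs) -> CATState:
    """Administer one item and fold its response into the session.

    ``item_id`` defaults to the information-maximal choice of
    :func:`select_next_item`.  Records the response, re-estimates the
    provisional measure, refreshes mse/resi/corr, and applies the stop rules.
    """
    if state.stopped:
        raise RuntimeError("session already stopped")
    response = float(response)
    if not 0.0 <= response <= 1.0:
        raise ValueError(f"response {response} outside the unit interval")
    if item_id is None:
        item_id = select_next_item(state, bank)
    elif item_id in set(state.administered_ids):
        raise ValueError(f"item {item_id!r} already administered")
    else:
        bank.index_of(item_id)  # raises ValueError for unknown ids
    state.responses.append((item_id, response))
    state.theta = update_theta(state, bank, **theta_kwargs)
    state.theta_trail.append(state.theta)
    state.mse = standard_error(state, bank)
    state.resi = convergence_residual(state)
    state.corr, state.corr_flat = convergence_corr(state)
    reason = stop_reason_for(state.resi, state.n_administered,
                             bank.size - state.n_administered, state.max_items)
    if reason is not None:
        state.stopped = True
        state.stop_reason = reason
    return state


def run_session(bank: ItemBank, respond, max_items: int | None = None,
                **theta_kwargs) -> CATState:
    """Drive a full session: ``respond(difficulty) -> x`` supplies responses
    (e.g. :class:`raschcir.simulate.Respondent`)."""
    state = CATState(max_items=max_items)
    while not state.stopped:
        item_id = select_next_item(state, bank)
        x = respond(bank.difficulties[bank.index_of(item_id)])
        step(state, bank, x, item_id=item_id, **theta_kwargs)
    return state
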
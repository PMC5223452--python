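"""The persons x items response container.

Rows are respondents (persons, departments, teams...), columns are items
(questionnaire items, survey domains, score components).  Cells hold raw
responses in arbitrary units together with per-item bounds used to rescale
them to the unit interval; missing cells are allowed and excluded from every
sum downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ResponseMatrix:
    """Raw N x L response matrix with per-item bounds and a missing mask.

    ``values`` holds NaN at missing cells; ``missing_mask`` mirrors that.
    Every non-missing value must lie inside its item's ``[item_min,
    item_max]`` interval, and each item needs ``item_min < item_max`` for the
    unit-interval rescaling to be defined.
    """

    person_ids: list
    item_ids: list
    values: np.ndarray
    item_min: np.ndarray
    item_max: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D persons x items grid")
        n, l = self.values.shape
        if n < 2 or l < 2:
            raise ValueError(
                f"need at least 2 persons and 2 items for estimation, got {n} x {l}"
            )
        if len(self.person_ids) != n or len(self.item_ids) != l:
            raise ValueError("id lists must match the grid shape")
        if len(set(map(str, self.person_ids))) != n:
            raise ValueError("duplicate person identifiers")
        if len(set(map(str, self.item_ids))) != l:
            raise ValueError("duplicate item identifiers")
        self.item_min = np.broadcast_to(
            np.asarray(self.item_min, dtype=float), (l,)
        ).copy()
        self.item_max = np.broadcast_to(
            np.asarray(self.item_max, dtype=float), (l,)
        ).copy()
        if np.any(self.item_min >= self.item_max):
            bad = [self.item_ids[j] for j in np.nonzero(self.item_min >= self.item_max)[0]]
            raise ValueError(f"item_min must be < item_max; offending items: {bad}")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != (n, l):
            raise ValueError("missing_mask must match the grid shape")
        self.values = np.where(self.missing_mask, np.nan, self.values)
        obs = ~self.missing_mask
        low = obs & (self.values < self.item_min)
        high = obs & (self.values > self.item_max)
        if low.any() or high.any():
            i, j = np.argwhere(low | high)[0]
            raise ValueError(
                f"response {self.values[i, j]!r} for person {self.person_ids[i]!r}, "
                f"item {self.item_ids[j]!r} lies outside its bounds "
                f"[{self.item_min[j]}, {self.item_max[j]}]"
            )

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def observed_mask(self) -> np.ndarray:
        """Boolean grid, True where a response was recorded."""
        return ~self.missing_mask
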
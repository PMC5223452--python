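"""Run configuration for estimation and adaptive-testing sessions."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class RunConfig:
    """Settings shared by the estimation loop and the CAT engine.

    Parameters
    ----------
    convergence_tol
        Stop the joint estimation loop once the total absolute residual
        ``sum |O - E|`` over all observed cells falls below this level.
        On noisy data this sum never approaches zero, so the parameter-change
        criterion below is the one that usually fires.
    change_tol
        Stop once the largest absolute parameter change (person measures and
        item difficulties, in logits) in one full iteration falls below this.
    max_iter
        Hard cap on outer iterations; hitting it yields ``converged=False``
        and a warning, never an exception.
    variance_floor
        Lower bound applied to every cell variance ``p(1-p)`` so Newton
        denominators and standardized residuals stay finite as ``p`` nears
        a bound.
    max_step
        Damping: a single Newton update is never larger than this many logits.
    theta_clamp
        Measures and difficulties are kept inside ``[-theta_clamp,
        theta_clamp]``; extreme response strings (all cells at a scale bound)
        have divergent maximum-likelihood estimates and end up pinned here.
    normalize_mnsq
        If true, INFIT/OUTFIT mean squares are rescaled so each set has mean
        exactly 1.0 (continuous responses tend to produce uniformly small
        residuals, which pushes raw mean squares well below their nominal
        expectation).
    seed
        Single seed from which every stochastic component (simulation,
        simulated CAT respondents) derives its randomness.
    """

    convergence_tol: float = 0.01
    change_tol: float = 1e-4
    max_iter: int = 1000
    variance_floor: float = 1e-6
    max_step: float = 1.0
    theta_clamp: float = 10.0
    normalize_mnsq: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("convergence_tol", "change_tol", "variance_floor",
                     "max_step", "theta_clamp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
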
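"""Seeded generators for synthetic trial data.

Survival fixtures follow the model the closed-form calculations assume:
exponential event times ``T ~ Exp(ln 2 / median)`` per arm, with
independent right-censoring calibrated so the expected fraction of
observed events equals a target non-censoring probability ``p``.  Two
censoring families are supported:

* ``"exponential"`` — censoring times ``C ~ Exp(lambda_c)``; then
  ``p = lambda_e / (lambda_e + lambda_c)`` gives the closed form
  ``lambda_c = lambda_e (1 - p) / p``;
* ``"uniform"`` — administrative censoring ``C ~ Uniform(0, b)`` with the
  horizon ``b`` solved numerically from
  ``p = 1 - (1 - exp(-lambda_e b)) / (lambda_e b)``.

``p = 1`` disables censoring exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import DesignError
from .survival import SurvivalDataset

__all__ = ["ArmGenSpec", "SurvivalGenSpec", "gen_exponential_cohort", "gen_binary_cohort"]


@dataclass(frozen=True)
class ArmGenSpec:
    label: str
    median: float  # months
    n: int

    def __post_init__(self) -> None:
        if not self.median > 0:
            raise DesignError("median must be positive")
        if self.n < 1:
            raise DesignError("n must be a positive integer")


@dataclass(frozen=True)
class SurvivalGenSpec:
    """Generator settings: one or more arms plus a shared censoring model."""

    arms: tuple[ArmGenSpec, ...]
    target_noncensor: float = 1.0
    censoring: str = "exponential"  # or "uniform" (administrative)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.arms:
            raise DesignError("at least one arm required")
        if not 0.0 < self.target_noncensor <= 1.0:
            raise DesignError("target_noncensor must lie in (0, 1]")
        if self.censoring not in ("exponential", "uniform"):
            raise DesignError("censoring must be 'exponential' or 'uniform'")


def _uniform_horizon(lam: float, p: float) -> float:
    # solve 1 - (1 - exp(-lam*b)) / (lam*b) = p for the horizon b
    def g(b: float) -> float:
        x = lam * b
        return 1.0 - (1.0 - math.exp(-x)) / x - p

    lo, hi = 1e-9, 1.0
    while g(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            raise DesignError("failed to bracket the censoring horizon")
    return brentq(g, lo, hi)


def gen_exponential_cohort(spec: SurvivalGenSpec) -> SurvivalDataset:
    """Draw a seeded exponential cohort with calibrated censoring."""
    rng = np.random.default_rng(spec.seed)
    arms, times, events = [], [], []
    for arm in spec.arms:
        lam = math.log(2.0) / arm.median
        t_event = rng.exponential(1.0 / lam, size=arm.n)
        if spec.target_noncensor >= 1.0:
            obs, ev = t_event, np.ones(arm.n, dtype=int)
        else:
            if spec.censoring == "exponential":
                lam_c = lam * (1.0 - spec.target_noncensor) / spec.target_noncensor
                c = rng.exponential(1.0 / lam_c, size=arm.n)
            else:
                b = _uniform_horizon(lam, spec.target_noncensor)
                c = rng.uniform(0.0, b, size=arm.n)
            obs = np.minimum(t_event, c)
            ev = (t_event <= c).astype(int)
        arms.extend([arm.label] * arm.n)
        times.append(obs)
        events.append(ev)
    return SurvivalDataset.from_arrays(
        arms, np.concatenate(times), np.concatenate(events)
    )


def gen_binary_cohort(p_success: float, n: int, seed: int = 0) -> int:
    """One seeded binomial draw: the success count out of n patients."""
    if not 0.0 <= p_success <= 1.0:
        raise DesignError("p_success must lie in [0, 1]")
    if n < 1:
        raise DesignError("n must be a positive integer")
    return int(np.random.default_rng(seed).binomial(n, p_success))
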
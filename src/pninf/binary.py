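"""Exact-binomial and Monte-Carlo design calculations for binary endpoints.

The margin of practical non-inferiority for a binary endpoint (e.g.
objective response) is a difference in success proportions: the trial
concludes practical non-inferiority when the observed approved-minus-
reduced difference ``(k2 - k1)/n`` is at most the margin.  With per-arm
counts ``k1 ~ Bin(n, p1)`` and ``k2 ~ Bin(n, p2)`` the operating
characteristics are exact joint-binomial probabilities; beyond a
configurable enumeration limit a seeded Monte-Carlo estimate is used.

The non-inferiority event uses an inclusive ``<=`` and its complement a
strict ``>``, which matters on the integer lattice of count differences.
Unlike the Gaussian time-to-event case, ``pi_n`` is not monotone in n
(the margin threshold ``floor(margin * n)`` moves on the lattice), so the
sample-size searches scan every integer n rather than bisecting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np
from scipy.stats import binom

from .errors import DesignError, UnattainableDesignError

__all__ = [
    "BinaryDesignSpec",
    "MCEstimate",
    "BinarySampleSizeResult",
    "exact_prob_noninf",
    "exact_prob_inf",
    "mc_prob",
    "n_hat_noninf_binary",
    "n_hat_inf_binary",
    "recommended_n_binary",
]

# slack for comparing the integer count difference with margin * n, so an
# exactly-on-margin lattice point is counted inclusively despite rounding
_LATTICE_EPS = 1e-9


@dataclass(frozen=True)
class BinaryDesignSpec:
    """Parameterization of a binary-endpoint practical-NI design.

    ``p_approved`` is the success rate assumed for the approved dose
    (under the second perspective, the experimental-arm rate of the prior
    phase III); ``p_reduced_inferior`` is the rate assumed for the reduced
    dose under that perspective (typically the prior control-arm rate).
    ``margin_points`` is the margin as a difference in proportions.
    """

    p_approved: float
    p_reduced_inferior: float
    margin_points: float
    q_threshold: float = 0.80
    z_threshold: float = 0.80
    n_cap: int = 20_000
    exact_limit: int = 2_000
    mc_reps: int = 100_000
    seed: int = 20_250

    def __post_init__(self) -> None:
        for name in ("p_approved", "p_reduced_inferior", "q_threshold", "z_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise DesignError(f"{name} must lie strictly in (0, 1)")
        if self.p_reduced_inferior >= self.p_approved:
            raise DesignError("p_reduced_inferior must be below p_approved")
        if not 0.0 < self.margin_points < 1.0:
            raise DesignError("margin_points must lie strictly in (0, 1)")
        if self.margin_points >= self.p_approved - self.p_reduced_inferior:
            raise DesignError(
                "margin_points must be smaller than the assumed decrement "
                "p_approved - p_reduced_inferior, else the inferiority "
                "perspective is unattainable"
            )
        if self.n_cap < 1 or self.exact_limit < 1:
            raise DesignError("n_cap and exact_limit must be positive")
        if self.mc_reps < 1000:
            raise DesignError("mc_reps must be at least 1000")


class MCEstimate(NamedTuple):
    value: float
    se: float


@dataclass(frozen=True)
class BinarySampleSizeResult:
    n_recommended: int
    n_noninf: int
    n_inf: int
    prob_noninf_at_recommended: float
    prob_inf_at_recommended: float

    def to_dict(self) -> dict:
        return {
            "n_recommended": self.n_recommended,
            "n_noninf": self.n_noninf,
            "n_inf": self.n_inf,
            "prob_noninf_at_recommended": self.prob_noninf_at_recommended,
            "prob_inf_at_recommended": self.prob_inf_at_recommended,
        }


def _validate_rate(name: str, v: float) -> None:
    if not 0.0 <= v <= 1.0:
        raise DesignError(f"{name} must lie in [0, 1]")


def _prob_diff_le(n: int, p_reduced: float, p_approved: float, margin: float) -> float:
    """Exact Pr((k2 - k1)/n <= margin), inclusive, via an O(n) convolution.

    k1 ~ Bin(n, p_reduced), k2 ~ Bin(n, p_approved).  For each value of
    k2 the condition is k1 >= k2 - margin*n, a binomial upper tail.
    """
    k2 = np.arange(n + 1)
    k1_min = np.ceil(k2 - margin * n - _LATTICE_EPS).astype(int)
    pmf2 = binom.pmf(k2, n, p_approved)
    tail1 = np.where(k1_min <= 0, 1.0, binom.sf(np.maximum(k1_min, 1) - 1, n, p_reduced))
    tail1 = np.where(k1_min > n, 0.0, tail1)
    return float(min(1.0, np.dot(pmf2, tail1)))


def exact_prob_noninf(
    n_per_arm: int,
    p_common: float,
    margin_points: float,
    exact_limit: int = 2_000,
) -> float:
    """pi_n under the first perspective (both arms at ``p_common``):
    exact probability that the observed difference is within the margin."""
    if n_per_arm < 1:
        raise DesignError("n_per_arm must be >= 1")
    if n_per_arm > exact_limit:
        raise DesignError(
            f"n_per_arm={n_per_arm} exceeds exact_limit={exact_limit}; "
            "use mc_prob for large sample sizes"
        )
    _validate_rate("p_common", p_common)
    if margin_points < 0:
        raise DesignError("margin_points must be non-negative")
    if margin_points >= 1:
        return 1.0
    return _prob_diff_le(n_per_arm, p_common, p_common, margin_points)


def exact_prob_inf(n_per_arm: int, spec: BinaryDesignSpec) -> float:
    """kappa_n under the second perspective: exact probability that the
    observed difference strictly exceeds the margin when the approved arm
    responds at ``p_approved`` and the reduced arm at
    ``p_reduced_inferior``.  By construction the complement of the
    inclusive non-inferiority event at the same unequal rates."""
    if n_per_arm < 1:
        raise DesignError("n_per_arm must be >= 1")
    if n_per_arm > spec.exact_limit:
        raise DesignError(
            f"n_per_arm={n_per_arm} exceeds exact_limit={spec.exact_limit}; "
            "use mc_prob for large sample sizes"
        )
    if spec.margin_points >= 1:
        return 0.0
    return 1.0 - _prob_diff_le(
        n_per_arm, spec.p_reduced_inferior, spec.p_approved, spec.margin_points
    )


def mc_prob(
    n_per_arm: int,
    rate_arm1: float,
    rate_arm2: float,
    margin_points: float,
    mc_reps: int = 100_000,
    seed: int = 0,
    event: Literal["noninf", "inf"] = "noninf",
) -> MCEstimate:
    """Monte-Carlo estimate of pi_n or kappa_n with its binomial SE.

    Draws ``mc_reps`` trial replicates of (k1, k2) and evaluates the same
    inclusive/strict lattice inequality as the exact routines.
    Bit-reproducible for a fixed seed.
    """
    if n_per_arm < 1:
        raise DesignError("n_per_arm must be >= 1")
    if mc_reps < 1000:
        raise DesignError("mc_reps must be at least 1000")
    _validate_rate("rate_arm1", rate_arm1)
    _validate_rate("rate_arm2", rate_arm2)
    if event not in ("noninf", "inf"):
        raise DesignError("event must be 'noninf' or 'inf'")
    rng = np.random.default_rng(seed)
    k1 = rng.binomial(n_per_arm, rate_arm1, size=mc_reps)
    k2 = rng.binomial(n_per_arm, rate_arm2, size=mc_reps)
    within = (k2 - k1) <= margin_points * n_per_arm + _LATTICE_EPS
    est = float(np.mean(within if event == "noninf" else ~within))
    return MCEstimate(est, math.sqrt(est * (1.0 - est) / mc_reps))


def _prob_at(n: int, spec: BinaryDesignSpec, which: Literal["noninf", "inf"]) -> float:
    if n <= spec.exact_limit:
        if which == "noninf":
            return exact_prob_noninf(
                n, spec.p_approved, spec.margin_points, spec.exact_limit
            )
        return exact_prob_inf(n, spec)
    # derive a per-n stream so the scan is deterministic for a fixed spec seed
    sub = np.random.SeedSequence([spec.seed, n]).generate_state(1)[0] % (2**31)
    if which == "noninf":
        return mc_prob(
            n, spec.p_approved, spec.p_approved, spec.margin_points,
            spec.mc_reps, int(sub), "noninf",
        ).value
    return mc_prob(
        n, spec.p_reduced_inferior, spec.p_approved, spec.margin_points,
        spec.mc_reps, int(sub), "inf",
    ).value


def _scan(spec: BinaryDesignSpec, which: Literal["noninf", "inf"],
          threshold: float) -> int:
    # pi_n / kappa_n are not monotone in n on the lattice: scan every n
    for n in range(1, spec.n_cap + 1):
        if _prob_at(n, spec, which) >= threshold:
            return n
    name = "pi_n" if which == "noninf" else "kappa_n"
    raise UnattainableDesignError(
        f"{name} did not reach {threshold} for any n_per_arm up to "
        f"n_cap={spec.n_cap}"
    )


def n_hat_noninf_binary(spec: BinaryDesignSpec) -> int:
    """Smallest per-arm n with pi_n >= Q (first crossing of the scan)."""
    return _scan(spec, "noninf", spec.q_threshold)


def n_hat_inf_binary(spec: BinaryDesignSpec) -> int:
    """Smallest per-arm n with kappa_n >= Z (first crossing of the scan)."""
    return _scan(spec, "inf", spec.z_threshold)


def recommended_n_binary(spec: BinaryDesignSpec) -> BinarySampleSizeResult:
    """Recommended per-arm n = max of the two component searches."""
    n_ni = n_hat_noninf_binary(spec)
    n_if = n_hat_inf_binary(spec)
    n_rec = max(n_ni, n_if)
    return BinarySampleSizeResult(
        n_recommended=n_rec,
        n_noninf=n_ni,
        n_inf=n_if,
        prob_noninf_at_recommended=_prob_at(n_rec, spec, "noninf"),
        prob_inf_at_recommended=_prob_at(n_rec, spec, "inf"),
    )
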
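"""Closed-form design calculations for time-to-event endpoints.

A dose-reduction trial compares a reduced dose (arm 1) against the
approved dose (arm 2) of a licensed drug.  Practical non-inferiority is
declared when the *observed* difference in median survival times falls
within a pre-specified margin, expressed here as a ratio of medians in
(0, 1).  Under exponential survival, ``T_i ~ Exp(lambda_i)``, the
difference of log rate estimates is asymptotically Gaussian,

    ln(lambda2_hat) - ln(lambda1_hat)  ~  N(ln HR, 2 / (n p)),

where ``n`` is the per-arm sample size, ``p`` the probability that a
patient's event is observed (non-censoring), and the hazard ratio equals
the inverse ratio of medians.  Two operating characteristics follow:

* ``pi_n`` — probability the trial lands inside the margin when the two
  doses are truly equivalent (``lambda1 = lambda2``);
* ``kappa_n`` — probability the trial lands outside the margin when the
  reduced dose is truly only as good as a reference inferior median
  (e.g. the historical control of the preceding phase III trial).

The recommended per-arm sample size is the larger of the two argmins
``min{n : pi_n >= Q}`` and ``min{n : kappa_n >= Z}``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import DesignError, UnattainableDesignError

__all__ = [
    "TTEDesignSpec",
    "OperatingCharacteristics",
    "SampleSizeResult",
    "prob_practical_noninf",
    "prob_practical_inf",
    "n_hat_noninf",
    "n_hat_inf",
    "recommended_n",
    "margin_as_months",
    "design_curve",
]

_SEARCH_CHUNK = 1 << 14


@dataclass(frozen=True)
class TTEDesignSpec:
    """Full parameterization of a time-to-event practical-NI design.

    Parameters
    ----------
    median_approved : float
        Median survival of the approved dose, in months.  Fixes the
        approved-arm hazard ``lambda2 = ln 2 / median_approved``.
    median_reference_inferior : float
        A meaningfully worse median (months) assumed for the reduced
        dose under the second design perspective — typically the
        historical control of the prior phase III trial.  Must be below
        ``median_approved``.
    margin_ratio : float
        Margin of practical non-inferiority as a ratio of medians in
        (0, 1); e.g. 0.90 means an observed reduced/approved median
        ratio of at least 90% counts as practically non-inferior.
    q_threshold, z_threshold : float
        Design thresholds Q and Z that ``pi_n`` and ``kappa_n`` must
        respectively reach.
    p_noncensor : float
        Expected fraction of patients whose event is observed; scales
        the variance ``2 / (n p)``.  Common to both arms.
    n_cap : int
        Upper bound for the per-arm sample-size searches.
    """

    median_approved: float
    median_reference_inferior: float
    margin_ratio: float
    q_threshold: float = 0.90
    z_threshold: float = 0.80
    p_noncensor: float = 1.0
    n_cap: int = 100_000

    def __post_init__(self) -> None:
        if not self.median_approved > 0 or not math.isfinite(self.median_approved):
            raise DesignError("median_approved must be positive and finite")
        if not self.median_reference_inferior > 0:
            raise DesignError("median_reference_inferior must be positive")
        if self.median_reference_inferior >= self.median_approved:
            raise DesignError(
                "median_reference_inferior must be below median_approved "
                "(the reference decrement must be a genuine decrease)"
            )
        if not 0.0 < self.margin_ratio < 1.0:
            raise DesignError("margin_ratio must lie strictly in (0, 1)")
        for name in ("q_threshold", "z_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise DesignError(f"{name} must lie strictly in (0, 1)")
        if not 0.0 < self.p_noncensor <= 1.0:
            raise DesignError("p_noncensor must lie in (0, 1]")
        if self.n_cap < 1:
            raise DesignError("n_cap must be a positive integer")

    @classmethod
    def from_margin_months(
        cls,
        median_approved: float,
        margin_months: float,
        median_reference_inferior: float,
        **kwargs,
    ) -> "TTEDesignSpec":
        """Build a spec from an absolute margin width in months.

        The width is converted to the canonical ratio form,
        ``ratio = 1 - margin_months / median_approved``.
        """
        if not 0.0 < margin_months < median_approved:
            raise DesignError("margin_months must lie in (0, median_approved)")
        return cls(
            median_approved=median_approved,
            median_reference_inferior=median_reference_inferior,
            margin_ratio=1.0 - margin_months / median_approved,
            **kwargs,
        )

    @property
    def margin_log(self) -> float:
        """The margin on the log-hazard scale, ``ln(margin_ratio) < 0``."""
        return math.log(self.margin_ratio)

    @property
    def true_log_ratio(self) -> float:
        """``ln(median_reference_inferior / median_approved)``, the mean of
        the log-rate difference under the second perspective."""
        return math.log(self.median_reference_inferior / self.median_approved)


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Design curve: per-arm n with the paired probabilities pi_n, kappa_n."""

    n_per_arm: np.ndarray
    prob_noninf: np.ndarray
    prob_inf: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_per_arm": self.n_per_arm,
                "prob_noninf": self.prob_noninf,
                "prob_inf": self.prob_inf,
            }
        )


@dataclass(frozen=True)
class SampleSizeResult:
    """Recommended per-arm n with the per-perspective breakdown."""

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


def _check_n(n_per_arm) -> None:
    if not float(np.min(n_per_arm)) >= 1:
        raise DesignError("n_per_arm must be a positive integer (>= 1)")


def _sd(n_per_arm, p_noncensor: float):
    # standard deviation of the log-rate difference, sqrt(2 / (n p))
    return np.sqrt(2.0 / (np.asarray(n_per_arm, dtype=float) * p_noncensor))


def _pi(n_per_arm, spec: TTEDesignSpec):
    return norm.sf(spec.margin_log / _sd(n_per_arm, spec.p_noncensor))


def _kappa(n_per_arm, spec: TTEDesignSpec):
    return norm.cdf(
        (spec.margin_log - spec.true_log_ratio) / _sd(n_per_arm, spec.p_noncensor)
    )


def prob_practical_noninf(n_per_arm: int, spec: TTEDesignSpec) -> float:
    """Probability pi_n of concluding practical non-inferiority when the
    two doses are truly equivalent.

    With equal hazards the log-rate difference D is centred at zero, so
    ``pi_n = Pr(ln(margin_ratio) <= D) = Phi(-ln(margin_ratio) *
    sqrt(n p / 2))``.  Ties at the margin count as non-inferior.
    """
    _check_n(n_per_arm)
    return float(_pi(n_per_arm, spec))


def prob_practical_inf(n_per_arm: int, spec: TTEDesignSpec) -> float:
    """Probability kappa_n of concluding practical *inferiority* when the
    reduced dose truly sits at the reference inferior median.

    D is then centred at ``ln(median_reference_inferior /
    median_approved)`` (the HR equals the inverse ratio of medians under
    exponential survival) and ``kappa_n = Pr(D < ln(margin_ratio))``.
    """
    _check_n(n_per_arm)
    return float(_kappa(n_per_arm, spec))


def _first_crossing(prob_fn, threshold: float, n_cap: int, what: str) -> int:
    """Smallest n in [1, n_cap] with prob_fn(n) >= threshold."""
    start = 1
    while start <= n_cap:
        stop = min(start + _SEARCH_CHUNK, n_cap + 1)
        ns = np.arange(start, stop)
        probs = prob_fn(ns)
        hits = np.nonzero(probs >= threshold)[0]
        if hits.size:
            return int(ns[hits[0]])
        start = stop
    raise UnattainableDesignError(
        f"{what} does not reach its threshold {threshold} for any "
        f"n_per_arm up to n_cap={n_cap}; the limiting parameter is n_cap "
        "(raise it) unless the threshold is unreachable for this margin"
    )


def n_hat_noninf(spec: TTEDesignSpec) -> int:
    """Smallest per-arm n with ``pi_n >= Q`` (integer scan from n=1)."""
    return _first_crossing(
        lambda ns: _pi(ns, spec), spec.q_threshold, spec.n_cap, "pi_n"
    )


def n_hat_inf(spec: TTEDesignSpec) -> int:
    """Smallest per-arm n with ``kappa_n >= Z``.

    Requires the true log-ratio to lie strictly outside the margin
    (``ln(ref/approved) < ln(margin_ratio)``) so that kappa_n -> 1.
    """
    if spec.true_log_ratio >= spec.margin_log:
        raise UnattainableDesignError(
            "kappa_n cannot reach a threshold above 1/2: the reference "
            "inferior median lies inside the margin "
            f"(ratio {spec.median_reference_inferior / spec.median_approved:.4f}"
            f" >= margin_ratio {spec.margin_ratio}); the limiting parameter "
            "is median_reference_inferior (or margin_ratio)"
        )
    return _first_crossing(
        lambda ns: _kappa(ns, spec), spec.z_threshold, spec.n_cap, "kappa_n"
    )


def recommended_n(spec: TTEDesignSpec) -> SampleSizeResult:
    """Recommended per-arm sample size ``max(n_noninf, n_inf)`` with the
    component argmins and the probabilities achieved at the maximum."""
    n_ni = n_hat_noninf(spec)
    n_if = n_hat_inf(spec)
    n_rec = max(n_ni, n_if)
    return SampleSizeResult(
        n_recommended=n_rec,
        n_noninf=n_ni,
        n_inf=n_if,
        prob_noninf_at_recommended=prob_practical_noninf(n_rec, spec),
        prob_inf_at_recommended=prob_practical_inf(n_rec, spec),
    )


def margin_as_months(median_approved: float, margin_ratio: float) -> tuple[float, float]:
    """Translate a ratio margin into month units.

    Returns ``(threshold_median, margin_width)`` — the smallest reduced-dose
    median (months) still inside the margin, and the corresponding width
    ``median_approved - threshold_median`` — both rounded to one decimal,
    matching the precision at which trial medians are reported.
    """
    if median_approved <= 0:
        raise DesignError("median_approved must be positive")
    if not 0.0 < margin_ratio <= 1.0:
        raise DesignError("margin_ratio must lie in (0, 1]")
    threshold = round(margin_ratio * median_approved, 1)
    return threshold, round(median_approved - threshold, 1)


def design_curve(
    spec: TTEDesignSpec, n_min: int, n_max: int, step: int = 1
) -> OperatingCharacteristics:
    """Evaluate pi_n and kappa_n over a grid of per-arm sample sizes."""
    if step < 1:
        raise DesignError("step must be a positive integer")
    if not 1 <= n_min <= n_max:
        raise DesignError("need 1 <= n_min <= n_max")
    ns = np.arange(n_min, n_max + 1, step)
    if ns.size == 0:
        raise DesignError("empty sample-size grid")
    return OperatingCharacteristics(
        n_per_arm=ns,
        prob_noninf=_pi(ns, spec),
        prob_inf=_kappa(ns, spec),
    )
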
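"""Bootstrap verification of the closed-form design on patient-level data.

The closed-form sample size rests on an exponential approximation.  When
patient-level data from the preceding phase III trial are available (or
reconstructed), the design can be verified directly: simulate the planned
trial many times by resampling patients with replacement, compute the
Kaplan-Meier median of each simulated arm, and count how often the
observed median difference falls inside / outside the margin.

Two scenarios mirror the two design perspectives:

* equivalence — *both* simulated arms are drawn from the approved-dose
  arm's data, imposing exact equivalence; the fraction of replicates with
  (approved median - reduced median) <= margin estimates P_noninf;
* inferiority — the simulated reduced arm is drawn from a designated
  inferior source (typically the historical control arm) and the approved
  arm from its own data; the fraction with difference > margin estimates
  P_inf.

A replicate arm whose KM median is never reached is treated as median
= +inf; the signed difference then classifies deterministically (an
unreached reduced-arm median can only favour non-inferiority, an
unreached approved-arm median with a finite reduced median counts as
outside the margin).  Replicates where both medians are unreached show no
decrement and count as non-inferior.  All unreached counts are reported;
no replicate is dropped.

The module also hosts the margin-calibration simulation (conditional
probability of *conventional* non-inferiority given practical
non-inferiority, per candidate margin) and a fixed-time variant that
replaces the median with the difference in survival probabilities at a
landmark time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import DesignError
from .survival import SurvivalDataset

__all__ = [
    "BootstrapReport",
    "MarginCalibrationRow",
    "bootstrap_verify",
    "margin_calibration",
    "fixed_time_verify",
]


# ---------------------------------------------------------------------------
# vectorized product-limit machinery (one replicate per row)
# ---------------------------------------------------------------------------

def _sort_rows(times: np.ndarray, events: np.ndarray):
    """Row-wise sort by time, events before censorings at tied times."""
    order = np.lexsort((1 - events, times), axis=-1)
    t = np.take_along_axis(times, order, axis=-1)
    e = np.take_along_axis(events, order, axis=-1)
    return t, e


def _km_factors(e: np.ndarray) -> np.ndarray:
    # product-limit factor at sorted position j: 1 - e_j / (n - j); the
    # sequential product over a tie group equals the grouped (1 - d/r) form
    n = e.shape[-1]
    at_risk = n - np.arange(n)
    return np.where(e == 1, 1.0 - 1.0 / at_risk, 1.0)


def _km_median_rows(times: np.ndarray, events: np.ndarray) -> np.ndarray:
    """KM median per row; +inf where the curve never reaches 0.5."""
    t, e = _sort_rows(times, events)
    surv = np.cumprod(_km_factors(e), axis=-1)
    hit = (e == 1) & (surv <= 0.5 + 1e-12)
    has = hit.any(axis=-1)
    idx = hit.argmax(axis=-1)
    med = np.take_along_axis(t, idx[:, None], axis=-1)[:, 0]
    return np.where(has, med, np.inf)


def _km_survival_at_rows(times: np.ndarray, events: np.ndarray, t_star: float) -> np.ndarray:
    """KM survival probability at t_star per row (right-continuous)."""
    t, e = _sort_rows(times, events)
    factors = np.where(t <= t_star, _km_factors(e), 1.0)
    return np.prod(factors, axis=-1)


def _resample(rng: np.random.Generator, times: np.ndarray, events: np.ndarray,
              reps: int, n_per_arm: int):
    idx = rng.integers(0, times.size, size=(reps, n_per_arm))
    return times[idx], events[idx]


def _signed_diff(m_approved: np.ndarray, m_reduced: np.ndarray) -> np.ndarray:
    """approved - reduced median difference with the unreached policy."""
    both = np.isinf(m_approved) & np.isinf(m_reduced)
    with np.errstate(invalid="ignore"):
        diff = m_approved - m_reduced
    return np.where(both, 0.0, diff)  # no observable decrement -> within margin


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BootstrapReport:
    """Replicate-level differences and the estimated P_noninf / P_inf."""

    p_noninf: float
    p_inf: float
    se_noninf: float
    se_inf: float
    diffs_equivalence: np.ndarray
    diffs_inferiority: np.ndarray
    unreached: dict
    reps: int
    seed: int
    margin: float
    n_per_arm: int
    statistic: str = "median_difference_months"

    def to_dict(self) -> dict:
        """JSON-ready summary (replicate arrays exported separately)."""
        return {
            "statistic": self.statistic,
            "p_noninf": self.p_noninf,
            "p_inf": self.p_inf,
            "se_noninf": self.se_noninf,
            "se_inf": self.se_inf,
            "reps": self.reps,
            "seed": self.seed,
            "margin": self.margin,
            "n_per_arm": self.n_per_arm,
            "unreached": self.unreached,
        }

    def diffs_frame(self) -> pd.DataFrame:
        rows = [
            pd.DataFrame({"scenario": "equivalence", "diff": self.diffs_equivalence}),
            pd.DataFrame({"scenario": "inferiority", "diff": self.diffs_inferiority}),
        ]
        return pd.concat(rows, ignore_index=True)


def _binom_se(p: float, reps: int) -> float:
    return math.sqrt(p * (1.0 - p) / reps)


def bootstrap_verify(
    data: SurvivalDataset,
    approved_arm: str,
    reduced_source_arm: str,
    n_per_arm: int,
    margin_months: float,
    reps: int = 10_000,
    seed: int = 0,
) -> BootstrapReport:
    """Estimate P_noninf and P_inf by resampling patients with replacement.

    Each replicate draws ``n_per_arm`` patients per simulated arm (with
    replacement) from the designated source arms, computes the KM median
    of each, and compares the approved-minus-reduced difference with
    ``margin_months``.  Seeded and reproducible.
    """
    if n_per_arm < 1:
        raise DesignError("n_per_arm must be >= 1")
    if reps < 1:
        raise DesignError("reps must be >= 1")
    if margin_months < 0:
        raise DesignError("margin_months must be non-negative")
    ta, ea = data.arm_data(approved_arm)
    tr, er = data.arm_data(reduced_source_arm)
    rng = np.random.default_rng(seed)

    # equivalence scenario: both simulated arms from the approved-dose data
    m_app_eq = _km_median_rows(*_resample(rng, ta, ea, reps, n_per_arm))
    m_red_eq = _km_median_rows(*_resample(rng, ta, ea, reps, n_per_arm))
    diff_eq = _signed_diff(m_app_eq, m_red_eq)

    # inferiority scenario: reduced arm from the designated inferior source
    m_app_inf = _km_median_rows(*_resample(rng, ta, ea, reps, n_per_arm))
    m_red_inf = _km_median_rows(*_resample(rng, tr, er, reps, n_per_arm))
    diff_inf = _signed_diff(m_app_inf, m_red_inf)

    p_noninf = float(np.mean(diff_eq <= margin_months))
    p_inf = float(np.mean(diff_inf > margin_months))
    unreached = {
        "equivalence_approved": int(np.isinf(m_app_eq).sum()),
        "equivalence_reduced": int(np.isinf(m_red_eq).sum()),
        "inferiority_approved": int(np.isinf(m_app_inf).sum()),
        "inferiority_reduced": int(np.isinf(m_red_inf).sum()),
    }
    return BootstrapReport(
        p_noninf=p_noninf,
        p_inf=p_inf,
        se_noninf=_binom_se(p_noninf, reps),
        se_inf=_binom_se(p_inf, reps),
        diffs_equivalence=diff_eq,
        diffs_inferiority=diff_inf,
        unreached=unreached,
        reps=reps,
        seed=seed,
        margin=margin_months,
        n_per_arm=n_per_arm,
    )


def fixed_time_verify(
    data: SurvivalDataset,
    approved_arm: str,
    reduced_source_arm: str,
    n_per_arm: int,
    t_star: float,
    margin_points: float,
    reps: int = 10_000,
    seed: int = 0,
) -> BootstrapReport:
    """Bootstrap verification with a landmark statistic: the difference in
    KM survival probabilities at ``t_star`` months instead of the median
    difference.  Useful where the median may not be reached (e.g. early-
    stage disease)."""
    if n_per_arm < 1:
        raise DesignError("n_per_arm must be >= 1")
    if t_star < 0:
        raise DesignError("t_star must be non-negative")
    ta, ea = data.arm_data(approved_arm)
    tr, er = data.arm_data(reduced_source_arm)
    if t_star > ta.max() or t_star > tr.max():
        raise DesignError(
            f"t_star={t_star} exceeds the follow-up of at least one source arm"
        )
    rng = np.random.default_rng(seed)

    s_app_eq = _km_survival_at_rows(*_resample(rng, ta, ea, reps, n_per_arm), t_star)
    s_red_eq = _km_survival_at_rows(*_resample(rng, ta, ea, reps, n_per_arm), t_star)
    diff_eq = s_app_eq - s_red_eq

    s_app_inf = _km_survival_at_rows(*_resample(rng, ta, ea, reps, n_per_arm), t_star)
    s_red_inf = _km_survival_at_rows(*_resample(rng, tr, er, reps, n_per_arm), t_star)
    diff_inf = s_app_inf - s_red_inf

    p_noninf = float(np.mean(diff_eq <= margin_points))
    p_inf = float(np.mean(diff_inf > margin_points))
    return BootstrapReport(
        p_noninf=p_noninf,
        p_inf=p_inf,
        se_noninf=_binom_se(p_noninf, reps),
        se_inf=_binom_se(p_inf, reps),
        diffs_equivalence=diff_eq,
        diffs_inferiority=diff_inf,
        unreached={},
        reps=reps,
        seed=seed,
        margin=margin_points,
        n_per_arm=n_per_arm,
        statistic=f"survival_difference_at_{t_star}_months",
    )


# ---------------------------------------------------------------------------
# margin calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarginCalibrationRow:
    margin_months: float
    n_practical_noninf: int
    conditional_prob_conventional: float | None  # None if conditioning set empty

    def to_dict(self) -> dict:
        return {
            "margin_months": self.margin_months,
            "n_practical_noninf": self.n_practical_noninf,
            "conditional_prob_conventional": self.conditional_prob_conventional,
        }


def margin_calibration(
    data: SurvivalDataset,
    approved_arm: str,
    n_per_arm: int,
    candidate_margins: list[float],
    conventional_margin_hr: float,
    alpha: float = 0.025,
    reps: int = 10_000,
    seed: int = 0,
    reduced_source_arm: str | None = None,
) -> list[MarginCalibrationRow]:
    """Conditional probability of conventional NI given practical NI.

    For each candidate margin (months), among bootstrap replicates whose
    observed median difference lies within the margin, report the
    fraction that would also meet a *conventional* non-inferiority test:
    the upper limit of the (1 - 2 alpha) confidence interval for the
    hazard ratio of reduced vs approved must fall below
    ``conventional_margin_hr``.  The HR is estimated per replicate by the
    exponential-rate MLE ``lambda_hat = events / total follow-up time``,
    with log-HR variance ``1/d1 + 1/d2``.

    By default both simulated arms are resampled from the approved arm
    (the equivalence scenario); pass ``reduced_source_arm`` to resample
    the reduced arm from different data.
    """
    if conventional_margin_hr <= 1.0:
        raise DesignError("conventional_margin_hr must exceed 1 on the hazard scale")
    if not 0.0 < alpha < 0.5:
        raise DesignError("alpha must lie in (0, 0.5)")
    if any(m <= 0 for m in candidate_margins):
        raise DesignError("candidate margins must be positive")
    ta, ea = data.arm_data(approved_arm)
    if reduced_source_arm is None:
        tr, er = ta, ea
    else:
        tr, er = data.arm_data(reduced_source_arm)
    rng = np.random.default_rng(seed)

    t_app, e_app = _resample(rng, ta, ea, reps, n_per_arm)
    t_red, e_red = _resample(rng, tr, er, reps, n_per_arm)

    diff = _signed_diff(_km_median_rows(t_app, e_app), _km_median_rows(t_red, e_red))

    d_app = e_app.sum(axis=1).astype(float)
    d_red = e_red.sum(axis=1).astype(float)
    tot_app = t_app.sum(axis=1)
    tot_red = t_red.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_hr = np.log(d_red / tot_red) - np.log(d_app / tot_app)
        se = np.sqrt(1.0 / d_red + 1.0 / d_app)
        upper = log_hr + norm.ppf(1.0 - alpha) * se
    # replicates with a zero-event arm cannot bound the HR: conventional NI fails
    conventional = np.where(
        (d_red > 0) & (d_app > 0), upper < math.log(conventional_margin_hr), False
    )

    rows = []
    for m in candidate_margins:
        sel = diff <= m
        k = int(sel.sum())
        cond = float(np.mean(conventional[sel])) if k > 0 else None
        rows.append(MarginCalibrationRow(float(m), k, cond))
    return rows
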
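import numpy as np
import pytest

from pninf import ArmGenSpec, SurvivalGenSpec, TTEDesignSpec, gen_exponential_cohort

# medians (months) of the cabazitaxel case study: approved dose 15.1,
# historical control 12.7, margin 90% of the approved median
CASE_MEDIAN_APPROVED = 15.1
CASE_MEDIAN_CONTROL = 12.7
CASE_MARGIN_RATIO = 0.90


@pytest.fixture(scope="session")
def case_spec() -> TTEDesignSpec:
    return TTEDesignSpec(
        median_approved=CASE_MEDIAN_APPROVED,
        median_reference_inferior=CASE_MEDIAN_CONTROL,
        margin_ratio=CASE_MARGIN_RATIO,
        q_threshold=0.90,
        z_threshold=0.80,
        p_noncensor=1.0,
    )


@pytest.fixture(scope="session")
def phase3_scale_ipd():
    """Synthetic uncensored exponential cohort at phase-III scale
    (378 + 377 patients, the arm sizes of a large confirmatory trial)."""
    return gen_exponential_cohort(
        SurvivalGenSpec(
            arms=(
                ArmGenSpec("approved", CASE_MEDIAN_APPROVED, 378),
                ArmGenSpec("control", CASE_MEDIAN_CONTROL, 377),
            ),
            target_noncensor=1.0,
            seed=20_251,
        )
    )


def uncensored_km_median(times: np.ndarray) -> float:
    """Independent oracle: with no censoring the KM curve equals the
    empirical survival function, so the median is the order statistic at
    which the empirical survival first drops to 1/2 or below."""
    x = np.sort(np.asarray(times, float))
    n = x.size
    k = int(np.ceil(n / 2))  # survival after k-th event is 1 - k/n <= 1/2
    return float(x[k - 1])
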
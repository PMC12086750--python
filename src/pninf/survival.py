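"""Individual-patient-data handling and Kaplan-Meier estimation.

Datasets hold one row per patient: an arm label, a follow-up time in
months, and an event indicator (1 = event observed, 0 = right-censored).
Curves are product-limit estimates computed through lifelines; medians
and fixed-time survival probabilities are read off the step function.

Conventions: at tied timestamps events precede censorings (so patients
censored at an event time are still at risk at that time), and the median
is the smallest observed event time at which survival drops to 0.5 or
below.  A curve that never reaches 0.5 has an explicitly *not reached*
median, represented as ``math.inf``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .errors import DesignError

__all__ = [
    "SurvivalDataset",
    "KMCurve",
    "MEDIAN_NOT_REACHED",
    "read_ipd",
    "write_ipd",
    "km_estimate",
    "km_median",
    "km_survival_at",
]

MEDIAN_NOT_REACHED = math.inf

_COLUMNS = ("arm", "time", "event")


@dataclass(frozen=True)
class SurvivalDataset:
    """Per-patient follow-up data for one or more trial arms."""

    table: pd.DataFrame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SurvivalDataset":
        cols = {c.lower().strip(): c for c in frame.columns}
        missing = [c for c in _COLUMNS if c not in cols]
        if missing:
            raise DesignError(f"IPD table is missing column(s): {missing}")
        out = frame.rename(columns={cols[c]: c for c in _COLUMNS})[list(_COLUMNS)]
        out = out.copy()
        times = pd.to_numeric(out["time"], errors="coerce")
        events = pd.to_numeric(out["event"], errors="coerce")
        bad_time = times.isna() | (times < 0) | ~np.isfinite(times)
        if bad_time.any():
            row = int(np.nonzero(bad_time.to_numpy())[0][0])
            raise DesignError(
                f"row {row}: follow-up time must be a finite non-negative "
                f"number, got {out['time'].iloc[row]!r}"
            )
        bad_event = events.isna() | ~events.isin((0, 1))
        if bad_event.any():
            row = int(np.nonzero(bad_event.to_numpy())[0][0])
            raise DesignError(
                f"row {row}: event indicator must be 0 or 1, got "
                f"{out['event'].iloc[row]!r}"
            )
        out["time"] = times.astype(float)
        out["event"] = events.astype(int)
        out["arm"] = out["arm"].astype(str)
        if (out["arm"].str.len() == 0).any():
            raise DesignError("empty arm label encountered")
        return cls(out.reset_index(drop=True))

    @classmethod
    def from_arrays(cls, arm, time, event) -> "SurvivalDataset":
        return cls.from_frame(pd.DataFrame({"arm": arm, "time": time, "event": event}))

    @property
    def arms(self) -> list[str]:
        return sorted(self.table["arm"].unique())

    def arm_data(self, arm: str) -> tuple[np.ndarray, np.ndarray]:
        """(times, events) arrays for one arm."""
        sub = self.table[self.table["arm"] == arm]
        if sub.empty:
            raise KeyError(f"unknown arm {arm!r}; available: {self.arms}")
        return sub["time"].to_numpy(float), sub["event"].to_numpy(int)

    def __len__(self) -> int:
        return len(self.table)


def read_ipd(path) -> SurvivalDataset:
    """Read an IPD CSV with (case-insensitive) columns arm, time, event."""
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # malformed CSV structure
        raise DesignError(f"could not parse IPD file {path}: {exc}") from exc
    return SurvivalDataset.from_frame(frame)


def write_ipd(data: SurvivalDataset, path) -> None:
    data.table.to_csv(path, index=False)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit step function for one arm.

    ``times`` are the ordered distinct *event* times; ``survival`` the
    estimate just after each; ``at_risk`` the risk-set size at each.
    Survival starts at 1 and is non-increasing.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


def km_estimate(data: SurvivalDataset, arm: str) -> KMCurve:
    """Kaplan-Meier curve for one arm of the dataset."""
    times, events = data.arm_data(arm)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tab = kmf.event_table
    ev = tab[tab["observed"] > 0]
    surv = np.cumprod(1.0 - ev["observed"].to_numpy(float) / ev["at_risk"].to_numpy(float))
    return KMCurve(
        times=ev.index.to_numpy(float),
        survival=surv,
        at_risk=ev["at_risk"].to_numpy(int),
    )


def km_median(curve: KMCurve) -> float:
    """Smallest event time with S(t) <= 0.5, or ``MEDIAN_NOT_REACHED``."""
    hit = np.nonzero(curve.survival <= 0.5 + 1e-12)[0]
    if hit.size == 0:
        return MEDIAN_NOT_REACHED
    return float(curve.times[hit[0]])


def km_survival_at(curve: KMCurve, t: float) -> float:
    """Right-continuous step-function value S(t)."""
    if t < 0:
        raise DesignError("t must be non-negative")
    idx = int(np.searchsorted(curve.times, t, side="right"))
    return 1.0 if idx == 0 else float(curve.survival[idx - 1])
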
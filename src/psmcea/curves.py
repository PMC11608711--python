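"""Digitized Kaplan-Meier curves and their CSV dialect.

A digitized curve is the coordinate trace read off a published KM plot
(time, survival probability) together with the number-at-risk table printed
beneath it. Curve files use months, the native unit of oncology KM plots;
everything downstream works in years, and this module is the single
conversion point (1 month = 1/12 year).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import MONTHS_PER_YEAR

logger = logging.getLogger(__name__)


@dataclass
class DigitizedCurve:
    """KM coordinates plus the at-risk table for one arm/endpoint.

    Times are stored in years. ``survival`` is repaired to be non-increasing
    at construction (cumulative minimum) because digitization jitter is
    expected and pseudo-IPD reconstruction assumes a monotone input.
    """

    times: np.ndarray            # years, ascending, >= 0
    survival: np.ndarray         # in [0, 1], non-increasing after repair
    risk_times: np.ndarray       # years, ascending
    n_risk: np.ndarray           # non-increasing counts
    total_events: int | None = None
    arm: str = ""
    endpoint: str = ""           # "OS" or "PFS"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        self.risk_times = np.asarray(self.risk_times, dtype=float)
        self.n_risk = np.asarray(self.n_risk, dtype=int)
        if self.times.size < 2:
            raise ValueError("curve needs at least two coordinates")
        if np.any(np.diff(self.times) < 0) or np.any(self.times < 0):
            raise ValueError("time not ascending (or negative)")
        if np.any((self.survival < 0) | (self.survival > 1)):
            raise ValueError("survival outside [0, 1]")
        if self.risk_times.size == 0:
            raise ValueError("empty at-risk table")
        if np.any(np.diff(self.risk_times) <= 0):
            raise ValueError("risk-table times not strictly ascending")
        if np.any(np.diff(self.n_risk) > 0):
            raise ValueError("number at risk increases over time")
        if self.risk_times[0] > self.times[0]:
            raise ValueError("first risk time must be <= first curve time")
        repaired = np.minimum.accumulate(self.survival)
        if np.any(repaired != self.survival):
            logger.warning(
                "%s %s: digitized survival not monotone; repaired by cumulative minimum",
                self.arm, self.endpoint,
            )
            self.survival = repaired

    @property
    def n_initial(self) -> int:
        return int(self.n_risk[0])


def read_digitized_curve(
    curve_path: str | Path,
    risk_path: str | Path | None = None,
    total_events: int | None = None,
    arm: str = "",
    endpoint: str = "",
) -> DigitizedCurve:
    """Read a curve CSV (``time_months, survival``) plus its at-risk table.

    The at-risk table may live in a companion file (``time_months, n_risk``)
    or in the same file under those column names.
    """
    curve_path = Path(curve_path)
    df = pd.read_csv(curve_path)
    if not {"time_months", "survival"} <= set(df.columns):
        raise ValueError(f"{curve_path}: expected columns time_months, survival")
    if risk_path is not None:
        risk = pd.read_csv(risk_path)
    elif "n_risk" in df.columns:
        risk = df[["time_months", "n_risk"]].dropna()
    else:
        raise ValueError("no at-risk table: pass risk_path or include an n_risk column")
    if not {"time_months", "n_risk"} <= set(risk.columns):
        raise ValueError("at-risk table needs columns time_months, n_risk")
    risk = risk.dropna(subset=["n_risk"])
    if risk.empty:
        raise ValueError("empty at-risk table")
    return DigitizedCurve(
        times=df["time_months"].to_numpy() / MONTHS_PER_YEAR,
        survival=df["survival"].to_numpy(),
        risk_times=risk["time_months"].to_numpy() / MONTHS_PER_YEAR,
        n_risk=risk["n_risk"].to_numpy(),
        total_events=total_events,
        arm=arm,
        endpoint=endpoint,
    )


def write_digitized_curve(
    curve: DigitizedCurve, curve_path: str | Path, risk_path: str | Path
) -> None:
    pd.DataFrame(
        {"time_months": curve.times * MONTHS_PER_YEAR, "survival": curve.survival}
    ).to_csv(curve_path, index=False)
    pd.DataFrame(
        {"time_months": curve.risk_times * MONTHS_PER_YEAR, "n_risk": curve.n_risk}
    ).to_csv(risk_path, index=False)
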
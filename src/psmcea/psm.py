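"""The partitioned survival model engine.

State occupancy in the three health states (progression-free, progressed
disease, dead) is read directly off the per-cycle OS and PFS curves:
pfs_k = min(PFS_k, OS_k), pd_k = OS_k - pfs_k, dead_k = 1 - OS_k. Costs and
QALYs accrue at cycle starts (no half-cycle correction in the base
configuration; a switch enables it) and are discounted at an annual rate
applied in continuous cycle time: factor_k = (1 + r)^(-t_k).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .config import RunConfig
from . import economics

logger = logging.getLogger(__name__)


@dataclass
class StateOccupancy:
    """Per-cycle proportions in each health state; partitions to 1."""

    pfs: np.ndarray
    pd: np.ndarray
    dead: np.ndarray

    def __post_init__(self) -> None:
        total = self.pfs + self.pd + self.dead
        if np.max(np.abs(total - 1.0)) > 1e-9:
            raise ValueError("state occupancy does not partition to 1")

    @property
    def alive(self) -> np.ndarray:
        return self.pfs + self.pd

    @property
    def new_deaths(self) -> np.ndarray:
        """Death mass entering at each cycle; new_deaths_0 = dead_0."""
        return np.diff(self.dead, prepend=0.0)

    def __len__(self) -> int:
        return len(self.pfs)


def compute_occupancy(
    os_curve, pfs_curve, half_cycle: bool = False
) -> StateOccupancy:
    """Partition the cohort into PFS / PD / dead from the two curves.

    A digitized PFS sitting above OS (possible with separate digitizations)
    is clamped to OS with a warning, putting zero mass in PD there.
    """
    os_v = np.asarray(os_curve, dtype=float)
    pfs_v = np.asarray(pfs_curve, dtype=float)
    if os_v.shape != pfs_v.shape:
        raise ValueError("OS and PFS vectors must have the same length")
    if np.any((os_v < 0) | (os_v > 1)) or np.any((pfs_v < 0) | (pfs_v > 1)):
        raise ValueError("survival values outside [0, 1]")
    if half_cycle:
        os_v = np.concatenate([(os_v[:-1] + os_v[1:]) / 2, os_v[-1:]])
        pfs_v = np.concatenate([(pfs_v[:-1] + pfs_v[1:]) / 2, pfs_v[-1:]])
    if np.any(pfs_v > os_v + 1e-12):
        logger.warning("PFS exceeds OS at %d cycle(s); clamping PFS to OS",
                       int(np.sum(pfs_v > os_v + 1e-12)))
    pfs_c = np.minimum(pfs_v, os_v)
    return StateOccupancy(pfs=pfs_c, pd=os_v - pfs_c, dead=1.0 - os_v)


def discount_factors(config: RunConfig, rate: float | None = None) -> np.ndarray:
    """Per-cycle discount factors (1 + r)^(-t_k), t_k in years."""
    r = config.discount_rate_annual if rate is None else rate
    return (1.0 + r) ** (-config.cycle_times())


def discount_factor(k: int, config: RunConfig, rate: float | None = None) -> float:
    if k < 0:
        raise ValueError("cycle index must be >= 0")
    r = config.discount_rate_annual if rate is None else rate
    return float((1.0 + r) ** (-(k * config.cycle_length_years)))


def cycle_durations(config: RunConfig) -> np.ndarray:
    """Duration of each cycle in years; optionally the final cycle is
    weighted by its true fraction so the horizon is covered exactly."""
    n = config.n_cycles
    dur = np.full(n, config.cycle_length_years)
    if config.truncate_final_cycle:
        covered = (n - 1) * config.cycle_length_years
        dur[-1] = max(config.horizon_years - covered, 0.0)
    return dur


@dataclass
class EconTrace:
    """Per-cycle discounted cost and QALY streams for one arm."""

    arm: str
    occupancy: StateOccupancy
    factors: np.ndarray
    durations: np.ndarray
    cost_components: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    qaly_stream: np.ndarray | None = field(repr=False, default=None)

    @property
    def cost_stream(self) -> np.ndarray:
        return sum(self.cost_components.values())

    @property
    def total_cost(self) -> float:
        return float(self.cost_stream.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.qaly_stream.sum())

    @property
    def life_years(self) -> float:
        """Undiscounted life-years."""
        return float((self.occupancy.alive * self.durations).sum())

    @property
    def disc_life_years(self) -> float:
        return float((self.occupancy.alive * self.durations * self.factors).sum())

    def component_totals(self) -> dict[str, float]:
        return {k: float(v.sum()) for k, v in self.cost_components.items()}

    def to_frame(self) -> pd.DataFrame:
        occ = self.occupancy
        df = pd.DataFrame(
            {
                "cycle": np.arange(len(occ)),
                "time_years": np.cumsum(np.concatenate([[0.0], self.durations[:-1]])),
                "pfs": occ.pfs, "pd": occ.pd, "dead": occ.dead,
                "disc_factor": self.factors,
            }
        )
        for name, arr in self.cost_components.items():
            df[f"cost_{name}"] = arr
        df["qaly"] = self.qaly_stream
        return df


def run_model(
    arm: str,
    curves: tuple,
    params: Mapping[str, float],
    config: RunConfig,
) -> EconTrace:
    """Run the discounted partitioned survival model for one arm.

    *curves* is an ``(os_vector, pfs_vector)`` pair of per-cycle survival
    probabilities; *params* maps parameter names to point values (base-case
    means, a sensitivity bound, or one probabilistic draw).
    """
    os_v, pfs_v = curves
    occ = compute_occupancy(os_v, pfs_v, half_cycle=config.half_cycle_correction)
    rate = params.get("Discount", config.discount_rate_annual)
    factors = discount_factors(config, rate=rate)
    durations = cycle_durations(config)
    components = economics.cost_components(arm, occ, params, config, factors, durations)
    qaly = economics.qaly_trace(arm, occ, params, config, factors, durations)
    return EconTrace(
        arm=arm, occupancy=occ, factors=factors, durations=durations,
        cost_components=components, qaly_stream=qaly,
    )


class ModelRunner:
    """Re-runnable three-arm model: BC and ABC from fitted curves, the
    pembrolizumab arm anchored to BC through the sampled hazard ratios."""

    def __init__(
        self,
        bc_curves: tuple,
        abc_curves: tuple,
        config: RunConfig,
        pbc_curves: tuple | None = None,
    ):
        self.bc_curves = tuple(np.asarray(c, dtype=float) for c in bc_curves)
        self.abc_curves = tuple(np.asarray(c, dtype=float) for c in abc_curves)
        self.pbc_curves = (
            tuple(np.asarray(c, dtype=float) for c in pbc_curves)
            if pbc_curves is not None else None
        )
        self.config = config

    def curves_for(self, arm: str, values: Mapping[str, float]) -> tuple:
        if arm == "BC":
            return self.bc_curves
        if arm == "ABC":
            return self.abc_curves
        if arm == "PBC":
            if self.pbc_curves is not None:
                return self.pbc_curves
            from .fitting import apply_hazard_ratio

            os_v = apply_hazard_ratio(self.bc_curves[0], values["HR_OS_PEM VS C"])
            pfs_v = apply_hazard_ratio(self.bc_curves[1], values["HR_PFS_PEM VS C"])
            return os_v, pfs_v
        raise ValueError(f"unknown arm {arm!r}")

    def run(self, values: Mapping[str, float]) -> dict[str, EconTrace]:
        return {
            arm: run_model(arm, self.curves_for(arm, values), values, self.config)
            for arm in ("BC", "ABC", "PBC")
        }

    def run_totals(self, values: Mapping[str, float]) -> dict[str, tuple]:
        """(cost, QALY, life-years) per arm — the PSA fast path."""
        out = {}
        for arm, trace in self.run(values).items():
            out[arm] = (trace.total_cost, trace.total_qaly, trace.life_years)
        return out
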
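"""Run configuration for the partitioned-survival cost-effectiveness model.

All defaults encode the base-case analysis: 21-day cycles, 20-year horizon,
3% annual discounting, a willingness-to-pay grid from $0 to $300,000/QALY,
a 2-year atezolizumab stopping rule, and 10,000 probabilistic iterations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

DAYS_PER_YEAR = 365.25
MONTHS_PER_YEAR = 12.0

SCHEMA_VERSION = 1


def _default_wtp_grid() -> list[float]:
    return [float(x) for x in range(0, 300_001, 5_000)]


@dataclass
class RunConfig:
    """Model settings; defaults reproduce the base-case configuration."""

    cycle_length_days: int = 21
    horizon_years: float = 20.0
    discount_rate_annual: float = 0.03
    wtp_grid: list[float] = field(default_factory=_default_wtp_grid)
    #: atezolizumab stopping rule in years; ``None`` removes the cap (scenario)
    atezolizumab_cap_years: float | None = 2.0
    psa_iterations: int = 10_000
    rng_seed: int = 2024
    #: apply half-cycle correction to state occupancy (off in base case)
    half_cycle_correction: bool = False
    #: weight the final partial cycle by its true fraction of 21 days
    truncate_final_cycle: bool = False
    #: best-supportive-care and subsequent-treatment costs accrue per cycle
    bsc_per_cycle: bool = True
    #: SAE disutility as a full-QALY decrement instead of one cycle's duration
    sae_full_decrement: bool = False
    #: sample the discount rate in PSA (its tabulated range is 0-0.08)
    sample_discount_rate: bool = False
    #: resample survival-model coefficients from their covariance in PSA
    psa_resample_curves: bool = False
    #: model-selection override, e.g. "rp_hazard,2" or "weibull"; None = by AIC
    model_override: str | None = None
    #: "common" selects one family for all arms/endpoints by summed AIC
    #: (coherent cross-arm extrapolation); "independent" selects per fit list
    model_selection: str = "common"
    #: anchor the pembrolizumab arm on fitted curves ("fitted") or raw KM ("km")
    anchor_basis: str = "fitted"
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.cycle_length_days <= 0:
            raise ValueError("cycle_length_days must be > 0")
        if not (0 <= self.discount_rate_annual < 1):
            raise ValueError("discount_rate_annual must be in [0, 1)")
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be > 0")
        self.wtp_grid = [float(x) for x in self.wtp_grid]
        if any(b < a for a, b in zip(self.wtp_grid, self.wtp_grid[1:])):
            raise ValueError("wtp_grid must be sorted ascending")

    @property
    def cycle_length_years(self) -> float:
        return self.cycle_length_days / DAYS_PER_YEAR

    @property
    def n_cycles(self) -> int:
        """Number of model cycles covering the horizon (ceiling)."""
        return math.ceil(self.horizon_years * DAYS_PER_YEAR / self.cycle_length_days)

    def cycle_times(self):
        """Cycle-start times in years, length ``n_cycles``."""
        import numpy as np

        return np.arange(self.n_cycles) * self.cycle_length_years

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)
        return cls.from_dict(data or {})

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in {".yml", ".yaml"}:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))


def apply_scenario(config: RunConfig, scenario: str) -> RunConfig:
    """Return a copy of *config* adjusted for a named scenario.

    Scenarios: ``base``, ``atezo-uncapped``, ``horizon5``, ``horizon10``.
    """
    d = config.to_dict()
    if scenario == "base":
        pass
    elif scenario == "atezo-uncapped":
        d["atezolizumab_cap_years"] = None
    elif scenario == "horizon5":
        d["horizon_years"] = 5.0
    elif scenario == "horizon10":
        d["horizon_years"] = 10.0
    else:
        raise ValueError(f"unknown scenario: {scenario!r}")
    return RunConfig.from_dict(d)
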
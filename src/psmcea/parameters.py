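"""Economic and clinical model parameters with sampling distributions.

A :class:`ParameterSet` holds one entry per model input: base-case mean,
standard deviation, a low/high range for one-way sensitivity analysis, and
the distribution family used in probabilistic analysis (gamma for costs,
beta for probabilities/proportions/utilities, lognormal for hazard ratios,
or fixed). A bundled default file carries the full published input table in
2024 US dollars.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd

VALID_DISTRIBUTIONS = {"gamma", "beta", "lognormal", "fixed"}


@dataclass(frozen=True)
class Parameter:
    name: str
    mean: float
    sd: float = 0.0
    low: float | None = None
    high: float | None = None
    distribution: str = "fixed"

    def __post_init__(self) -> None:
        if self.distribution not in VALID_DISTRIBUTIONS:
            raise ValueError(
                f"{self.name}: distribution {self.distribution!r} not one of "
                f"{sorted(VALID_DISTRIBUTIONS)}"
            )
        if self.sd < 0:
            raise ValueError(f"{self.name}: sd must be >= 0")
        low, high = self.dsa_bounds()
        if low > high:
            raise ValueError(f"{self.name}: low {low} > high {high}")
        if not (low <= self.mean <= high):
            raise ValueError(f"{self.name}: mean {self.mean} outside [{low}, {high}]")
        if self.distribution == "beta" and not (0 <= self.mean <= 1):
            raise ValueError(f"{self.name}: beta distribution requires mean in [0, 1]")

    def dsa_bounds(self) -> tuple[float, float]:
        """Low/high bounds for one-way sensitivity analysis.

        Uses the tabulated range when present, otherwise +/-20% of the mean.
        """
        if self.low is not None and self.high is not None:
            return float(self.low), float(self.high)
        return 0.8 * self.mean, 1.2 * self.mean


class ParameterSet(Mapping[str, Parameter]):
    """Ordered, name-keyed collection of model parameters."""

    def __init__(self, parameters: list[Parameter]):
        self._params: dict[str, Parameter] = {}
        for p in parameters:
            if p.name in self._params:
                raise ValueError(f"duplicate parameter: {p.name}")
            self._params[p.name] = p

    def __getitem__(self, name: str) -> Parameter:
        try:
            return self._params[name]
        except KeyError:
            raise KeyError(f"parameter {name!r} not in set") from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._params)

    def __len__(self) -> int:
        return len(self._params)

    def value(self, name: str) -> float:
        return self[name].mean

    def values_dict(self) -> dict[str, float]:
        """Base-case point values for every parameter."""
        return {name: p.mean for name, p in self._params.items()}

    def replace(self, name: str, **changes) -> "ParameterSet":
        params = [
            Parameter(**{**asdict(p), **(changes if p.name == name else {})})
            for p in self._params.values()
        ]
        if name not in self._params:
            raise KeyError(name)
        return ParameterSet(params)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(p) for p in self._params.values()])


#: every row of the published input table must be present
MANDATORY_PARAMETERS = [
    p["name"]
    for p in json.loads(
        resources.files("psmcea.data").joinpath("default_parameters.json").read_text()
    )["parameters"]
]


def _from_records(records: list[dict]) -> ParameterSet:
    params = []
    for rec in records:
        dist = str(rec.get("distribution", "fixed")).strip().lower().replace("-", "")
        params.append(
            Parameter(
                name=str(rec["name"]),
                mean=float(rec["mean"]),
                sd=float(rec.get("sd") or 0.0),
                low=None if pd.isna(rec.get("low")) else float(rec["low"]),
                high=None if pd.isna(rec.get("high")) else float(rec["high"]),
                distribution=dist,
            )
        )
    return ParameterSet(params)


def read_parameter_set(path: str | Path, require_complete: bool = True) -> ParameterSet:
    """Read a parameter table from JSON or CSV.

    JSON files carry a ``parameters`` list (or a bare list); CSV files need
    columns ``name, mean, sd, low, high, distribution``. When
    *require_complete* is set, every mandatory model input must be present.
    """
    path = Path(path)
    if path.suffix == ".json":
        data = json.loads(path.read_text())
        records = data["parameters"] if isinstance(data, dict) else data
    else:
        records = pd.read_csv(path).to_dict("records")
    pset = _from_records(records)
    if require_complete:
        missing = [n for n in MANDATORY_PARAMETERS if n not in pset]
        if missing:
            raise ValueError(f"missing mandatory parameter(s): {missing}")
    return pset


def write_parameter_set(pset: ParameterSet, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        payload = {"schema_version": 1, "parameters": [asdict(p) for p in pset.values()]}
        path.write_text(json.dumps(payload, indent=2))
    else:
        pset.to_frame().to_csv(path, index=False)


def default_parameters() -> ParameterSet:
    """The bundled base-case parameter table (2024 USD)."""
    data = json.loads(
        resources.files("psmcea.data").joinpath("default_parameters.json").read_text()
    )
    return _from_records(data["parameters"])
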
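"""Deterministic and probabilistic sensitivity analysis.

One-way (tornado) analysis varies each parameter between its tabulated
range (or +/-20% of the mean when no range is given) holding the rest at
base case. Probabilistic analysis draws every uncertain parameter from its
assigned family -- gamma for costs, beta for probabilities, proportions and
utilities, lognormal for hazard ratios -- with parameters matched to the
tabulated mean/SD by the method of moments (the lognormal spread comes
from the 95% interval). Cost-effectiveness acceptability curves report, at
each willingness-to-pay threshold, the fraction of draws in which each arm
maximizes net monetary benefit (NMB = lambda x QALY - cost).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .parameters import ParameterSet, Parameter
from .psm import ModelRunner

logger = logging.getLogger(__name__)

ARMS = ("BC", "ABC", "PBC")


def method_of_moments(
    mean: float, sd: float, distribution: str,
    low: float | None = None, high: float | None = None,
) -> dict[str, float]:
    """Distribution parameters matching a tabulated mean and SD.

    gamma: shape = (mean/sd)^2, scale = sd^2/mean.
    beta:  nu = mean(1-mean)/sd^2 - 1; alpha = mean*nu, beta = (1-mean)*nu.
    lognormal (hazard ratios): mu = ln(mean),
    sigma = (ln(high) - ln(low)) / (2 * 1.96) from the 95% range.
    """
    if distribution == "fixed" or sd == 0:
        return {}
    if distribution == "gamma":
        return {"shape": (mean / sd) ** 2, "scale": sd**2 / mean}
    if distribution == "beta":
        var = sd**2
        if var >= mean * (1 - mean):
            raise ValueError(
                f"invalid beta moments: sd^2 {var:.4g} >= mean(1-mean) "
                f"{mean * (1 - mean):.4g}"
            )
        nu = mean * (1 - mean) / var - 1
        return {"alpha": mean * nu, "beta": (1 - mean) * nu}
    if distribution == "lognormal":
        if not (low and high and low > 0):
            raise ValueError("lognormal needs a positive (low, high) range")
        return {"mu": math.log(mean), "sigma": (math.log(high) - math.log(low)) / (2 * 1.96)}
    raise ValueError(f"unknown distribution {distribution!r}")


def _is_sampled(p: Parameter, config: RunConfig) -> bool:
    if p.distribution == "fixed" or p.sd == 0:
        return False
    if p.name == "Discount" and not config.sample_discount_rate:
        return False
    return True


def sample_parameters(
    params: ParameterSet, config: RunConfig, n_iter: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Independent joint draws for every uncertain parameter."""
    cols = {}
    for name, p in params.items():
        if not _is_sampled(p, config):
            continue
        mom = method_of_moments(p.mean, p.sd, p.distribution, *p.dsa_bounds())
        if p.distribution == "gamma":
            cols[name] = rng.gamma(mom["shape"], mom["scale"], size=n_iter)
        elif p.distribution == "beta":
            cols[name] = rng.beta(mom["alpha"], mom["beta"], size=n_iter)
        elif p.distribution == "lognormal":
            cols[name] = rng.lognormal(mom["mu"], mom["sigma"], size=n_iter)
    return pd.DataFrame(cols)


@dataclass
class PSADraws:
    """Sampled parameter matrix with per-iteration per-arm outcomes."""

    draws: pd.DataFrame = field(repr=False)
    costs: pd.DataFrame = field(repr=False)
    qalys: pd.DataFrame = field(repr=False)
    seed: int = 0

    @property
    def n_iter(self) -> int:
        return len(self.costs)


def run_psa(
    runner: ModelRunner,
    params: ParameterSet,
    config: RunConfig,
    n_iter: int | None = None,
    seed: int | None = None,
) -> PSADraws:
    """Monte Carlo PSA: rerun the model under joint parameter draws.

    Survival curves stay at their fitted base-case shapes ("fixed-curves"
    mode, the published parameter inventory); the pembrolizumab arm still
    varies through its sampled hazard ratios.
    """
    n_iter = config.psa_iterations if n_iter is None else n_iter
    seed = config.rng_seed if seed is None else seed
    rng = np.random.default_rng(seed)
    draws = sample_parameters(params, config, n_iter, rng)
    base = params.values_dict()
    cost_rows = np.empty((n_iter, len(ARMS)))
    qaly_rows = np.empty((n_iter, len(ARMS)))
    draw_records = draws.to_dict("records") if len(draws.columns) else [{}] * n_iter
    for i, rec in enumerate(draw_records):
        values = {**base, **rec}
        totals = runner.run_totals(values)
        for j, arm in enumerate(ARMS):
            cost_rows[i, j], qaly_rows[i, j], _ = totals[arm]
    return PSADraws(
        draws=draws,
        costs=pd.DataFrame(cost_rows, columns=ARMS),
        qalys=pd.DataFrame(qaly_rows, columns=ARMS),
        seed=seed,
    )


def ceac(psa: PSADraws, wtp_grid) -> pd.DataFrame:
    """Acceptability: P(arm maximizes NMB) at each threshold; ties split."""
    wtp_grid = np.asarray(list(wtp_grid), dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("empty WTP grid")
    costs = psa.costs.to_numpy()
    qalys = psa.qalys.to_numpy()
    arms = list(psa.costs.columns)
    rows = []
    for lam in wtp_grid:
        nmb = lam * qalys - costs
        best = nmb.max(axis=1, keepdims=True)
        winners = nmb >= best - 1e-9
        weights = winners / winners.sum(axis=1, keepdims=True)
        probs = weights.mean(axis=0)
        rows.append({"wtp": lam, **dict(zip(arms, probs))})
    return pd.DataFrame(rows)


def dsa(
    runner: ModelRunner,
    params: ParameterSet,
    config: RunConfig,
    reference: str = "BC",
) -> pd.DataFrame:
    """One-way sensitivity analysis: ICER vs reference at each bound.

    Returns one row per (parameter, comparison arm), sorted by tornado bar
    width |ICER_high - ICER_low| descending. Utility bounds above 1 are
    clipped with a warning.
    """
    base = params.values_dict()
    base_totals = runner.run_totals(base)
    comparisons = [a for a in ARMS if a != reference]

    def icers(totals):
        out = {}
        for arm in comparisons:
            dc = totals[arm][0] - totals[reference][0]
            dq = totals[arm][1] - totals[reference][1]
            out[arm] = dc / dq if dq != 0 else np.nan
        return out

    base_icers = icers(base_totals)
    rows = []
    for name, p in params.items():
        low, high = p.dsa_bounds()
        if name.startswith("Utility") and high > 1:
            logger.warning("%s: high bound %.3g clipped to 1", name, high)
            high = 1.0
        if low == high:
            for arm in comparisons:
                rows.append({"parameter": name, "comparison": arm,
                             "low": low, "high": high,
                             "icer_low": base_icers[arm],
                             "icer_high": base_icers[arm], "spread": 0.0})
            continue
        icers_lo = icers(runner.run_totals({**base, name: low}))
        icers_hi = icers(runner.run_totals({**base, name: high}))
        for arm in comparisons:
            spread = abs(icers_hi[arm] - icers_lo[arm])
            rows.append({"parameter": name, "comparison": arm,
                         "low": low, "high": high,
                         "icer_low": icers_lo[arm], "icer_high": icers_hi[arm],
                         "spread": 0.0 if np.isnan(spread) else float(spread)})
    out = pd.DataFrame(rows).sort_values(
        ["spread", "parameter", "comparison"],
        ascending=[False, True, True], ignore_index=True,
    )
    out.attrs["base_icers"] = base_icers
    return out
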
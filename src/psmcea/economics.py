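"""Costing and QALY accumulation for the three first-line regimens.

Arms: BC (bevacizumab + platinum/taxane chemotherapy), ABC (atezolizumab
added), PBC (pembrolizumab added). Dosing follows the trial protocols:
bevacizumab 15 mg/kg q3w while progression-free; atezolizumab 1200 mg q3w
capped at 2 years in the base case; pembrolizumab 200 mg q3w for up to 35
cycles; chemotherapy (paclitaxel 175 mg/m2 + cisplatin 75 mg/m2 by
default) for 6 cycles. Drugs are priced linearly per mg at published pack
prices (no vial rounding). Severe adverse events (grade >= 3, incidence
> 5%) are costed as a one-off at cycle 0 and carry a one-cycle disutility.
Progressed patients receive subsequent active treatment or best supportive
care per cycle; dying patients incur a one-off end-of-life cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .config import RunConfig, DAYS_PER_YEAR

ARMS = ("BC", "ABC", "PBC")


@dataclass(frozen=True)
class Patient:
    """Average US female body metrics used to resolve weight/BSA dosing."""

    weight_kg: float = 77.5
    body_surface_m2: float = 1.86

    def __post_init__(self) -> None:
        if self.weight_kg <= 0 or self.body_surface_m2 <= 0:
            raise ValueError("weight and body surface must be > 0")

    @classmethod
    def from_params(cls, values: Mapping[str, float]) -> "Patient":
        return cls(
            weight_kg=values["Average weight of the US female"],
            body_surface_m2=values["Average body surface of the US female"],
        )


@dataclass(frozen=True)
class RegimenComponent:
    """One drug in a regimen: dosing rule, dose, price source, duration cap."""

    drug: str
    rule: str               # "per_kg", "per_m2" or "flat" (dose in mg)
    dose: float
    price_param: str        # parameter holding the pack price
    pack_mg: float          # mg per priced pack
    max_cycles: int | None  # None = given while progression-free

    def resolved_dose_mg(self, patient: Patient) -> float:
        if self.rule == "per_kg":
            return self.dose * patient.weight_kg
        if self.rule == "per_m2":
            return self.dose * patient.body_surface_m2
        if self.rule == "flat":
            return self.dose
        raise ValueError(f"unknown dosing rule {self.rule!r}")


def atezolizumab_cap_cycles(config: RunConfig) -> int | None:
    if config.atezolizumab_cap_years is None:
        return None
    return math.floor(config.atezolizumab_cap_years * DAYS_PER_YEAR
                      / config.cycle_length_days)


def regimen_components(arm: str, config: RunConfig) -> list[RegimenComponent]:
    chemo = [
        RegimenComponent("paclitaxel", "per_m2", 175.0, "Cost_paclitaxel_1 mg", 1.0, 6),
        RegimenComponent("cisplatin", "per_m2", 75.0, "Cost_cisplatin_10 mg", 10.0, 6),
    ]
    bev = RegimenComponent("bevacizumab", "per_kg", 15.0,
                           "Cost_bevacizumab_10 mg", 10.0, None)
    if arm == "BC":
        return [bev, *chemo]
    if arm == "ABC":
        atez = RegimenComponent("atezolizumab", "flat", 1200.0,
                                "Cost_atezolizumab_10 mg", 10.0,
                                atezolizumab_cap_cycles(config))
        return [atez, bev, *chemo]
    if arm == "PBC":
        pem = RegimenComponent("pembrolizumab", "flat", 200.0,
                               "Cost_pembrolizumab_1 mg", 1.0, 35)
        return [pem, bev, *chemo]
    raise ValueError(f"unknown arm {arm!r}")


def drug_cost_per_cycle(
    component: RegimenComponent, patient: Patient, values: Mapping[str, float]
) -> float:
    """Cost of one administration, priced linearly at pack price per mg."""
    if component.price_param not in values:
        raise KeyError(f"missing price for {component.drug}: {component.price_param}")
    dose_mg = component.resolved_dose_mg(patient)
    return dose_mg / component.pack_mg * values[component.price_param]


#: severe adverse events entering each arm's cost/disutility profile
SAE_PROFILES: dict[str, list[tuple[str, str]]] = {
    "BC": [
        ("SAE_BC_asthenia", "Cost_asthenia"),
        ("SAE_BC_anaemia", "Cost_anaemia"),
        ("SAE_BC_neutropenia", "Cost_neutropenia"),
        ("SAE_BC_hypertension", "Cost_hypertension"),
        ("SAE_BC_thrombocytopenia", "Cost_thrombocytopenia"),
    ],
    "ABC": [
        ("SAE_ABC_peripheral or sensory neuropathy", "Cost_peripheral or sensory neuropathy"),
        ("SAE_ABC_asthenia", "Cost_asthenia"),
        ("SAE_ABC_anaemia", "Cost_anaemia"),
        ("SAE_ABC_neutropenia", "Cost_neutropenia"),
        ("SAE_ABC_hypertension", "Cost_hypertension"),
        ("SAE_ABC_proteinuria", "Cost_proteinuria"),
        ("SAE_ABC_thrombocytopenia", "Cost_thrombocytopenia"),
    ],
    "PBC": [
        ("SAE_PBC_anaemia", "Cost_anaemia"),
        ("SAE_PBC_neutropenia", "Cost_neutropenia"),
        ("SAE_PBC_hypertension", "Cost_hypertension"),
        ("SAE_PBC_thrombocytopenia", "Cost_thrombocytopenia"),
        ("SAE_PBC_urinary tract infection", "Cost_urinary tract infection"),
        ("SAE_PBC_platelet count decreased", "Cost_platelet count decreased"),
        ("SAE_PBC_white blood cell count decreased", "Cost_white blood cell count decreased"),
        ("SAE_PBC_neutrophil count decreased", "Cost_neutrophil count decreased"),
        ("SAE_PBC_febrile neutropenia", "Cost_febrile neutropenia"),
    ],
}


def sae_cost(arm: str, values: Mapping[str, float]) -> float:
    """One-off SAE management cost: sum of incidence x unit cost."""
    return float(sum(values[inc] * values[cost] for inc, cost in SAE_PROFILES[arm]))


def cost_components(
    arm: str,
    occupancy,
    values: Mapping[str, float],
    config: RunConfig,
    factors: np.ndarray,
    durations: np.ndarray,
) -> dict[str, np.ndarray]:
    """All discounted per-cycle cost streams for one arm.

    Components: drug acquisition (x PFS proportion, respecting duration
    caps), administration (every cycle with an IV component), follow-up
    (all alive), SAE management (one-off, cycle 0), post-progression care,
    end-of-life. Recurring (non-administration) costs in a truncated final
    cycle are prorated by its duration fraction.
    """
    patient = Patient.from_params(values)
    n = len(occupancy)
    k = np.arange(n)
    pfs, pd_, alive = occupancy.pfs, occupancy.pd, occupancy.alive
    dur_frac = durations / config.cycle_length_years

    acquisition = np.zeros(n)
    any_active = np.zeros(n, dtype=bool)
    for comp in regimen_components(arm, config):
        mask = np.ones(n, dtype=bool) if comp.max_cycles is None else k < comp.max_cycles
        any_active |= mask
        acquisition += drug_cost_per_cycle(comp, patient, values) * pfs * mask
    administration = values["Administration cost"] * pfs * any_active
    follow_up = values["Follow-up cost"] * alive * dur_frac

    sae = np.zeros(n)
    sae[0] = sae_cost(arm, values)

    p_sub = values[f"Subsequent active treatment_{arm}"]
    per_pd = (p_sub * values["Subsequent active treatment cost"]
              + (1 - p_sub) * values["Cost_best supportive care"])
    post_progression = pd_ * per_pd * dur_frac
    end_of_life = values["Cost_end-of-life care"] * occupancy.new_deaths

    return {
        "acquisition": acquisition * factors,
        "administration": administration * factors,
        "follow_up": follow_up * factors,
        "sae": sae,                      # cycle 0, factor there is 1
        "post_progression": post_progression * factors,
        "end_of_life": end_of_life * factors,
    }


def acquisition_cost_trace(
    arm: str, occupancy, values: Mapping[str, float], config: RunConfig,
    factors: np.ndarray | None = None, durations: np.ndarray | None = None,
) -> np.ndarray:
    """Drug + administration + follow-up per-cycle costs (discounted when
    factors are given, undiscounted otherwise)."""
    n = len(occupancy)
    if factors is None:
        factors = np.ones(n)
    if durations is None:
        durations = np.full(n, config.cycle_length_years)
    comps = cost_components(arm, occupancy, values, config, factors, durations)
    return comps["acquisition"] + comps["administration"] + comps["follow_up"]


def post_progression_cost_trace(
    arm: str, occupancy, values: Mapping[str, float], config: RunConfig,
    factors: np.ndarray | None = None, durations: np.ndarray | None = None,
) -> np.ndarray:
    """Post-progression care plus end-of-life per-cycle costs."""
    n = len(occupancy)
    if factors is None:
        factors = np.ones(n)
    if durations is None:
        durations = np.full(n, config.cycle_length_years)
    comps = cost_components(arm, occupancy, values, config, factors, durations)
    return comps["post_progression"] + comps["end_of_life"]


def qaly_trace(
    arm: str,
    occupancy,
    values: Mapping[str, float],
    config: RunConfig,
    factors: np.ndarray,
    durations: np.ndarray,
) -> np.ndarray:
    """Discounted per-cycle QALYs with the first-cycle SAE disutility.

    The SAE decrement lasts one cycle by default (loss = rate x disutility
    x cycle duration); ``config.sae_full_decrement`` switches to a whole
    QALY per affected patient.
    """
    u_pfs, u_pd = values["Utility_PFS"], values["Utility_PD"]
    if u_pfs > 1 or u_pd > 1:
        raise ValueError("utilities must be <= 1")
    q = (occupancy.pfs * u_pfs + occupancy.pd * u_pd) * durations * factors
    rate = values[f"SAE_{arm}"]
    loss = rate * values["Disu_SAE"]
    if not config.sae_full_decrement:
        loss *= config.cycle_length_years
    q[0] -= loss
    return q


# ---------------------------------------------------------------------------
# incremental analysis
# ---------------------------------------------------------------------------

def _totals(result) -> tuple[float, float, float]:
    if isinstance(result, tuple):
        return result
    return result.total_cost, result.total_qaly, result.life_years


def icer_table(results: Mapping[str, object], reference: str = "BC") -> pd.DataFrame:
    """Incremental cost-effectiveness vs the reference arm.

    ICER is reported when the arm is both costlier and more effective;
    otherwise the status column flags dominance ("dominant" = cheaper and
    more effective, "dominated" = costlier and less effective) or an
    undefined ratio (equal QALYs).
    """
    if len(results) < 2:
        raise ValueError("need at least two arms")
    if reference not in results:
        raise ValueError(f"reference arm {reference!r} not in results")
    ref_c, ref_q, _ = _totals(results[reference])
    rows = []
    for arm, res in results.items():
        c, q, ly = _totals(res)
        row = {"arm": arm, "cost": c, "qaly": q, "life_years": ly,
               "d_cost": None, "d_qaly": None, "icer": None, "status": "reference"}
        if arm != reference:
            dc, dq = c - ref_c, q - ref_q
            row.update(d_cost=dc, d_qaly=dq)
            if dq > 0 and dc > 0:
                row.update(icer=dc / dq, status="icer")
            elif dq > 0 and dc <= 0:
                row.update(status="dominant")
            elif dq < 0 and dc >= 0:
                row.update(status="dominated")
            elif dq == 0:
                row.update(status="undefined (equal QALYs)")
            else:
                row.update(icer=dc / dq, status="cheaper and less effective")
        rows.append(row)
    return pd.DataFrame(rows)


def pairwise_icers(results: Mapping[str, object]) -> pd.DataFrame:
    """ICER/dominance for every ordered arm pair."""
    rows = []
    for a in results:
        for b in results:
            if a == b:
                continue
            sub = icer_table({b: results[b], a: results[a]}, reference=b)
            row = sub[sub["arm"] == a].iloc[0].to_dict()
            row["vs"] = b
            rows.append(row)
    return pd.DataFrame(rows)[["arm", "vs", "d_cost", "d_qaly", "icer", "status"]]


def efficiency_frontier(results: Mapping[str, object]) -> pd.DataFrame:
    """Cost-effectiveness frontier with simple and extended dominance."""
    items = sorted(((arm, *_totals(res)) for arm, res in results.items()),
                   key=lambda r: (r[1], r[2]))
    status = {arm: "on frontier" for arm, *_ in items}
    frontier = list(items)
    changed = True
    while changed:
        changed = False
        # simple dominance: costlier and no more effective than a predecessor
        for i, a in enumerate(frontier):
            for b in frontier[:i]:
                if a[2] <= b[2]:
                    status[a[0]] = "dominated"
                    frontier.pop(i)
                    changed = True
                    break
            if changed:
                break
        if changed:
            continue
        # extended dominance: sequential ICERs must increase
        if len(frontier) >= 3:
            for i in range(1, len(frontier) - 1):
                icer_lo = ((frontier[i][1] - frontier[i - 1][1])
                           / (frontier[i][2] - frontier[i - 1][2]))
                icer_hi = ((frontier[i + 1][1] - frontier[i][1])
                           / (frontier[i + 1][2] - frontier[i][2]))
                if icer_hi < icer_lo:
                    status[frontier[i][0]] = "extendedly dominated"
                    frontier.pop(i)
                    changed = True
                    break
    rows = []
    for arm, c, q, ly in items:
        rows.append({"arm": arm, "cost": c, "qaly": q, "life_years": ly,
                     "status": status[arm]})
    return pd.DataFrame(rows)
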
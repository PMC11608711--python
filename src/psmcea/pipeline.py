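"""End-to-end analysis: reconstruct -> fit -> extrapolate -> economics -> uncertainty.

``run_pipeline`` takes digitized curves (real or synthetic) for the BC and
ABC arms, reconstructs pseudo-IPD, fits the candidate survival catalogue,
selects per arm/endpoint by AIC (or a configured override), extrapolates
per-cycle survival over the horizon, derives the PBC arm by hazard-ratio
anchoring, and runs the base case plus deterministic and probabilistic
sensitivity analyses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .curves import DigitizedCurve
from .economics import icer_table, efficiency_frontier
from .fitting import (
    PARAMETRIC_FAMILIES, SurvivalFit, apply_hazard_ratio, extrapolate,
    fit_catalogue, select_model, survival_at,
)
from .parameters import ParameterSet
from .psm import EconTrace, ModelRunner
from .reconstruct import (
    PseudoIPD, ReconstructionReport, km_estimate, reconstruct_ipd,
    validate_reconstruction,
)
from .uncertainty import PSADraws, ceac, dsa, run_psa

FITTED_ARMS = ("BC", "ABC")
ENDPOINTS = ("OS", "PFS")


@dataclass
class PipelineResult:
    """Everything the analysis produces, ready for export."""

    config: RunConfig
    ipd: dict[tuple, PseudoIPD] = field(repr=False, default_factory=dict)
    validation: dict[tuple, ReconstructionReport] = field(repr=False, default_factory=dict)
    selection_tables: dict[tuple, pd.DataFrame] = field(repr=False, default_factory=dict)
    chosen_fits: dict[tuple, SurvivalFit] = field(repr=False, default_factory=dict)
    curves_per_cycle: dict[str, tuple] = field(repr=False, default_factory=dict)
    traces: dict[str, EconTrace] = field(repr=False, default_factory=dict)
    incremental: pd.DataFrame | None = None
    frontier: pd.DataFrame | None = None
    tornado: pd.DataFrame | None = None
    psa: PSADraws | None = field(repr=False, default=None)
    ceac_table: pd.DataFrame | None = None

    def summary(self) -> dict:
        """Headline numbers as a JSON-serializable dict."""
        out = {"arms": {}}
        for arm, tr in self.traces.items():
            out["arms"][arm] = {
                "cost": round(tr.total_cost, 2),
                "qaly": round(tr.total_qaly, 4),
                "life_years": round(tr.life_years, 4),
                "cost_components": {k: round(v, 2)
                                    for k, v in tr.component_totals().items()},
            }
        if self.incremental is not None:
            out["incremental"] = json.loads(
                self.incremental.to_json(orient="records"))
        out["model_selection"] = {
            f"{arm}_{ep}": self.chosen_fits[(arm, ep)].describe()
            for (arm, ep) in self.chosen_fits
        }
        out["reconstruction_max_abs_dS"] = {
            f"{arm}_{ep}": round(r.max_abs_dS, 5)
            for (arm, ep), r in self.validation.items()
        }
        return out

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "summary.json").write_text(json.dumps(self.summary(), indent=2))
        for arm, tr in self.traces.items():
            tr.to_frame().to_csv(outdir / f"trace_{arm}.csv", index=False)
        if self.incremental is not None:
            self.incremental.to_csv(outdir / "incremental.csv", index=False)
        if self.frontier is not None:
            self.frontier.to_csv(outdir / "frontier.csv", index=False)
        for (arm, ep), table in self.selection_tables.items():
            table.to_csv(outdir / f"model_selection_{arm}_{ep}.csv", index=False)
        if self.tornado is not None:
            self.tornado.to_csv(outdir / "tornado.csv", index=False)
        if self.ceac_table is not None:
            self.ceac_table.to_csv(outdir / "ceac.csv", index=False)
        if self.psa is not None:
            pd.concat(
                {"cost": self.psa.costs, "qaly": self.psa.qalys}, axis=1
            ).to_csv(outdir / "psa_outcomes.csv", index=False)


def _anchored_base(
    chosen: SurvivalFit, ipd: PseudoIPD, config: RunConfig
) -> np.ndarray:
    """Per-cycle base curve for anchoring: fitted, or KM within follow-up
    with the fitted tail beyond (``config.anchor_basis == 'km'``)."""
    fitted = extrapolate(chosen, config)
    if config.anchor_basis == "fitted":
        return fitted
    km = km_estimate(ipd)
    times = config.cycle_times()
    within = times <= float(np.max(ipd.times))
    base = np.where(within, km(times), fitted)
    return np.minimum.accumulate(np.clip(base, 0, 1))


def run_pipeline(
    curves: dict[str, dict[str, DigitizedCurve]],
    params: ParameterSet,
    config: RunConfig | None = None,
    families: tuple[str, ...] = PARAMETRIC_FAMILIES,
    rp_knots: tuple[int, ...] = (1, 2, 3),
    do_dsa: bool = True,
    do_psa: bool = True,
) -> PipelineResult:
    """Run the full analysis from digitized curves to CEAC.

    *curves* maps the fitted arms ("BC", "ABC") to their OS/PFS digitized
    curves. The PBC arm is derived from BC through the tabulated hazard
    ratios (proportional hazards on the survival scale).
    """
    config = config or RunConfig()
    result = PipelineResult(config=config)
    values = params.values_dict()

    catalogues: dict[tuple, list[SurvivalFit]] = {}
    for arm in FITTED_ARMS:
        for ep in ENDPOINTS:
            curve = curves[arm][ep]
            ipd = reconstruct_ipd(curve)
            result.ipd[(arm, ep)] = ipd
            result.validation[(arm, ep)] = validate_reconstruction(curve, ipd)
            catalogues[(arm, ep)] = fit_catalogue(
                ipd, families=families, rp_knots=rp_knots)

    common_label = None
    if config.model_selection == "common" and not config.model_override:
        # one family for every arm/endpoint, chosen by total AIC: keeps the
        # 20-year extrapolations coherent across arms (a heavy tail fitted
        # to one arm and a light tail to another makes curves cross for
        # reasons unrelated to the data)
        shared = set.intersection(*[{f.label for f in v} for v in catalogues.values()])
        if shared:
            totals = {
                lab: sum(next(f for f in v if f.label == lab).aic
                         for v in catalogues.values())
                for lab in shared
            }
            common_label = min(totals, key=totals.get)

    per_cycle: dict[str, dict[str, np.ndarray]] = {}
    for arm in FITTED_ARMS:
        per_cycle[arm] = {}
        for ep in ENDPOINTS:
            fits = catalogues[(arm, ep)]
            table, chosen = select_model(fits, override=config.model_override)
            if common_label is not None:
                chosen = next(f for f in fits if f.label == common_label)
            result.selection_tables[(arm, ep)] = table
            result.chosen_fits[(arm, ep)] = chosen
            if arm == "BC":
                per_cycle[arm][ep] = _anchored_base(
                    chosen, result.ipd[(arm, ep)], config)
            else:
                per_cycle[arm][ep] = extrapolate(chosen, config)

    bc = (per_cycle["BC"]["OS"], per_cycle["BC"]["PFS"])
    abc = (per_cycle["ABC"]["OS"], per_cycle["ABC"]["PFS"])
    result.curves_per_cycle["BC"] = bc
    result.curves_per_cycle["ABC"] = abc
    result.curves_per_cycle["PBC"] = (
        apply_hazard_ratio(bc[0], values["HR_OS_PEM VS C"]),
        apply_hazard_ratio(bc[1], values["HR_PFS_PEM VS C"]),
    )

    runner = ModelRunner(bc, abc, config)
    result.traces = runner.run(values)
    totals = {arm: (t.total_cost, t.total_qaly, t.life_years)
              for arm, t in result.traces.items()}
    result.incremental = icer_table(totals, reference="BC")
    result.frontier = efficiency_frontier(totals)

    if do_dsa:
        result.tornado = dsa(runner, params, config, reference="BC")
    if do_psa:
        result.psa = run_psa(runner, params, config)
        result.ceac_table = ceac(result.psa, config.wtp_grid)
    return result
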
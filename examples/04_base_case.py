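"""Run the full base-case cost-effectiveness analysis.

Pipeline: reconstruct pseudo-IPD from the bundled fixture's digitized
curves, fit and select survival models, extrapolate to the 20-year
horizon on 21-day cycles, derive the pembrolizumab arm from the control
arm via published hazard ratios, and run the partitioned survival
economic model with the published cost/utility inputs.
"""

from psmcea import RunConfig
from psmcea.pipeline import run_pipeline
from psmcea.synthetic import paper_like_fixture

trial, params = paper_like_fixture(2024)
config = RunConfig()

result = run_pipeline(trial.curves, params, config, do_dsa=False, do_psa=False)

print("chosen survival models:")
for (arm, ep), fit in result.chosen_fits.items():
    print(f"  {arm:>3} {ep:>3}: {fit.label} (AIC {fit.aic:.1f})")

cols = ["arm", "cost", "qaly", "life_years", "d_cost", "d_qaly", "icer", "status"]
print("\nincremental analysis vs BC:")
print(result.incremental[cols].round(3).to_string(index=False))

print("\nefficiency frontier:")
print(result.frontier.round(3).to_string(index=False))
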
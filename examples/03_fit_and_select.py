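"""Fit the survival model catalogue and pick an extrapolation model.

Seven classical parametric families plus flexible spline models (hazard
and odds scales, 1-3 interior knots) are fitted by maximum likelihood to
reconstructed pseudo-IPD; models are ranked by AIC. The pipeline default
selects one common family across all arm/endpoint fits (summed AIC) so
extrapolations stay structurally comparable between arms.
"""

from psmcea.fitting import fit_catalogue, select_model
from psmcea.reconstruct import reconstruct_ipd
from psmcea.synthetic import DEFAULT_TRUTH, simulate_trial

trial = simulate_trial(DEFAULT_TRUTH, seed=11)
ipd = reconstruct_ipd(trial.curves["BC"]["OS"])

fits = fit_catalogue(ipd, rp_knots=(1, 2))
table, best = select_model(fits)

print(table[["model", "n_params", "log_likelihood", "aic"]].round(2).to_string(index=False))
print(f"\nbest by AIC: {best.label}  ({best.describe()})")
print("95% CI for each natural parameter:")
for name, _ in best.param_names:
    lo, hi = best.confint(name)
    print(f"  {name}: {best.params[name]:.3f}  [{lo:.3f}, {hi:.3f}]")
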
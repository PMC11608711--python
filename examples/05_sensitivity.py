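"""Deterministic and probabilistic sensitivity analysis.

One-way (tornado) analysis sweeps each parameter across its tabulated
range; probabilistic analysis draws all uncertain parameters jointly
(gamma/beta/lognormal by method of moments) and summarizes decision
uncertainty as cost-effectiveness acceptability curves.
"""

from psmcea import RunConfig
from psmcea.pipeline import run_pipeline
from psmcea.synthetic import paper_like_fixture

trial, params = paper_like_fixture(2024)
config = RunConfig(psa_iterations=2000)

result = run_pipeline(trial.curves, params, config)

print("top tornado bars (ICER spread vs BC):")
top = result.tornado.head(8)[["parameter", "comparison", "icer_low",
                              "icer_high", "spread"]]
print(top.round(0).to_string(index=False))

print(f"\nPSA: {result.psa.n_iter} iterations, seed {result.psa.seed}")
ceac = result.ceac_table
for wtp in (50_000, 150_000, 300_000):
    row = ceac[ceac["wtp"] == wtp].iloc[0]
    print(f"  P(best) at ${wtp:,}/QALY: "
          + ", ".join(f"{arm}={row[arm]:.2f}" for arm in ("BC", "ABC", "PBC")))
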
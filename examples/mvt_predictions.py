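"""Marginal Value Theorem predictions for the foraging environments.

Builds the semi-Markov chains of the travel-time experiment (patches
starting at 60/90/120 uL, depleting 8 uL per harvest, 10 s harvest trials)
and computes the rate-maximizing number of harvests per patch type in the
near-undiscounted limit (beta = .001, no decision noise).
"""

from foragefit.task import FORAGING_EXPERIMENTS, StateDurations, enumerate_chains
from foragefit.valuation import mvt_prediction

durations = StateDurations(decision_s=1.0, consumption_ul_per_s=20.0)

print("MVT-optimal harvests per patch (travel-time experiment)")
for cond, env in FORAGING_EXPERIMENTS["travel_time"].items():
    chains = enumerate_chains(env, durations)
    pred = mvt_prediction(chains)
    row = "  ".join(f"{int(v)} uL: {n}" for v, n in sorted(pred.items()))
    print(f"  travel {cond:>3}:  {row}")

print()
print(
    "Longer travel raises the cost of leaving, so the optimal policy stays\n"
    "longer in every patch type; richer patches always warrant more harvests."
)
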
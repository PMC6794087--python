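"""Mixed-effects behavioral analyses on a generated travel-time cohort.

Simulates the travel-time experiment for 8 quasi-hyperbolic rats, then runs
the harvests-per-patch mixed model (starting volume x travel time) and the
difference-from-optimal analysis against each rat's own MVT predictions.
"""

from foragefit.stats import (
    add_difference_from_optimal,
    fit_condition_lmm,
    fit_travel_lmm,
    harvests_per_patch,
)
from foragefit.synthetic import CohortSpec, simulate_foraging

cohort = simulate_foraging(
    CohortSpec(task="foraging", experiment="travel_time", n_rats=8,
               patches_per_condition=120, seed=11)
)
summaries = harvests_per_patch(cohort)

res = fit_travel_lmm(summaries)
i_vol = res.terms.index("vol_ml")
print("HarvestsPerPatch ~ StartingVolume * TravelTime  (+ per-rat random slopes)")
print(f"  starting-volume slope = {res.coef[i_vol]:7.2f} trials/mL (SE {res.se[i_vol]:.2f})")
cond_h = fit_condition_lmm(summaries, "harvests")
i_c = cond_h.terms.index("cond")
print("HarvestsPerPatch ~ Condition  (30 s - 10 s travel)")
print(f"  travel-time effect    = {cond_h.coef[i_c]:7.2f} trials    (SE {cond_h.se[i_c]:.2f})")

diff = add_difference_from_optimal(summaries, cohort)
over = fit_condition_lmm(diff, "difference_from_optimal")
i0, i1 = over.terms.index("Intercept"), over.terms.index("cond")
print("DifferenceFromOptimal ~ Condition  (intercept 0 = MVT-optimal)")
print(f"  overharvesting        = {over.coef[i0]:7.2f} trials (SE {over.se[i0]:.2f})")
print(f"  condition difference  = {over.coef[i1]:7.2f} trials (SE {over.se[i1]:.2f})")
print()
print(
    "Rats harvest more from richer patches and when travel is longer, and\n"
    "the positive intercept shows systematic overharvesting relative to the\n"
    "Marginal Value Theorem."
)
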
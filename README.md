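# foragefit

Semi-Markov valuation models of patch foraging and intertemporal choice,
with hierarchical model fitting and mixed-effects behavioral statistics.

## The problem

Rats (and most foragers) *overharvest*: they stay in depleting reward
patches longer than the Marginal Value Theorem (MVT) — leave when the
patch's reward rate falls to the environment's long-run average — says they
should. In intertemporal choice (ITC) tasks the same animals prefer
smaller-sooner over larger-later rewards more than exponential discounting
predicts. This package implements a single modeling framework that asks
whether one set of time preferences explains both behaviors.

Both tasks are modeled as continuous-time semi-Markov processes in which
every task event occupies a state with duration `T(s)` and reward rate
`r(s)`, and values obey

    Q(stay, s) = (1 − e^(−β·T(s)))/β · r(s) + e^(−β·T(s)) · V(s_next)
    Q(leave)   = e^(−β·τ) · V(s_first)

with `V(s) = max(Q(stay, s), Q(leave))` in decision states. Ten candidate
models modify this recursion — subjective leave costs, concave reward
utility (power / CRRA), linear or power distortion of pre- or post-reward
delays, and exponential, hyperbolic (10-muAgent), constant-sensitivity
(`e^(−β·t^α)`) and quasi-hyperbolic (`ω·e^(−βt) + (1−ω)·e^(−δt)`)
discounting. The MVT reference is the β → 0 limit (computed at β = .001).
Patch leaving is stochastic via a patchwise threshold-noise rule, ITC
choices via a magnitude-scaled probit; models are fit per rat under a
Gaussian group prior with hierarchical EM and compared by group-level iBIC
(Laplace-approximated evidence penalized by `(k/2)·log n`). A synthetic
cohort generator mirrors the trial-by-trial structure of both tasks so the
whole pipeline is testable end to end.

## Worked example

```bash
python examples/mvt_predictions.py
```

```
MVT-optimal harvests per patch (travel-time experiment)
  travel 10s:  60 uL: 0  90 uL: 3  120 uL: 7
  travel 30s:  60 uL: 2  90 uL: 5  120 uL: 9
```

Richer patches warrant more harvests, and tripling the travel time makes
leaving costlier, so the optimal policy stays ~2 extra harvests everywhere.
A quasi-hyperbolic agent (β = 0.5/s, δ = 0.005/s, ω = 0.3, σ = 0.15)
overharvests relative to those optima (`examples/leave_distributions.py`),
and the behavioral statistics recover the signatures from a simulated
cohort (`examples/behavioral_statistics.py`):

```
HarvestsPerPatch ~ StartingVolume * TravelTime  (+ per-rat random slopes)
  starting-volume slope =   85.21 trials/mL (SE 5.82)
HarvestsPerPatch ~ Condition  (30 s - 10 s travel)
  travel-time effect    =    1.15 trials    (SE 0.33)
DifferenceFromOptimal ~ Condition  (intercept 0 = MVT-optimal)
  overharvesting        =    3.23 trials (SE 0.19)
```

i.e. simulated rats harvest ~85 extra trials per mL of starting volume,
stay ~1.2 trials longer when travel takes 30 s instead of 10 s, and stay
~3.2 trials past the rate-maximizing optimum. Other examples fit a
hierarchical model to a synthetic cohort (`fit_hierarchical.py`), print ITC
choice curves by reward and delay (`itc_choice_curves.py`), and run the
cross-task test of whether a discount function fit to foraging predicts
held-out intertemporal choices (`cross_task_validation.py`).

## Layout

| module | contents |
|---|---|
| `foragefit.task` | semi-Markov states/chains, the five foraging environments, the ITC task |
| `foragefit.valuation` | discounting primitives, all model variants, value iteration, MVT predictions |
| `foragefit.likelihood` | patch-leave distribution, probit choice rule, dataset log-likelihoods |
| `foragefit.fitting` | parameter transforms, hierarchical EM, Laplace/iBIC, cross-task CV |
| `foragefit.stats` | harvests-per-patch summaries, LMMs, ITC logistic GLMM, post-hoc contrasts |
| `foragefit.synthetic` | generative rat cohorts for both tasks |
| `foragefit.io` | cohort CSV/JSON round trip with column mapping for external tables |

`docs/methods.md` documents the model, the numerical choices, the
generator's assumptions, and known identifiability limits.
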
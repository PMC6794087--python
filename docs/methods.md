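# Methods

## The model

Both tasks — serial patch foraging and two-alternative intertemporal choice
(ITC) — are represented as continuous-time semi-Markov processes: every task
event (cue onset, lever press, reward delivery and consumption, inter-trial
interval, travel between patches, the nose poke starting a new ITC episode)
occupies a state `s` with a constant duration `T(s)` (each rat's mean time
in that state) and a within-state reward rate `r(s)` (non-zero only while
reward is being delivered and consumed). The value of staying in a state is

    Q(stay, s) = R(stay, s) + γ(stay, s) · V(s_next)
    R(stay, s) = (1 − e^(−β·T(s))) / β · r(s)
    γ(stay, s) = e^(−β·T(s))

with discount rate β (1/s). Non-decision states have `V(s) = Q(stay, s)`;
in decision states `V(s) = max(Q(stay, s), Q(leave))` (foraging) or the max
over the SS/LL options (ITC). Leaving a patch is worth the travel-discounted
value of a replenished patch, `Q(leave) = e^(−β·τ) · V(s_first)`; when
several patch types exist, `V(s_first)` is their equiprobable mixture. ITC
episodes end in a gate state whose successor is the expectation over the 12
equiprobable larger-later configurations (3 rewards × 4 delays) of the next
episode, so values include all future episodes.

### Candidate mechanisms

All non-discounting variants run the recursion at the near-undiscounted
baseline rate β = .001/s and add one mechanism:

| variant | mechanism | free parameters |
|---|---|---|
| `mvt` | none (rate-maximizing reference) | — |
| `cost` | leave aversion: Q(leave) − c | c ≥ 0 |
| `util_pwr` / `util_crra` | concave utility of state rewards, R^η or (R^(1−η)−1)/(1−η) | η ∈ (0,1) |
| `post_del` / `post_del_pwr` | post-reward delays perceived as α·T or T^α | α ∈ (0,1) |
| `pre_del` | pre-reward delays (handling, travel, ITC delays) perceived as α·T | α > 1 |
| `disc_exp` | exponential discounting | β |
| `disc_hyp` | hyperbolic discounting via 10 muAgents | k |
| `disc_cs` | constant sensitivity: every duration enters as T^α | β, α |
| `disc_quasi` | two exponential systems, ω·e^(−βt) + (1−ω)·e^(−δt) | β > δ, ω |

Each rat additionally carries a decision-noise scale σ, so every model has
two subject-level parameters except constant sensitivity (three) and
quasi-hyperbolic (four).

The hyperbolic model averages ten exponential "muAgents" whose rates are
the 5%, 15%, …, 95% quantiles of an exponential distribution with rate 1/k;
the bank's mean discount approximates 1/(1+kt), exactly 0.5 at kt = 1, and
stays within 0.02 discount units of the closed form for kt ≤ 10 (the
relative error grows to ≈4.5% by kt = 10 — an intrinsic property of the
10-point quantile approximation). Hyperbolic and quasi-hyperbolic values
are solved per component system — each exponential system runs its own
recursion and its own max — and combined as the weighted sum of component
Q-values.

Interpretive choices the recursion itself does not fix: concave utility
applies to states that deliver reward (a zero reward keeps zero utility —
applying CRRA literally to R = 0 would act as a per-state cost); distorted
reward-state durations preserve the delivered volume (the rate is rescaled);
the episode gate is treated as unlearned transit and is not distorted by the
pre-delay model; Q(leave) discounts only the travel time, per the stated
recursion, while staying discounts the decision time.

### Solving the values

Within a chain the recursion is a backward pass; the only cycle runs through
`Q(leave)` (or the episode gate). `value_iteration(..., method="anchored")`
compiles each chain into per-decision segments (accumulated discounted
reward `c` and end-to-end discount `d`, so an action is worth `c + d·V`),
then solves the scalar anchor fixed point by Steffensen-accelerated
iteration — the map is a monotone piecewise-linear contraction, so the
acceleration is exact within each linear piece. Convergence is measured
relative to value magnitude (tolerance 1e−10 by default, 1e−9 inside
likelihood evaluations) because values scale like 1/β. A classic
synchronous-sweep solver (`method="sweep"`, capped at 1e5 sweeps, residual
trajectory recorded) is kept as an independent route to the same fixed
point and is cross-checked in the tests.

Chains are truncated at the first zero-reward harvest plus two extra
zero-reward trials; staying at the final decision state loops through a
zero-reward block (value `max(Q(leave), 0)` in the limit), and residual
probability of staying beyond the truncation goes to a tail bucket in the
likelihood.

### MVT predictions and the harvest-count convention

Rate-maximizing behavior is the β → 0 limit, computed at β = .001 with no
decision noise; the patch is abandoned at the first decision state with
`Q(stay, s) ≤ Q(leave)`. The recorded *harvest count* is that state's index
minus one — the crossing state's harvest is not taken. Policies whose
long-run reward rates differ by less than ≈0.1% are not resolved by the
β = .001 approximation (the residual discounting biases the threshold by
that order); the test-suite oracle treats such near-ties as equivalent.

### Choice likelihoods

Foraging uses a patch-level threshold-noise rule: once per patch the leave
threshold is drawn as `Q(leave)·(1 + ε)`, ε ~ N(0, σ²), so the cumulative
probability of having left by state n is
`1 − Φ((Q(stay,n) − Q(leave)) / (σ·|Q(leave)|))`. Because the threshold is
fixed within a patch, "left by n" is equivalent to the threshold exceeding
the running minimum of the stay values, which is exactly the running-max
rectification of the cumulative probabilities — so the analytic distribution
equals the generative first-crossing process even for non-monotone value
profiles. Observed harvest counts map to leave states as h → state h + 1,
with the (typically negligible) mass of leaving before the first harvest
merged into h = 1 since every recorded patch visit contains at least one
harvest. Per-observation probabilities are floored at 1e−12.

ITC choices are probit in the value difference with magnitude-scaled noise:
`p(LL) = 1 − Φ((Q_SS − Q_LL) / √(σ²·(Q_SS² + Q_LL²)))` — independent
Gaussian value representations with SD σ·|Q| each. Both rules are invariant
to a common positive rescaling of all values, which makes σ comparable
across conditions. Only free-choice trials enter the ITC likelihood; the
forced block shapes values through the chain structure. One-trial-horizon
variants replace chain values with the closed forms e^(−βd)·r, r/(1+kd),
e^(−βd^α)·r and [ω·e^(−βd)+(1−ω)·e^(−δd)]·r, and exist only for the ITC
task.

## Hierarchical fitting

Parameters are fit on an unconstrained scale: log for rates, the cost, and
σ; logit for ω, η and the bounded α; log(α−1) for the pre-delay exponent;
and the quasi-hyperbolic fast rate as log(β−δ) so β > δ is enforced and the
two systems cannot swap labels. EM alternates per-subject MAP estimation
under a diagonal Gaussian group prior (L-BFGS-B, bounds ±30 on the
transformed scale, 5 random starts on the first iteration and warm starts
afterwards — the default in `em_fit` is 3 starts, which profiling showed
reaches the same optima on these problems) with group updates: the mean of
subject MAPs, and a variance that adds the mean inverse posterior curvature
(central finite-difference Hessians, relative step 1e−4; non-positive
curvature is repaired to the nearest positive-definite matrix and flagged).
EM stops when the group mean moves less than 1e−2 (transformed scale) or
after 30 iterations.

Model evidence uses the Laplace approximation per subject,
`log p(D_i|θ_i) + log p(θ_i|θ) + (d/2)·log 2π − ½·log det H_i`, summed over
subjects, and models are compared by the group-level criterion
`iBIC = −log p(D|θ) + (k/2)·log n` with k = 2 × (subject-level parameters)
group-level quantities (a mean and a variance each) and n the number of
likelihood observations (patches, or free-choice trials). Lower is better;
both parameter counts are recorded on the fit result.

Cross-task generalization splits each task's data into three folds
(patches/episodes round-robin within condition), fits the quasi-hyperbolic
discount parameters by per-rat maximum likelihood on two thirds of one
task, refits only σ on the other task's training folds (the two tasks have
different noise structures), and compares held-out negative log-likelihoods
summed over the three rotations; a positive difference means the
foraging-fit discount function explained the held-out data better.

## The synthetic cohort generator

The generator emulates the structure of trial-by-trial behavioral tables:
per-patch foraging records and per-trial ITC records, with per-rat mean
state durations kept in a sidecar file. Defaults follow the study design:
8 rats; the five foraging experiments' environments (three patch types of
60/90/120 uL in the travel-time experiment, harvest-trial durations held
constant by adjusting the ITI except in the post-reward-delay experiment);
20-trial ITC episodes with a balanced 10-trial forced block and uniformly
drawn LL configuration; condition order counterbalanced across rats.
Observation counts default to 200 patches and 120 episodes per condition,
inside the ranges reported for the tasks (87–236 patches, 590–2810 free
choices per condition per rat).

Per-rat parameters are Gaussian on the transformed scale around group means
(fast rate 0.5/s, slow rate 0.005/s, fast weight 0.3, noise 0.15 for the
quasi-hyperbolic default) with SD 0.25; mean decision times are lognormal
around 1 s (log-SD 0.1); reward is consumed at 20 uL/s (so the largest
120 uL reward takes 6 s); the episode-gate nose poke takes 1 s; the base
ITC post-reward delay is 10 s, and in the constant-rate condition delay +
ITI is held at 16 s for both options. Behavior is sampled from the model's
own rules — one threshold draw per patch, Bernoulli probit choices per free
trial — so the generator and the likelihood are exact mirrors; this is
verified by Monte-Carlo equivalence tests. What the generator does *not*
emulate: within-session nonstationarity (satiety, motivation), trial-by-trial
duration variability entering the values (the constant-duration assumption
is shared with the fitted models), lapses, and side biases. Passing
recovery tests therefore demonstrates correctness of the pipeline under the
model's own assumptions, not robustness to real-data violations of them.

## Known limitations

- **Quasi-hyperbolic identifiability on foraging data.** All within-patch
  delays span several seconds, where a fast system with β ≳ 0.2/s is nearly
  saturated; a distinct (δ, β, ω, σ) combination attains a better likelihood
  than the generative truth even at ~12,000 patches. δ, ω and σ recover
  well; the fast rate does not. This is the model's geometry, not an
  optimizer failure (truth-initialized EM drifts to the same optimum), and
  it is why cross-task validation matters for this model.
- **Finite-sample ridges.** The post-delay-distortion model shows an α–σ
  ridge whose hierarchical optimum can sit a few group-SEs from the
  generative values at 200 patches/condition even though the large-sample
  MLE is consistent; recovery checks at that size are marginal for this
  model.
- **One-trial quasi fits.** The slow rate is not identifiable from 1–6 s
  delays under a one-trial horizon, so horizon comparisons of the
  quasi-hyperbolic discount factors are weakly determined in simulation.
- **Mixed-model backends.** Linear mixed models use REML via statsmodels
  MixedLM; the ITC logistic GLMM uses a MAP/Laplace binomial mixed model.
  Degrees-of-freedom and p-value conventions are backend-specific and are
  reported as such; condition factors default to sum-to-zero ±½ coding
  (intercept = cross-condition mean), with treatment coding available for
  sensitivity checks.
- **Recovery-study design.** Recovery simulations pair each mechanism with
  the environment that identifies it best (exponential discounting and
  quasi-hyperbolic with the scale experiment, subjective cost with travel
  time, post-delay distortion with the handling-time experiment); the
  generative values are the package defaults listed above, with α = 0.7 for
  the post-delay model (below ≈0.5 its likelihood is one-sidedly flat at
  these data sizes).
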
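"""State valuation under candidate discounting / bias models, and MVT limits.

The value of staying in state ``s`` is the discounted reward earned during
the state plus the discounted value of its successor,

    Q(stay, s) = R(stay, s) + gamma(stay, s) * V(s_next),
    R(stay, s) = (1 - exp(-beta * T(s))) / beta * r(s),
    gamma(stay, s) = exp(-beta * T(s)),

with constant state durations T(s) and within-state reward rate r(s).  The
value of leaving a patch is the travel-discounted value of the first state of
a replenished patch, Q(leave) = exp(-beta * tau) * V(s_first).  Candidate
models modify this recursion: a subjective cost subtracted from Q(leave),
concave reward utility, linear/power distortion of pre- or post-reward
delays, or genuine temporal discounting (exponential, hyperbolic via a bank
of exponential "muAgents", constant-sensitivity, quasi-hyperbolic).

Undiscounted long-run reward-rate maximization (the Marginal Value Theorem)
is the beta -> 0 limit; it is computed at beta = .001 with no decision noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .task import NEXT_EPISODE, NEXT_PATCH, SemiMarkovChain

__all__ = [
    "BASE_BETA",
    "ValuationSpec",
    "MuAgentBank",
    "ValueTable",
    "discounted_state_reward",
    "state_discount",
    "reward_utility",
    "distort_time",
    "apply_subjective_cost",
    "muagent_bank",
    "value_iteration",
    "mvt_prediction",
    "constant_sensitivity_values",
    "quasi_hyperbolic_values",
    "one_trial_itc_values",
]

#: discount rate (1/s) used for the near-undiscounted MVT limit and as the
#: baseline rate of the non-discounting models
BASE_BETA = 1e-3

VARIANTS = (
    "mvt",
    "cost",
    "util_pwr",
    "util_crra",
    "pre_del",
    "post_del",
    "post_del_pwr",
    "disc_exp",
    "disc_hyp",
    "disc_cs",
    "disc_quasi",
)

#: model labels as used in figures/configs <-> internal variant names
VARIANT_LABELS = {
    "cost": "cost",
    "util_pwr": "util-pwr",
    "util_crra": "util-crra",
    "pre_del": "pre-del",
    "post_del": "post-del",
    "post_del_pwr": "post-del-pwr",
    "disc_exp": "disc-exp",
    "disc_hyp": "disc-hyp",
    "disc_cs": "disc-cs",
    "disc_quasi": "disc-quasi",
    "mvt": "mvt",
}
LABEL_TO_VARIANT = {v: k for k, v in VARIANT_LABELS.items()}

_POST_DELAY_LABELS = frozenset({"iti", "ss_iti", "ll_iti"})
_PRE_DELAY_LABELS = frozenset({"handling", "travel", "ss_delay", "ll_delay"})

#: free model parameters per variant (decision noise sigma is separate)
FREE_PARAMS = {
    "mvt": (),
    "cost": ("cost_c",),
    "util_pwr": ("eta",),
    "util_crra": ("eta",),
    "pre_del": ("alpha",),
    "post_del": ("alpha",),
    "post_del_pwr": ("alpha",),
    "disc_exp": ("beta",),
    "disc_hyp": ("k_hyp",),
    "disc_cs": ("beta", "alpha"),
    "disc_quasi": ("beta", "delta", "omega"),
}


@dataclass(frozen=True)
class ValuationSpec:
    """Which model variant to evaluate, with its parameters.

    Rates ``beta``/``delta``/``k_hyp`` are in 1/s; ``alpha`` is the
    time-distortion (or constant-sensitivity) exponent; ``cost_c`` is in
    value units (uL-equivalents); ``eta`` the utility curvature; ``omega``
    the weight of the fast system in the quasi-hyperbolic mixture.  The
    ``horizon`` distinguishes the all-future recursion from the one-trial
    closed forms used only for the ITC task.
    """

    variant: str
    beta: float | None = None
    k_hyp: float | None = None
    alpha: float | None = None
    cost_c: float | None = None
    eta: float | None = None
    omega: float | None = None
    delta: float | None = None
    horizon: str = "all_future"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.horizon not in ("all_future", "one_trial"):
            raise ValueError(f"unknown horizon {self.horizon!r}")
        needed = set(FREE_PARAMS[self.variant])
        for name in ("beta", "k_hyp", "alpha", "cost_c", "eta", "omega", "delta"):
            v = getattr(self, name)
            if name in needed:
                if v is None:
                    raise ValueError(f"{self.variant}: parameter {name} required")
            elif v is not None:
                raise ValueError(f"{self.variant}: unexpected parameter {name}")
        if self.beta is not None and self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.delta is not None and self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.variant == "disc_quasi" and self.beta <= self.delta:
            raise ValueError("quasi-hyperbolic requires beta > delta")
        if self.k_hyp is not None and self.k_hyp <= 0:
            raise ValueError("k_hyp must be > 0")
        # boundary weights are degenerate single-system models; allowed here,
        # excluded during fitting by the logit transform
        if self.omega is not None and not (0 <= self.omega <= 1):
            raise ValueError("omega must lie in [0, 1]")
        if self.cost_c is not None and self.cost_c < 0:
            raise ValueError("cost_c must be >= 0")
        if self.variant in ("util_pwr", "util_crra") and not (0 < self.eta < 1):
            raise ValueError("eta must lie in (0, 1)")
        if self.variant == "pre_del" and not self.alpha >= 1:
            raise ValueError("pre-delay overestimation requires alpha >= 1")
        if self.variant in ("post_del", "post_del_pwr") and not (0 < self.alpha <= 1):
            raise ValueError("post-delay underestimation requires alpha in (0, 1]")
        if self.variant == "disc_cs" and not self.alpha > 0:
            raise ValueError("constant-sensitivity exponent alpha must be > 0")

    @property
    def free_params(self) -> tuple[str, ...]:
        return FREE_PARAMS[self.variant]


@dataclass(frozen=True)
class MuAgentBank:
    """Exponential rates of the 10 muAgents approximating hyperbolic discounting."""

    betas_i: tuple[float, ...]
    weights: tuple[float, ...]

    def discount(self, t):
        """Mean discount of the bank at delay t; approximates 1/(1 + k t)."""
        t = np.asarray(t, dtype=float)
        b = np.array(self.betas_i)
        w = np.array(self.weights)
        return np.exp(-np.multiply.outer(t, b)) @ w


def muagent_bank(k_hyp: float, n_agents: int = 10) -> MuAgentBank:
    """Rates at the 5%, 15%, ..., 95% quantiles of Exp(rate 1/k).

    Averaging exponential discounts exp(-beta_i t) over beta_i ~ Exp(1/k)
    yields exactly 1/(1 + k t); the 10-point quantile bank approximates it,
    and is exact (0.5) at k*t = 1 by the symmetry of the quantiles.
    """
    if k_hyp <= 0:
        raise ValueError("k_hyp must be > 0")
    q = (np.arange(n_agents) + 0.5) / n_agents
    betas = tuple(-k_hyp * np.log1p(-q))
    return MuAgentBank(betas_i=betas, weights=(1.0 / n_agents,) * n_agents)


# ---------------------------------------------------------------------------
# elementary operations


def discounted_state_reward(reward_rate: float, duration_s: float, beta: float) -> float:
    """Reward earned during a state, discounted within the state:
    (1 - exp(-beta T)) / beta * r.  Continuous at beta -> 0 (limit r*T)."""
    if beta <= 0:
        raise ValueError("beta must be > 0 (use BASE_BETA for the MVT limit)")
    if duration_s < 0:
        raise ValueError("duration must be >= 0")
    return -math.expm1(-beta * duration_s) / beta * reward_rate


def state_discount(duration_s: float, beta: float) -> float:
    """gamma(stay, s) = exp(-beta * T(s))."""
    return math.exp(-beta * duration_s)


def reward_utility(reward_value, eta: float, form: str = "power"):
    """Concave utility of a (state) reward: R^eta or CRRA (R^(1-eta)-1)/(1-eta)."""
    r = np.asarray(reward_value, dtype=float)
    if np.any(r < 0):
        raise ValueError("reward must be >= 0")
    if form == "power":
        if not 0 < eta <= 1:
            raise ValueError("power utility requires eta in (0, 1]")
        out = r**eta
    elif form == "crra":
        if eta == 1:
            raise ValueError("CRRA utility undefined at eta = 1 (use log form)")
        if eta > 1 and np.any(r == 0):
            raise ValueError("CRRA utility diverges at R = 0 for eta > 1")
        out = (r ** (1 - eta) - 1) / (1 - eta)
    else:
        raise ValueError(f"unknown utility form {form!r}")
    return out.item() if np.isscalar(reward_value) else out


def distort_time(duration_s, alpha: float, variant: str):
    """Perceived duration under a time-distortion variant.

    ``post_linear``: alpha*T with 0 < alpha <= 1 (post-reward underestimation);
    ``post_power``: T^alpha, same bounds; ``pre_linear``: alpha*T with
    alpha >= 1 (pre-reward overestimation).
    """
    t = np.asarray(duration_s, dtype=float)
    if variant in ("post_linear", "post_power"):
        if not 0 < alpha <= 1:
            raise ValueError("post-delay distortion requires alpha in (0, 1]")
        out = alpha * t if variant == "post_linear" else t**alpha
    elif variant == "pre_linear":
        if not alpha >= 1:
            raise ValueError("pre-delay distortion requires alpha >= 1")
        out = alpha * t
    else:
        raise ValueError(f"unknown distortion variant {variant!r}")
    return out.item() if np.isscalar(duration_s) else out


def apply_subjective_cost(q_leave: float, cost_c: float) -> float:
    """Q_cost(leave) = -c + gamma(leave) * V(s_first)."""
    if cost_c < 0:
        raise ValueError("cost_c must be >= 0")
    return q_leave - cost_c


def effective_duration(label: str, duration_s: float, spec: ValuationSpec) -> float:
    """State duration as perceived under the spec's time-distortion, if any."""
    if spec.variant == "post_del" and label in _POST_DELAY_LABELS:
        return spec.alpha * duration_s
    if spec.variant == "post_del_pwr" and label in _POST_DELAY_LABELS:
        return duration_s**spec.alpha
    if spec.variant == "pre_del" and label in _PRE_DELAY_LABELS:
        return spec.alpha * duration_s
    if spec.variant == "disc_cs":
        return duration_s**spec.alpha
    return duration_s


def _components(spec: ValuationSpec) -> list[tuple[float, float]]:
    """(weight, exponential rate) of each component discount system."""
    if spec.variant == "disc_hyp":
        bank = muagent_bank(spec.k_hyp)
        return list(zip(bank.weights, bank.betas_i))
    if spec.variant == "disc_quasi":
        return [(spec.omega, spec.beta), (1 - spec.omega, spec.delta)]
    if spec.variant in ("disc_exp", "disc_cs"):
        return [(1.0, spec.beta)]
    return [(1.0, BASE_BETA)]


def _state_reward(state, beta: float, spec: ValuationSpec, t_eff: float) -> float:
    """Within-state discounted reward, preserving total volume under
    time distortion, with concave utility applied to reward states."""
    vol = state.reward_rate_ul_per_s * state.duration_s
    if vol <= 0:
        return 0.0
    if t_eff <= 0:
        r = vol
    else:
        r = vol * (-math.expm1(-beta * t_eff)) / (beta * t_eff)
    if spec.variant == "util_pwr":
        r = reward_utility(r, spec.eta, "power")
    elif spec.variant == "util_crra":
        r = reward_utility(r, spec.eta, "crra")
    return r


# ---------------------------------------------------------------------------
# compiled chain segments

# A compiled chain maps each decision index to {action: (c, d, target)} where
# the action's value is c + d * V(target), target being the next decision
# index, "anchor" (the cross-chain linkage), or the decision itself.  The
# walk through each action's segment of non-decision states is extracted
# once per chain and cached; compiling for a given (rate, spec) is then a
# handful of vectorized operations.


def _chain_segments(chain: SemiMarkovChain):
    cached = chain.meta.get("_segments")
    if cached is not None:
        return cached
    dec_index = {sid: i for i, sid in enumerate(chain.decision_ids)}
    rows = []  # (dec, action, labels, durs, vols, target)
    for i, sid in enumerate(chain.decision_ids):
        dec = chain.states[sid]
        for action, nxt in dec.successors.items():
            include_decision_state = not (chain.kind == "foraging" and action == "leave")
            labels, durs, vols = [], [], []
            if include_decision_state:
                labels.append(dec.label)
                durs.append(dec.duration_s)
                vols.append(0.0)
            cur = nxt
            while True:
                if cur in (NEXT_PATCH, NEXT_EPISODE):
                    target = ("anchor", None)
                    break
                if cur in dec_index:
                    target = ("dec", dec_index[cur])
                    break
                st = chain.states[cur]
                labels.append(st.label)
                durs.append(st.duration_s)
                vols.append(st.reward_rate_ul_per_s * st.duration_s)
                cur = st.successors["advance"]
            rows.append((i, action, labels, durs, vols, target))
    # pad segments to a common length; zero-duration zero-volume states are
    # exact no-ops (discount 1, reward 0), so padding does not alter values
    width = max(len(r[3]) for r in rows)
    s = len(rows)
    dur = np.zeros((s, width))
    vol = np.zeros((s, width))
    post = np.zeros((s, width), dtype=bool)
    pre = np.zeros((s, width), dtype=bool)
    for j, (_, _, labels, durs, vols, _) in enumerate(rows):
        dur[j, : len(durs)] = durs
        vol[j, : len(vols)] = vols
        post[j, : len(labels)] = [l in _POST_DELAY_LABELS for l in labels]
        pre[j, : len(labels)] = [l in _PRE_DELAY_LABELS for l in labels]
    segments = {
        "dec": [r[0] for r in rows],
        "action": [r[1] for r in rows],
        "target": [r[5] for r in rows],
        "dur": dur,
        "vol": vol,
        "post": post,
        "pre": pre,
    }
    chain.meta["_segments"] = segments
    return segments


def _compile_chain(chain: SemiMarkovChain, beta: float, spec: ValuationSpec):
    """Per decision index: {action: (c, d, target)} so that the action's
    value is c + d * V(target); computed in one vectorized batch."""
    seg = _chain_segments(chain)
    t = seg["dur"]
    v = spec.variant
    # overflow in T**alpha for extreme exponents probed by the optimizer is
    # benign: an infinite perceived duration discounts to exactly zero
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        if v == "post_del":
            t = np.where(seg["post"], spec.alpha * t, t)
        elif v == "post_del_pwr":
            t = np.where(seg["post"], np.where(t > 0, t, 1.0) ** spec.alpha * (t > 0), t)
        elif v == "pre_del":
            t = np.where(seg["pre"], spec.alpha * t, t)
        elif v == "disc_cs":
            t = np.where(t > 0, t, 1.0) ** spec.alpha * (t > 0)
        g = np.exp(-beta * t)
    d = g.prod(axis=1)
    vol = seg["vol"]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(t > 0, -np.expm1(-beta * t) / (beta * np.where(t > 0, t, 1.0)), 1.0)
    r = vol * frac
    pos = vol > 0
    if v == "util_pwr" and pos.any():
        r[pos] = reward_utility(r[pos], spec.eta, "power")
    elif v == "util_crra" and pos.any():
        r[pos] = reward_utility(r[pos], spec.eta, "crra")
    prefix = np.ones_like(g)
    prefix[:, 1:] = np.cumprod(g[:, :-1], axis=1)
    c = (prefix * r).sum(axis=1)
    compiled = [dict() for _ in chain.decision_ids]
    for j, (i, action, target) in enumerate(zip(seg["dec"], seg["action"], seg["target"])):
        compiled[i][action] = (float(c[j]), float(d[j]), target)
    return compiled


# ---------------------------------------------------------------------------
# value tables


@dataclass
class ValueTable:
    """Converged values for a chain set under one spec.

    Foraging: ``q_stay[chain_id]`` per decision state, scalar ``q_leave``.
    ITC: ``q_ss``/``q_ll`` per trial (NaN for the unavailable forced action)
    and the episode-gate anchor ``gate_value``.  ``v`` holds decision-state
    values V(s) = max over available actions.  Component systems (muAgents,
    quasi-hyperbolic beta/delta) are kept in ``components``.
    """

    kind: str
    q_leave: float | None = None
    q_stay: dict[str, np.ndarray] = field(default_factory=dict)
    q_ss: dict[str, np.ndarray] = field(default_factory=dict)
    q_ll: dict[str, np.ndarray] = field(default_factory=dict)
    v: dict[str, np.ndarray] = field(default_factory=dict)
    gate_value: float | None = None
    components: list["ValueTable"] | None = None
    weights: tuple[float, ...] | None = None
    residuals: np.ndarray | None = None

    def validate(self) -> None:
        for cid, qs in self.q_stay.items():
            if not np.all(np.isfinite(qs)):
                raise ValueError(f"non-finite Q(stay) in chain {cid}")
            expect = np.maximum(qs, self.q_leave)
            if not np.allclose(self.v[cid], expect, rtol=0, atol=1e-8):
                raise ValueError("V(s) != max(Q(stay,s), Q(leave))")


class ValueIterationError(RuntimeError):
    def __init__(self, msg, residual=None):
        super().__init__(msg)
        self.residual = residual


def _fixed_point(g, x0: float, tol: float, max_rounds: int = 200) -> float:
    """Fixed point of a monotone, piecewise-linear contraction by Steffensen
    acceleration (exact within each linear piece)."""
    x = x0
    for _ in range(max_rounds):
        x1 = g(x)
        # relative tolerance: values can reach ~1/delta for tiny slow rates,
        # where an absolute criterion is below float resolution
        if abs(x1 - x) < tol * (1.0 + abs(x1)):
            return x1
        x2 = g(x1)
        denom = x2 - 2 * x1 + x
        if denom != 0:
            xs = x - (x1 - x) ** 2 / denom
            x = xs if math.isfinite(xs) else x2
        else:
            x = x2
    raise ValueIterationError(
        "anchor fixed point did not converge", residual=abs(g(x) - x)
    )


def _solve_foraging_component(chains, beta, spec, tol):
    compiled = [_compile_chain(ch, beta, spec) for ch in chains]
    cost = spec.cost_c if spec.variant == "cost" else 0.0
    stay = []
    g_leaves = []
    for comp in compiled:
        stay.append(
            (
                np.array([comp[i]["stay"][0] for i in range(len(comp))]),
                np.array([comp[i]["stay"][1] for i in range(len(comp))]),
            )
        )
        # gamma(leave): discount over the travel state only
        g_leaves.append(comp[0]["leave"][1])
    g_leave = float(np.mean(g_leaves))

    def backward(q):
        v_first, q_stays, v_all = [], [], []
        for cs, ds in stay:
            n = len(cs)
            v = np.empty(n)
            qs = np.empty(n)
            # terminal self-loop: staying forever in the depleted patch
            stay_loop = cs[-1] / (1 - ds[-1]) if ds[-1] < 1 else math.inf
            v[-1] = max(q, stay_loop)
            qs[-1] = cs[-1] + ds[-1] * v[-1]
            for i in range(n - 2, -1, -1):
                qs[i] = cs[i] + ds[i] * v[i + 1]
                v[i] = max(q, qs[i])
            v_first.append(v[0])
            q_stays.append(qs)
            v_all.append(v)
        return float(np.mean(v_first)), q_stays, v_all

    def g(q):
        # equiprobable mixture over patch types for the replenished patch
        vf, _, _ = backward(q)
        return -cost + g_leave * vf

    q_leave = _fixed_point(g, 0.0, tol)
    _, q_stays, v_all = backward(q_leave)
    table = ValueTable(kind="foraging", q_leave=q_leave)
    for ch, qs, v in zip(chains, q_stays, v_all):
        table.q_stay[ch.chain_id] = qs
        table.v[ch.chain_id] = v
    return table


def _solve_itc_component(chains, beta, spec, tol):
    n_chains = len(chains)
    forced = chains[0].meta["forced_actions"]
    n_forced = len(forced)
    n_trials = chains[0].n_decisions
    # per-trial (c, d) arrays across chains; forced trials mirror the single
    # available action into both slots and are masked afterwards
    c_ss = np.zeros((n_trials, n_chains))
    d_ss = np.zeros((n_trials, n_chains))
    c_ll = np.zeros((n_trials, n_chains))
    d_ll = np.zeros((n_trials, n_chains))
    for k, ch in enumerate(chains):
        comp = _compile_chain(ch, beta, spec)
        for t in range(n_trials):
            if t < n_forced:
                c, d, _ = comp[t]["advance"]
                c_ss[t, k] = c_ll[t, k] = c
                d_ss[t, k] = d_ll[t, k] = d
            else:
                c_ss[t, k], d_ss[t, k], _ = comp[t]["SS"]
                c_ll[t, k], d_ll[t, k], _ = comp[t]["LL"]
    free = np.arange(n_trials) >= n_forced
    forced_is_ll = np.array(
        [a == "LL" for a in forced] + [False] * (n_trials - n_forced)
    )

    def backward(x):
        qss = np.empty((n_trials, n_chains))
        qll = np.empty((n_trials, n_chains))
        vv = np.empty((n_trials, n_chains))
        v_next = np.full(n_chains, x)
        for t in range(n_trials - 1, -1, -1):
            qss[t] = c_ss[t] + d_ss[t] * v_next
            qll[t] = c_ll[t] + d_ll[t] * v_next
            vv[t] = np.maximum(qss[t], qll[t]) if free[t] else qss[t]
            v_next = vv[t]
        return vv, qss, qll

    def g(x):
        # the episode gate's successor is the expectation over configurations;
        # the gate state itself lies inside the trial-20 segment, so the
        # anchor is the configuration-mean first-decision value
        vv, _, _ = backward(x)
        return float(np.mean(vv[0]))

    x = _fixed_point(g, 0.0, tol)
    vv, qss, qll = backward(x)
    # mask out the unavailable action on forced trials
    qss[~free & forced_is_ll] = np.nan
    qll[~free & ~forced_is_ll] = np.nan
    gate = chains[0].states["episode_gate"]
    tg = effective_duration(gate.label, gate.duration_s, spec)
    table = ValueTable(kind="itc", gate_value=math.exp(-beta * tg) * x)
    for k, ch in enumerate(chains):
        table.q_ss[ch.chain_id] = qss[:, k]
        table.q_ll[ch.chain_id] = qll[:, k]
        table.v[ch.chain_id] = vv[:, k]
    return table


def _combine(tables, weights, kind):
    if len(tables) == 1:
        out = tables[0]
        out.components = None
        out.weights = None
        return out
    w = np.asarray(weights)
    out = ValueTable(kind=kind, components=tables, weights=tuple(weights))
    if kind == "foraging":
        out.q_leave = float(np.dot(w, [t.q_leave for t in tables]))
        for cid in tables[0].q_stay:
            qs = np.tensordot(w, [t.q_stay[cid] for t in tables], axes=1)
            out.q_stay[cid] = qs
            out.v[cid] = np.maximum(qs, out.q_leave)
    else:
        out.gate_value = float(np.dot(w, [t.gate_value for t in tables]))
        for cid in tables[0].q_ss:
            out.q_ss[cid] = np.tensordot(w, [t.q_ss[cid] for t in tables], axes=1)
            out.q_ll[cid] = np.tensordot(w, [t.q_ll[cid] for t in tables], axes=1)
            with np.errstate(invalid="ignore"):
                out.v[cid] = np.fmax(out.q_ss[cid], out.q_ll[cid])
    return out


def value_iteration(
    chains: list[SemiMarkovChain],
    spec: ValuationSpec,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    method: str = "anchored",
) -> ValueTable:
    """Converged state values for a set of linked chains under ``spec``.

    ``method='anchored'`` solves the cross-chain fixed point (Q(leave) for
    foraging, the episode-gate value for ITC) by root finding over exact
    within-chain backward induction.  ``method='sweep'`` runs classic
    synchronous value-iteration sweeps over the full state graph and records
    the residual trajectory; both converge to the same fixed point.

    Hyperbolic (muAgent) and quasi-hyperbolic models are solved per component
    exponential system — each with its own recursion and max — and combined
    as the weighted sum of component values.
    """
    if not chains:
        raise ValueError("no chains")
    kind = chains[0].kind
    if spec.horizon != "all_future":
        raise ValueError("value_iteration applies to all-future-horizon specs")
    solve_one = _solve_foraging_component if kind == "foraging" else _solve_itc_component
    tables, weights = [], []
    for w, b in _components(spec):
        if method == "sweep":
            tables.append(_sweep_component(chains, b, spec, tol, max_iter))
        else:
            tables.append(solve_one(chains, b, spec, tol))
        weights.append(w)
    return _combine(tables, weights, kind)


def _sweep_component(chains, beta, spec, tol, max_iter):
    """Synchronous value-iteration sweeps over the explicit state graph.

    Kept as an independent route to the same fixed point as the anchored
    solver; slower, but it exposes the residual trajectory.
    """
    kind = chains[0].kind
    cost = spec.cost_c if spec.variant == "cost" else 0.0
    ids = [(ci, sid) for ci, ch in enumerate(chains) for sid in ch.states]
    index = {key: i for i, key in enumerate(ids)}
    v = np.zeros(len(ids))
    residuals = []
    for sweep in range(max_iter):
        first_mean = np.mean([v[index[(ci, ch.first_decision)]] for ci, ch in enumerate(chains)])
        v_new = np.empty_like(v)
        for i, (ci, sid) in enumerate(ids):
            ch = chains[ci]
            st = ch.states[sid]
            t_eff = effective_duration(st.label, st.duration_s, spec)
            r = _state_reward(st, beta, spec, t_eff)
            g = math.exp(-beta * t_eff)
            vals = []
            for action, nxt in st.successors.items():
                if kind == "foraging" and action == "leave":
                    # Q(leave): travel discount only, no decision-time discount
                    travel = ch.states[nxt]
                    tt = effective_duration(travel.label, travel.duration_s, spec)
                    vals.append(-cost + math.exp(-beta * tt) * first_mean)
                elif nxt in (NEXT_PATCH, NEXT_EPISODE):
                    vals.append(r + g * first_mean)
                else:
                    vals.append(r + g * v[index[(ci, nxt)]])
            v_new[i] = max(vals) if vals else r
        resid = float(np.max(np.abs(v_new - v)))
        residuals.append(resid)
        v = v_new
        if resid < tol:
            break
    else:
        raise ValueIterationError(
            f"value iteration did not converge in {max_iter} sweeps", residual=resid
        )
    table = ValueTable(kind=kind, residuals=np.array(residuals))
    first_mean = np.mean([v[index[(ci, ch.first_decision)]] for ci, ch in enumerate(chains)])
    if kind == "foraging":
        travel = chains[0].states["travel"]
        tt = effective_duration(travel.label, travel.duration_s, spec)
        table.q_leave = -cost + math.exp(-beta * tt) * first_mean
        for ci, ch in enumerate(chains):
            qs = []
            for sid in ch.decision_ids:
                st = ch.states[sid]
                t_eff = effective_duration(st.label, st.duration_s, spec)
                g = math.exp(-beta * t_eff)
                qs.append(g * v[index[(ci, st.successors["stay"])]])
            table.q_stay[ch.chain_id] = np.array(qs)
            table.v[ch.chain_id] = np.maximum(table.q_stay[ch.chain_id], table.q_leave)
    else:
        forced = chains[0].meta["forced_actions"]
        for ci, ch in enumerate(chains):
            qss = np.full(ch.n_decisions, np.nan)
            qll = np.full(ch.n_decisions, np.nan)
            for t, sid in enumerate(ch.decision_ids):
                st = ch.states[sid]
                t_eff = effective_duration(st.label, st.duration_s, spec)
                g = math.exp(-beta * t_eff)
                for action, nxt in st.successors.items():
                    q = g * v[index[(ci, nxt)]]
                    a = forced[t] if action == "advance" else action
                    if a == "SS":
                        qss[t] = q
                    else:
                        qll[t] = q
            table.q_ss[ch.chain_id] = qss
            table.q_ll[ch.chain_id] = qll
            with np.errstate(invalid="ignore"):
                table.v[ch.chain_id] = np.fmax(qss, qll)
        gate = chains[0].states["episode_gate"]
        tg = effective_duration(gate.label, gate.duration_s, spec)
        table.gate_value = math.exp(-beta * tg) * first_mean
    return table


# ---------------------------------------------------------------------------
# predictions


def mvt_prediction(chains: list[SemiMarkovChain], tol: float = 1e-10) -> dict:
    """Optimal (long-run rate maximizing) harvest count per patch type.

    Computed as the near-undiscounted limit: values at beta = .001 with no
    decision noise.  The patch is abandoned at the first decision state at
    which Q(stay, s) <= Q(leave); the harvest count is that state's index
    minus one (the crossing state's harvest is not taken).
    """
    table = value_iteration(chains, ValuationSpec("mvt"), tol=tol)
    return optimal_harvests(table, chains)


def optimal_harvests(table: ValueTable, chains) -> dict:
    out = {}
    for ch in chains:
        qs = table.q_stay[ch.chain_id]
        below = np.nonzero(qs <= table.q_leave + 1e-12)[0]
        n_leave = int(below[0]) + 1 if below.size else len(qs) + 1
        out[ch.meta.get("patch_type", ch.chain_id)] = n_leave - 1
    return out


def constant_sensitivity_values(chains, beta, alpha, tol=1e-10) -> ValueTable:
    """Exponential recursion with every duration replaced by T^alpha."""
    return value_iteration(chains, ValuationSpec("disc_cs", beta=beta, alpha=alpha), tol=tol)


def quasi_hyperbolic_values(chains, beta, delta, omega, tol=1e-10) -> ValueTable:
    """Weighted sum of a fast (beta) and slow (delta) exponential system."""
    return value_iteration(
        chains, ValuationSpec("disc_quasi", beta=beta, delta=delta, omega=omega), tol=tol
    )


def one_trial_itc_values(reward_ul: float, delay_s: float, spec: ValuationSpec) -> float:
    """Discounted value of one option under the one-trial-horizon ITC models."""
    if spec.horizon != "one_trial":
        raise ValueError("spec.horizon must be 'one_trial'")
    r, d = reward_ul, delay_s
    if spec.variant == "disc_exp":
        return math.exp(-spec.beta * d) * r
    if spec.variant == "disc_hyp":
        return r / (1 + spec.k_hyp * d)
    if spec.variant == "disc_cs":
        return math.exp(-spec.beta * d**spec.alpha) * r
    if spec.variant == "disc_quasi":
        w = spec.omega
        return (w * math.exp(-spec.beta * d) + (1 - w) * math.exp(-spec.delta * d)) * r
    raise ValueError(f"one-trial horizon is defined for discounting models, not {spec.variant!r}")
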
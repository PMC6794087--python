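"""Synthetic rat cohorts generated from the valuation models themselves.

The generator mirrors the structure of trial-by-trial behavioral tables:
per-patch foraging records (rat, experiment, condition, patch type, patch
index, harvest count) and per-trial intertemporal-choice records (rat,
condition, episode, trial, forced flag, LL reward/delay, choice).  Each rat
receives parameters sampled from a Gaussian group distribution on the
unconstrained fit scale and mean state durations with small lognormal
jitter around the cohort means; behavior is then sampled from the model's
own generative rules — a patchwise noisy leave threshold for foraging, and
per-trial magnitude-scaled probit choices for ITC.

Defaults follow the study design: 8 rats per cohort, three patch types in
the travel-time environment, 20-trial episodes with 10 forced trials, and
per-condition observation counts inside the ranges seen in the task
(87-236 patches; 590-2810 free choices, i.e. 59-281 episodes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import parameter_transform, spec_and_noise
from .likelihood import SubjectDataset, itc_choice_prob, one_trial_itc_values
from .task import (
    FORAGING_EXPERIMENTS,
    StateDurations,
    enumerate_chains,
    forced_action_schedule,
    itc_environment,
)
from .valuation import value_iteration

__all__ = ["CohortSpec", "simulate_foraging", "simulate_itc", "sample_rats"]


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a synthetic cohort.

    ``group_means`` are natural-scale parameter values (model parameters plus
    ``sigma``); ``group_sds`` are standard deviations on the unconstrained
    fit scale (a dict, or one float applied to every parameter).  Durations:
    per-rat mean decision times are lognormal around ``decision_mean_s`` with
    log-scale spread ``decision_jitter``.
    """

    task: str
    experiment: str
    variant: str = "disc_quasi"
    group_means: dict = field(
        default_factory=lambda: {"beta": 0.5, "delta": 0.005, "omega": 0.3, "sigma": 0.15}
    )
    group_sds: dict | float = 0.25
    n_rats: int = 8
    patches_per_condition: int = 200
    episodes_per_condition: int = 120
    decision_mean_s: float = 1.0
    decision_jitter: float = 0.1
    consumption_ul_per_s: float = 20.0
    gate_s: float = 1.0
    horizon: str = "all_future"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("foraging", "itc"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.n_rats <= 0 or self.patches_per_condition <= 0 or self.episodes_per_condition <= 0:
            raise ValueError("counts must be positive")
        if self.decision_mean_s <= 0:
            raise ValueError("durations must be positive")

    def sd_for(self, name: str) -> float:
        if isinstance(self.group_sds, dict):
            return self.group_sds.get(name, 0.25)
        return float(self.group_sds)


def sample_rats(spec: CohortSpec, rng: np.random.Generator):
    """Per-rat natural parameters and mean state durations."""
    tf = parameter_transform(spec.variant)
    mu = tf.to_unconstrained({n: spec.group_means[n] for n in tf.names})
    sds = np.array([spec.sd_for(n) for n in tf.names])
    rats = []
    for i in range(spec.n_rats):
        x = mu + sds * rng.standard_normal(tf.dim)
        params = tf.to_natural(x)
        decision_s = float(
            np.exp(np.log(spec.decision_mean_s) + spec.decision_jitter * rng.standard_normal())
        )
        durations = StateDurations(
            decision_s=decision_s,
            consumption_ul_per_s=spec.consumption_ul_per_s,
            gate_s=spec.gate_s,
        )
        rats.append({"rat_id": f"rat{i + 1:02d}", "params": params, "durations": durations})
    return rats


def _condition_order(conditions: list[str], rat_index: int) -> list[str]:
    """Counterbalanced condition order across rats (alternating by parity)."""
    return conditions if rat_index % 2 == 0 else conditions[::-1]


def simulate_foraging(spec: CohortSpec) -> list[SubjectDataset]:
    """Sample a foraging cohort from the generative threshold model.

    Per patch, one threshold-noise draw eps ~ N(0, sigma^2) sets the leave
    threshold Q(leave) * (1 + eps); the rat leaves at the first decision
    state whose Q(stay) falls at or below it.  Patch types are drawn
    uniformly (all types are encountered within sessions)."""
    if spec.task != "foraging":
        raise ValueError("spec.task must be 'foraging'")
    rng = np.random.default_rng(spec.seed)
    envs = FORAGING_EXPERIMENTS[spec.experiment]
    conditions = list(envs)
    datasets = []
    for i, rat in enumerate(sample_rats(spec, rng)):
        vspec, noise = spec_and_noise(spec.variant, rat["params"])
        rows = []
        durations = {}
        for cond in _condition_order(conditions, i):
            durations[cond] = rat["durations"]
            chains = enumerate_chains(envs[cond], rat["durations"])
            table = value_iteration(chains, vspec, tol=1e-10)
            q_stays = {ch.meta["patch_type"]: table.q_stay[ch.chain_id] for ch in chains}
            types = [ch.meta["patch_type"] for ch in chains]
            for p in range(1, spec.patches_per_condition + 1):
                ptype = types[rng.integers(len(types))]
                qs = q_stays[ptype]
                threshold = table.q_leave * (1 + noise.sigma * rng.standard_normal())
                below = np.nonzero(qs <= threshold)[0]
                if below.size:
                    # abandon at the crossing state: its harvest is not taken,
                    # but every recorded visit has at least one harvest
                    harvests = max(int(below[0]), 1)
                else:
                    harvests = len(qs)  # stayed past the chain: tail bucket
                rows.append(
                    {
                        "rat": rat["rat_id"],
                        "experiment": spec.experiment,
                        "condition": cond,
                        "patch_type": ptype,
                        "patch_index": p,
                        "harvests": harvests,
                    }
                )
        datasets.append(
            SubjectDataset(
                task="foraging",
                rat_id=rat["rat_id"],
                experiment=spec.experiment,
                observations=pd.DataFrame(rows),
                durations=durations,
            )
        )
    return datasets


def simulate_itc(spec: CohortSpec) -> list[SubjectDataset]:
    """Sample an ITC cohort: per episode a uniformly drawn LL configuration,
    a fixed balanced forced block, then free choices that are Bernoulli in
    the model's magnitude-scaled probit probabilities."""
    if spec.task != "itc":
        raise ValueError("spec.task must be 'itc'")
    rng = np.random.default_rng(spec.seed)
    conditions = ["constant_delay", "constant_rate"]
    datasets = []
    for i, rat in enumerate(sample_rats(spec, rng)):
        vspec, noise = spec_and_noise(spec.variant, rat["params"], horizon=spec.horizon)
        rows = []
        durations = {}
        for cond in _condition_order(conditions, i):
            durations[cond] = rat["durations"]
            env = itc_environment(cond)
            chains = enumerate_chains(env, rat["durations"])
            forced = forced_action_schedule(env.n_forced)
            p_ll = {}  # (reward, delay) -> per-trial P(choose LL)
            if spec.horizon == "one_trial":
                q_ss = one_trial_itc_values(env.ss_reward_ul, env.ss_delay_s, vspec)
                for ch in chains:
                    r, d = ch.meta["ll_reward"], ch.meta["ll_delay"]
                    q_ll = one_trial_itc_values(r, d, vspec)
                    p = itc_choice_prob(q_ss, q_ll, noise.sigma)
                    p_ll[(r, d)] = np.full(env.episode_len, p)
            else:
                table = value_iteration(chains, vspec, tol=1e-10)
                for ch in chains:
                    key = (ch.meta["ll_reward"], ch.meta["ll_delay"])
                    with np.errstate(invalid="ignore"):
                        p_ll[key] = itc_choice_prob(
                            table.q_ss[ch.chain_id], table.q_ll[ch.chain_id], noise.sigma
                        )
            configs = env.configurations
            for ep in range(1, spec.episodes_per_condition + 1):
                r, d = configs[rng.integers(len(configs))]
                for t in range(1, env.episode_len + 1):
                    if t <= env.n_forced:
                        choice = int(forced[t - 1] == "LL")
                        is_forced = True
                    else:
                        choice = int(rng.random() < p_ll[(r, d)][t - 1])
                        is_forced = False
                    rows.append(
                        {
                            "rat": rat["rat_id"],
                            "condition": cond,
                            "episode": ep,
                            "trial": t,
                            "forced": is_forced,
                            "ll_reward": r,
                            "ll_delay": d,
                            "choice": choice,
                        }
                    )
        datasets.append(
            SubjectDataset(
                task="itc",
                rat_id=rat["rat_id"],
                experiment="itc",
                observations=pd.DataFrame(rows),
                durations=durations,
            )
        )
    return datasets
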
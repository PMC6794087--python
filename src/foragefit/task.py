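"""Semi-Markov task structure for patch-foraging and intertemporal-choice experiments.

Both tasks are represented as continuous-time semi-Markov chains: every task
event (cue onset, lever press, reward delivery, inter-trial interval, travel)
occupies a state with a real-valued duration.  Transitions are deterministic
except in decision states, where the animal chooses to stay/leave (foraging)
or between a smaller-sooner (SS) and larger-later (LL) option (ITC).

Chains are built per patch type (foraging) or per LL reward/delay
configuration (ITC); leaving a patch routes through a travel state back to the
first decision state of a replenished patch, and the end of an ITC episode
routes through an ``episode_gate`` state representing the nose poke that
starts the next episode, whose successor is the expectation over all LL
configurations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import yaml

__all__ = [
    "SemiMarkovState",
    "SemiMarkovChain",
    "ForagingEnvironment",
    "ITCEnvironment",
    "StateDurations",
    "build_foraging_chain",
    "build_itc_chain",
    "enumerate_chains",
    "chain_edge_list",
    "environment_from_dict",
    "environment_to_dict",
    "load_environment",
    "FORAGING_EXPERIMENTS",
    "itc_environment",
    "NEXT_PATCH",
    "NEXT_EPISODE",
]

STATE_LABELS = frozenset(
    {
        "decision",
        "handling",
        "reward",
        "iti",
        "travel",
        "ss_delay",
        "ss_reward",
        "ss_iti",
        "ll_delay",
        "ll_reward",
        "ll_iti",
        "episode_gate",
    }
)
REWARD_LABELS = frozenset({"reward", "ss_reward", "ll_reward"})

#: sentinel successor ids resolved across chains by the valuation layer
NEXT_PATCH = "__next_patch__"
NEXT_EPISODE = "__next_episode__"


@dataclass(frozen=True)
class SemiMarkovState:
    """One task event: a label, a duration, a reward rate, and successors.

    ``successors`` maps an action name to the id of the next state.  Decision
    states carry the task's full action set ({stay, leave} or {SS, LL});
    every other state has the single action ``advance``.
    """

    state_id: str
    label: str
    duration_s: float
    reward_rate_ul_per_s: float = 0.0
    successors: dict[str, str] = field(default_factory=dict)
    is_decision: bool = False

    def __post_init__(self) -> None:
        if self.label not in STATE_LABELS:
            raise ValueError(f"unknown state label {self.label!r}")
        if self.duration_s < 0:
            raise ValueError(f"state {self.state_id}: duration {self.duration_s} < 0")
        if self.reward_rate_ul_per_s < 0:
            raise ValueError(f"state {self.state_id}: negative reward rate")
        if self.reward_rate_ul_per_s > 0 and self.label not in REWARD_LABELS:
            raise ValueError(
                f"state {self.state_id}: non-reward label {self.label!r} with "
                "positive reward rate"
            )
        if not self.is_decision and set(self.successors) not in ({"advance"}, set()):
            raise ValueError(
                f"state {self.state_id}: non-decision states must have exactly "
                "the 'advance' action"
            )

    @property
    def reward_ul(self) -> float:
        return self.reward_rate_ul_per_s * self.duration_s


@dataclass
class SemiMarkovChain:
    """An ordered collection of states for one patch type or LL configuration.

    ``decision_ids`` lists decision states in trial order; ``meta`` carries
    chain-level facts (per-trial rewards, the forced-action schedule, ...).
    """

    chain_id: str
    kind: str  # "foraging" | "itc"
    states: dict[str, SemiMarkovState]
    first_decision: str
    decision_ids: list[str]
    meta: dict = field(default_factory=dict)

    def state(self, state_id: str) -> SemiMarkovState:
        return self.states[state_id]

    @property
    def n_decisions(self) -> int:
        return len(self.decision_ids)


# ---------------------------------------------------------------------------
# environments


@dataclass(frozen=True)
class ForagingEnvironment:
    """Parameters of one foraging condition.

    The harvest-trial clock is: decision time + pre-reward delay (handling) +
    reward consumption + ITI.  Under ``iti_rule='fill_to_harvest_time'`` the
    ITI absorbs whatever time remains of ``harvest_time_s``; under
    ``'fixed_post_delay'`` the ITI is always ``fixed_post_delay_s`` and total
    trial time floats.
    """

    start_volumes_ul: tuple[float, ...]
    depletion_ul_per_harvest: float
    pre_reward_delay_s: float
    harvest_time_s: float
    travel_time_s: float
    iti_rule: str = "fill_to_harvest_time"
    fixed_post_delay_s: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "start_volumes_ul", tuple(self.start_volumes_ul))
        if not self.start_volumes_ul or min(self.start_volumes_ul) <= 0:
            raise ValueError("start volumes must be positive")
        if self.depletion_ul_per_harvest <= 0:
            raise ValueError("depletion must be > 0")
        for name in ("pre_reward_delay_s", "harvest_time_s", "travel_time_s", "fixed_post_delay_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.iti_rule not in ("fill_to_harvest_time", "fixed_post_delay"):
            raise ValueError(f"unknown iti_rule {self.iti_rule!r}")


@dataclass(frozen=True)
class ITCEnvironment:
    """Parameters of one intertemporal-choice condition.

    In the ``constant_delay`` condition the post-reward delay (ITI) is the
    same regardless of the chosen option's delay, so longer pre-reward delays
    lower the reward rate.  In ``constant_rate`` the ITI shrinks as the
    pre-reward delay grows so that (delay + ITI) is the same for both options.
    """

    condition: str  # "constant_delay" | "constant_rate"
    ss_reward_ul: float = 40.0
    ss_delay_s: float = 1.0
    ll_rewards_ul: tuple[float, ...] = (40.0, 80.0, 120.0)
    ll_delays_s: tuple[float, ...] = (1.0, 2.0, 4.0, 6.0)
    episode_len: int = 20
    n_forced: int = 10
    iti_s: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "ll_rewards_ul", tuple(self.ll_rewards_ul))
        object.__setattr__(self, "ll_delays_s", tuple(self.ll_delays_s))
        if self.condition not in ("constant_delay", "constant_rate"):
            raise ValueError(f"unknown ITC condition {self.condition!r}")
        if not (self.episode_len > self.n_forced >= 0):
            raise ValueError("episode_len must exceed n_forced >= 0")
        if self.ss_delay_s <= 0 or min(self.ll_delays_s) <= 0:
            raise ValueError("delays must be > 0")
        if self.ss_reward_ul <= 0 or min(self.ll_rewards_ul) <= 0:
            raise ValueError("rewards must be > 0")

    def iti_for_delay(self, delay_s: float) -> float:
        """Post-reward delay following an option with pre-reward delay ``delay_s``."""
        if self.condition == "constant_delay":
            return self.iti_s
        # constant_rate: delay + ITI fixed at (longest delay + base ITI)
        return self.iti_s + max(self.ll_delays_s) - delay_s

    @property
    def configurations(self) -> list[tuple[float, float]]:
        return [
            (r, d)
            for r, d in itertools.product(self.ll_rewards_ul, self.ll_delays_s)
        ]


@dataclass(frozen=True)
class StateDurations:
    """Per-rat mean state durations (seconds).

    Durations the task imposes (handling, ITI rules, travel) come from the
    environment; this type carries the rat-controlled components: mean
    decision time, reward consumption speed, and the episode-gate nose-poke
    latency.  ``travel_s``/``handling_s`` override the environment when the
    measured times differ from the programmed ones.
    """

    decision_s: float = 1.0
    consumption_ul_per_s: float = 20.0
    gate_s: float = 1.0
    travel_s: float | None = None
    handling_s: float | None = None

    def __post_init__(self) -> None:
        if self.decision_s < 0 or self.gate_s < 0:
            raise ValueError("durations must be >= 0")
        if self.consumption_ul_per_s <= 0:
            raise ValueError("consumption rate must be > 0")
        for name in ("travel_s", "handling_s"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")

    def consumption_time(self, volume_ul: float) -> float:
        return volume_ul / self.consumption_ul_per_s if volume_ul > 0 else 0.0


# ---------------------------------------------------------------------------
# chain construction


def patch_trial_rewards(
    start_volume_ul: float, depletion_ul: float, n_trials: int
) -> list[float]:
    """Reward volume on harvest trials 1..n: max(0, start - (n-1)*depletion)."""
    return [max(0.0, start_volume_ul - (n - 1) * depletion_ul) for n in range(1, n_trials + 1)]


def _n_max(start_volume_ul: float, depletion_ul: float) -> int:
    # first zero-reward trial plus two extra zero-reward decision states, so
    # the likelihood covers rats staying past depletion
    n = 1
    while start_volume_ul - (n - 1) * depletion_ul > 0:
        n += 1
    return n + 2


def build_foraging_chain(
    env: ForagingEnvironment,
    durations: StateDurations,
    patch_type: float,
    n_max: int | None = None,
) -> SemiMarkovChain:
    """Build the harvest-trial chain for one patch type (starting volume).

    Each harvest trial n contributes a decision -> handling -> reward -> ITI
    block; the reward on trial n is max(0, start - (n-1)*depletion).  The
    ``leave`` action transitions from any decision state to the travel state,
    whose successor is the (cross-chain) first decision state of a replenished
    patch.  Staying at the final decision state loops through a zero-reward
    block back to itself.
    """
    if patch_type not in env.start_volumes_ul:
        raise ValueError(
            f"unknown patch type {patch_type!r}; expected one of {env.start_volumes_ul}"
        )
    if n_max is None:
        n_max = _n_max(patch_type, env.depletion_ul_per_harvest)
    rewards = patch_trial_rewards(patch_type, env.depletion_ul_per_harvest, n_max)
    handling_s = (
        durations.handling_s if durations.handling_s is not None else env.pre_reward_delay_s
    )
    travel_s = durations.travel_s if durations.travel_s is not None else env.travel_time_s

    states: dict[str, SemiMarkovState] = {}
    decision_ids: list[str] = []
    travel_id = "travel"
    states[travel_id] = SemiMarkovState(
        travel_id, "travel", travel_s, successors={"advance": NEXT_PATCH}
    )
    for n, vol in enumerate(rewards, start=1):
        dec = f"dec_{n}"
        hand = f"handling_{n}"
        rew = f"reward_{n}"
        iti = f"iti_{n}"
        consume_s = durations.consumption_time(vol)
        if env.iti_rule == "fill_to_harvest_time":
            iti_s = env.harvest_time_s - durations.decision_s - handling_s - consume_s
            if iti_s < 0:
                raise ValueError(
                    f"state {iti}: computed ITI {iti_s:.3f} s < 0 (decision + handling "
                    f"+ consumption exceed harvest time {env.harvest_time_s} s)"
                )
        else:
            iti_s = env.fixed_post_delay_s
        next_dec = f"dec_{n + 1}" if n < n_max else dec  # final block loops on itself
        states[dec] = SemiMarkovState(
            dec,
            "decision",
            durations.decision_s,
            successors={"stay": hand, "leave": travel_id},
            is_decision=True,
        )
        states[hand] = SemiMarkovState(hand, "handling", handling_s, successors={"advance": rew})
        rate = vol / consume_s if vol > 0 else 0.0
        states[rew] = SemiMarkovState(
            rew, "reward", consume_s, reward_rate_ul_per_s=rate, successors={"advance": iti}
        )
        states[iti] = SemiMarkovState(iti, "iti", iti_s, successors={"advance": next_dec})
        decision_ids.append(dec)

    return SemiMarkovChain(
        chain_id=f"patch_{patch_type:g}",
        kind="foraging",
        states=states,
        first_decision="dec_1",
        decision_ids=decision_ids,
        meta={
            "patch_type": patch_type,
            "rewards_ul": rewards,
            "n_max": n_max,
            "env": env,
            "durations": durations,
        },
    )


def forced_action_schedule(n_forced: int) -> list[str]:
    """Fixed balanced forced-trial order: strict alternation for the first
    block, then a counterbalanced ABBA tail, giving equal SS/LL counts."""
    if n_forced % 2:
        raise ValueError("n_forced must be even for a balanced schedule")
    head = ["SS", "LL"] * max(0, (n_forced - 4) // 2)
    tail = ["LL", "SS", "SS", "LL"] if n_forced >= 4 else ["SS", "LL"] * (n_forced // 2)
    return (head + tail)[:n_forced]


def build_itc_chain(
    env: ITCEnvironment,
    durations: StateDurations,
    ll_reward: float,
    ll_delay: float,
) -> SemiMarkovChain:
    """Build one 20-trial episode chain for a given LL configuration.

    Each trial is decision -> (SS or LL) delay -> reward -> ITI -> next
    decision.  The first ``n_forced`` trials carry a single fixed action; the
    final trial's ITI leads to the episode gate whose successor is the
    expectation over all LL configurations of the next episode.
    """
    if ll_reward not in env.ll_rewards_ul or ll_delay not in env.ll_delays_s:
        raise ValueError(
            f"configuration ({ll_reward}, {ll_delay}) outside the environment grid"
        )
    forced = forced_action_schedule(env.n_forced)
    states: dict[str, SemiMarkovState] = {}
    decision_ids: list[str] = []
    gate_id = "episode_gate"
    states[gate_id] = SemiMarkovState(
        gate_id, "episode_gate", durations.gate_s, successors={"advance": NEXT_EPISODE}
    )

    branch_spec = {
        "SS": (env.ss_reward_ul, env.ss_delay_s, "ss"),
        "LL": (ll_reward, ll_delay, "ll"),
    }
    for t in range(1, env.episode_len + 1):
        dec = f"dec_{t}"
        is_forced = t <= env.n_forced
        next_dec = f"dec_{t + 1}" if t < env.episode_len else gate_id
        succ: dict[str, str] = {}
        actions = [forced[t - 1]] if is_forced else ["SS", "LL"]
        for a in actions:
            vol, delay_s, pref = branch_spec[a]
            d_id, r_id, i_id = (f"{pref}_delay_{t}", f"{pref}_reward_{t}", f"{pref}_iti_{t}")
            consume_s = durations.consumption_time(vol)
            rate = vol / consume_s if vol > 0 else 0.0
            states[d_id] = SemiMarkovState(
                d_id, f"{pref}_delay", delay_s, successors={"advance": r_id}
            )
            states[r_id] = SemiMarkovState(
                r_id,
                f"{pref}_reward",
                consume_s,
                reward_rate_ul_per_s=rate,
                successors={"advance": i_id},
            )
            states[i_id] = SemiMarkovState(
                i_id, f"{pref}_iti", env.iti_for_delay(delay_s), successors={"advance": next_dec}
            )
            succ["advance" if is_forced else a] = d_id
        states[dec] = SemiMarkovState(
            dec,
            "decision",
            durations.decision_s,
            successors=succ,
            is_decision=not is_forced,
        )
        decision_ids.append(dec)

    return SemiMarkovChain(
        chain_id=f"ll_{ll_reward:g}ul_{ll_delay:g}s",
        kind="itc",
        states=states,
        first_decision="dec_1",
        decision_ids=decision_ids,
        meta={
            "ll_reward": ll_reward,
            "ll_delay": ll_delay,
            "forced_actions": forced,
            "env": env,
            "durations": durations,
        },
    )


def enumerate_chains(
    env: ForagingEnvironment | ITCEnvironment, durations: StateDurations
) -> list[SemiMarkovChain]:
    """All chains of an environment: one per patch type or per LL configuration."""
    if isinstance(env, ForagingEnvironment):
        return [build_foraging_chain(env, durations, v) for v in env.start_volumes_ul]
    if isinstance(env, ITCEnvironment):
        return [build_itc_chain(env, durations, r, d) for r, d in env.configurations]
    raise TypeError(f"unsupported environment type {type(env).__name__}")


def chain_edge_list(chain: SemiMarkovChain) -> list[str]:
    """Plain-text edge list (``state -action-> successor``) for inspection."""
    lines = []
    for sid in sorted(chain.states):
        s = chain.states[sid]
        for action, nxt in sorted(s.successors.items()):
            lines.append(
                f"{sid}\t{action}\t{nxt}\tT={s.duration_s:.3f}\tr={s.reward_rate_ul_per_s:.3f}"
            )
    return lines


# ---------------------------------------------------------------------------
# experiment definitions

# The five foraging experiments: condition -> environment.  Rewards in uL,
# times in seconds.  In the post-reward-delay experiment the trial length is
# not controlled; the ITI is fixed instead.
FORAGING_EXPERIMENTS: dict[str, dict[str, ForagingEnvironment]] = {
    "travel_time": {
        "10s": ForagingEnvironment((60, 90, 120), 8, 0, 10, 10),
        "30s": ForagingEnvironment((60, 90, 120), 8, 0, 10, 30),
    },
    "depletion_rate": {
        "8uL": ForagingEnvironment((90,), 8, 0, 12, 12),
        "16uL": ForagingEnvironment((90,), 16, 0, 12, 12),
    },
    "scale": {
        "90uL_10s": ForagingEnvironment((90,), 8, 0, 10, 10),
        "180uL_20s": ForagingEnvironment((180,), 16, 0, 20, 20),
    },
    "handling_time": {
        "0s": ForagingEnvironment((90,), 8, 0, 15, 15),
        "3s": ForagingEnvironment((90,), 8, 3, 15, 15),
    },
    "post_reward_delay": {
        "3s": ForagingEnvironment(
            (90,), 8, 0, 0, 10, iti_rule="fixed_post_delay", fixed_post_delay_s=3
        ),
        "12s": ForagingEnvironment(
            (90,), 8, 0, 0, 10, iti_rule="fixed_post_delay", fixed_post_delay_s=12
        ),
    },
}


def itc_environment(condition: str, **kwargs) -> ITCEnvironment:
    return ITCEnvironment(condition=condition, **kwargs)


# ---------------------------------------------------------------------------
# config serialization


def environment_to_dict(env: ForagingEnvironment | ITCEnvironment) -> dict:
    if isinstance(env, ForagingEnvironment):
        return {
            "task": "foraging",
            "start_rewards": list(env.start_volumes_ul),
            "depletion": env.depletion_ul_per_harvest,
            "pre_delay": env.pre_reward_delay_s,
            "harvest_time": env.harvest_time_s,
            "travel_time": env.travel_time_s,
            "iti_rule": env.iti_rule,
            "fixed_post_delay": env.fixed_post_delay_s,
        }
    return {
        "task": "itc",
        "condition": env.condition,
        "ss_reward": env.ss_reward_ul,
        "ss_delay": env.ss_delay_s,
        "ll_rewards": list(env.ll_rewards_ul),
        "ll_delays": list(env.ll_delays_s),
        "episode_len": env.episode_len,
        "n_forced": env.n_forced,
        "iti": env.iti_s,
    }


def environment_from_dict(d: dict) -> ForagingEnvironment | ITCEnvironment:
    task = d.get("task", "foraging")
    if task == "foraging":
        return ForagingEnvironment(
            start_volumes_ul=tuple(d["start_rewards"]),
            depletion_ul_per_harvest=d["depletion"],
            pre_reward_delay_s=d["pre_delay"],
            harvest_time_s=d["harvest_time"],
            travel_time_s=d["travel_time"],
            iti_rule=d.get("iti_rule", "fill_to_harvest_time"),
            fixed_post_delay_s=d.get("fixed_post_delay", 0.0),
        )
    if task == "itc":
        return ITCEnvironment(
            condition=d["condition"],
            ss_reward_ul=d.get("ss_reward", 40.0),
            ss_delay_s=d.get("ss_delay", 1.0),
            ll_rewards_ul=tuple(d.get("ll_rewards", (40.0, 80.0, 120.0))),
            ll_delays_s=tuple(d.get("ll_delays", (1.0, 2.0, 4.0, 6.0))),
            episode_len=d.get("episode_len", 20),
            n_forced=d.get("n_forced", 10),
            iti_s=d.get("iti", 10.0),
        )
    raise ValueError(f"unknown task {task!r}")


def load_environment(path) -> ForagingEnvironment | ITCEnvironment:
    with open(path) as fh:
        return environment_from_dict(yaml.safe_load(fh))
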
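"""Trial-level choice probabilities and dataset log-likelihoods.

Foraging uses a patch-level threshold-noise rule: the leave threshold
Q(leave) * (1 + eps), eps ~ N(0, sigma^2), is drawn once per patch, so the
cumulative probability of having left by decision state n is

    pi(leave, n) = 1 - Phi((Q(stay, n) - Q(leave)) / (sigma * |Q(leave)|)).

The ITC task uses a magnitude-scaled probit: option values are represented
as independent Gaussians with SD sigma * |Q|, and

    p(LL) = 1 - Phi((Q(SS) - Q(LL)) / sqrt(sigma^2 * (Q(SS)^2 + Q(LL)^2))).

Both noise rules scale with value magnitude, making likelihoods invariant to
a common positive rescaling of all values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .task import StateDurations
from .valuation import ValuationSpec, ValueTable, one_trial_itc_values, value_iteration

__all__ = [
    "NoiseSpec",
    "PatchLeaveDistribution",
    "SubjectDataset",
    "patch_leave_distribution",
    "harvest_count_probs",
    "foraging_loglik",
    "itc_choice_prob",
    "itc_loglik",
    "foraging_dataset_loglik",
    "itc_dataset_loglik",
    "FORAGING_COLUMNS",
    "ITC_COLUMNS",
]

#: per-observation probability floor keeping optimization finite
LIK_FLOOR = 1e-12

FORAGING_COLUMNS = ["rat", "experiment", "condition", "patch_type", "patch_index", "harvests"]
ITC_COLUMNS = ["rat", "condition", "episode", "trial", "forced", "ll_reward", "ll_delay", "choice"]


@dataclass(frozen=True)
class NoiseSpec:
    """Decision-noise scale sigma (dimensionless, relative to value magnitude)."""

    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass
class PatchLeaveDistribution:
    """Probabilities of leaving at decision state n = 1..n_max, plus the
    tail mass of staying past n_max.  Sums to 1."""

    per_n: np.ndarray
    tail: float
    cumulative: np.ndarray

    @property
    def n_max(self) -> int:
        return len(self.per_n)

    def prob(self, n: int) -> float:
        """Mass at leave state n; observations beyond n_max get the tail."""
        if n < 1:
            raise ValueError("leave state must be >= 1")
        return float(self.per_n[n - 1]) if n <= self.n_max else self.tail


@dataclass
class SubjectDataset:
    """One rat's observations for one task and experiment.

    Foraging observations: one row per patch visit with columns
    rat, experiment, condition, patch_type, patch_index, harvests.
    ITC observations: one row per trial with columns
    rat, condition, episode, trial, forced, ll_reward, ll_delay, choice
    (choice 1 = LL, 0 = SS; forced trials keep the imposed action).
    ``durations`` holds the per-condition mean state durations used to build
    this rat's chains.
    """

    task: str
    rat_id: str
    experiment: str
    observations: pd.DataFrame
    durations: dict[str, StateDurations] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.task not in ("foraging", "itc"):
            raise ValueError(f"unknown task {self.task!r}")
        cols = FORAGING_COLUMNS if self.task == "foraging" else ITC_COLUMNS
        missing = [c for c in cols if c not in self.observations.columns]
        if missing:
            raise ValueError(f"observations missing required columns: {missing}")
        if self.task == "foraging" and (self.observations["harvests"] < 1).any():
            raise ValueError("harvest counts must be >= 1")

    @property
    def conditions(self) -> list[str]:
        return sorted(self.observations["condition"].unique())

    def free_choices(self) -> pd.DataFrame:
        """ITC free-choice trials — the likelihood observations."""
        if self.task != "itc":
            raise ValueError("free_choices applies to ITC datasets")
        return self.observations[~self.observations["forced"].astype(bool)]

    @property
    def n_obs(self) -> int:
        """Number of likelihood observations (patches, or free-choice trials)."""
        if self.task == "foraging":
            return len(self.observations)
        return len(self.free_choices())


# ---------------------------------------------------------------------------
# foraging likelihood


def patch_leave_distribution(
    q_stay: np.ndarray, q_leave: float, sigma: float, n_max: int | None = None
) -> PatchLeaveDistribution:
    """Leave-state distribution under the patchwise threshold-noise rule.

    The cumulative leave-by-n probabilities are rectified to be
    non-decreasing (running max) before differencing, which only matters for
    non-monotone Q(stay) sequences under exotic parameters; residual mass
    beyond n_max goes to the tail bucket.
    """
    if q_leave == 0:
        raise ValueError("q_leave = 0: the magnitude-scaled noise degenerates")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    q_stay = np.asarray(q_stay, dtype=float)
    if n_max is not None:
        q_stay = q_stay[:n_max]
    z = (q_stay - q_leave) / (sigma * abs(q_leave))
    cumulative = norm.sf(z)
    cumulative = np.maximum.accumulate(cumulative)
    per_n = np.diff(cumulative, prepend=0.0)
    tail = 1.0 - cumulative[-1]
    return PatchLeaveDistribution(per_n=per_n, tail=tail, cumulative=cumulative)


def harvest_count_probs(dist: PatchLeaveDistribution) -> np.ndarray:
    """Map the leave-state distribution onto observable harvest counts.

    A patch abandoned at decision state n yielded n - 1 harvests; the small
    mass of leaving before the first harvest is merged into h = 1 (every
    recorded patch visit has at least one harvest).  Index j holds P(h = j+1)
    for h = 1..n_max-1; counts >= n_max take the remaining (tail) mass.
    """
    per_n = dist.per_n
    probs = per_n[1:].copy()
    probs[0] += per_n[0]
    return probs


def foraging_loglik(
    observations: pd.DataFrame,
    table: ValueTable,
    noise: NoiseSpec,
    chain_for_patch: dict | None = None,
    floor: float = LIK_FLOOR,
) -> float:
    """Sum over patches of the log leave-distribution mass at the observed
    harvest count, patch type matched to its chain."""
    if chain_for_patch is None:
        chain_for_patch = {cid: cid for cid in table.q_stay}
    ll = 0.0
    for patch_type, grp in observations.groupby("patch_type", sort=False):
        cid = chain_for_patch[patch_type]
        dist = patch_leave_distribution(table.q_stay[cid], table.q_leave, noise.sigma)
        probs = harvest_count_probs(dist)
        tail = dist.tail + 0.0
        counts = grp["harvests"].to_numpy(dtype=int)
        p = np.where(
            counts < dist.n_max,
            probs[np.clip(counts, 1, dist.n_max - 1) - 1],
            tail,
        )
        ll += float(np.sum(np.log(np.maximum(p, floor))))
    return ll


# ---------------------------------------------------------------------------
# ITC likelihood


def itc_choice_prob(q_ss, q_ll, sigma: float):
    """P(choose LL): probit of the value difference with variance
    sigma^2 * (Q_SS^2 + Q_LL^2) (independent magnitude-scaled Gaussians)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    q_ss = np.asarray(q_ss, dtype=float)
    q_ll = np.asarray(q_ll, dtype=float)
    denom2 = sigma**2 * (q_ss**2 + q_ll**2)
    if np.any(denom2 == 0):
        raise ValueError("both option values are zero: choice probability undefined")
    p = norm.sf((q_ss - q_ll) / np.sqrt(denom2))
    return p.item() if p.ndim == 0 else p


def itc_loglik(
    observations: pd.DataFrame,
    tables: dict[tuple[float, float], tuple[np.ndarray, np.ndarray]],
    noise: NoiseSpec,
    floor: float = LIK_FLOOR,
) -> float:
    """Bernoulli log-likelihood of free choices.

    ``tables`` maps (ll_reward, ll_delay) to per-trial (q_ss, q_ll) arrays
    indexed by trial number 1..episode_len; only free-choice rows of
    ``observations`` contribute.
    """
    free = observations[~observations["forced"].astype(bool)]
    ll = 0.0
    for (r, d), grp in free.groupby(["ll_reward", "ll_delay"], sort=False):
        q_ss, q_ll = tables[(r, d)]
        idx = grp["trial"].to_numpy(dtype=int) - 1
        p_ll = itc_choice_prob(q_ss[idx], q_ll[idx], noise.sigma)
        p_ll = np.clip(p_ll, floor, 1 - floor)
        y = grp["choice"].to_numpy(dtype=float)
        ll += float(np.sum(y * np.log(p_ll) + (1 - y) * np.log(1 - p_ll)))
    return ll


# ---------------------------------------------------------------------------
# dataset-level assembly (chains prebuilt once per rat and condition)


def foraging_dataset_loglik(
    dataset: SubjectDataset,
    chain_sets: dict[str, list],
    spec: ValuationSpec,
    noise: NoiseSpec,
    tol: float = 1e-9,
) -> float:
    """Log-likelihood of a rat's foraging observations across conditions.

    ``chain_sets`` maps condition -> prebuilt chains (one per patch type).
    """
    ll = 0.0
    for cond, grp in dataset.observations.groupby("condition", sort=False):
        chains = chain_sets[cond]
        table = value_iteration(chains, spec, tol=tol)
        mapping = {ch.meta["patch_type"]: ch.chain_id for ch in chains}
        ll += foraging_loglik(grp, table, noise, chain_for_patch=mapping)
    return ll


def itc_dataset_loglik(
    dataset: SubjectDataset,
    chain_sets: dict[str, list],
    spec: ValuationSpec,
    noise: NoiseSpec,
    tol: float = 1e-9,
) -> float:
    """Log-likelihood of a rat's ITC free choices across conditions.

    All-future specs solve the linked episode chains; one-trial specs use the
    closed-form option values (identical across trials and conditions).
    """
    ll = 0.0
    for cond, grp in dataset.observations.groupby("condition", sort=False):
        chains = chain_sets[cond]
        env = chains[0].meta["env"]
        n_trials = chains[0].n_decisions
        tables = {}
        if spec.horizon == "one_trial":
            q_ss_val = one_trial_itc_values(env.ss_reward_ul, env.ss_delay_s, spec)
            for ch in chains:
                r, d = ch.meta["ll_reward"], ch.meta["ll_delay"]
                q_ll_val = one_trial_itc_values(r, d, spec)
                tables[(r, d)] = (
                    np.full(n_trials, q_ss_val),
                    np.full(n_trials, q_ll_val),
                )
        else:
            table = value_iteration(chains, spec, tol=tol)
            for ch in chains:
                tables[(ch.meta["ll_reward"], ch.meta["ll_delay"])] = (
                    table.q_ss[ch.chain_id],
                    table.q_ll[ch.chain_id],
                )
        ll += itc_loglik(grp, tables, noise)
    return ll
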
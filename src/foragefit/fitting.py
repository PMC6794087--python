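"""Hierarchical expectation-maximization fitting and model comparison.

Each rat's parameters (model parameters plus decision noise sigma) are fit
on an unconstrained scale (log for rates/cost/sigma, logit for bounded
parameters) under a diagonal Gaussian group prior.  EM alternates per-subject
MAP estimation (E) with group mean/variance updates (M) that include the
per-subject posterior curvature, following the standard hierarchical
random-effects recipe.  Model evidence is the Laplace-approximated log
marginal likelihood, penalized at the group level by iBIC:

    iBIC = -log p(D | theta) + (k / 2) * log(n),

with k group-level parameters (a mean and a variance per subject-level
parameter) and n likelihood observations (patches, or free-choice trials).
Lower is better.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .likelihood import (
    NoiseSpec,
    SubjectDataset,
    foraging_dataset_loglik,
    itc_dataset_loglik,
)
from .task import FORAGING_EXPERIMENTS, enumerate_chains, itc_environment
from .valuation import FREE_PARAMS, ValuationSpec

__all__ = [
    "ParameterTransform",
    "parameter_transform",
    "FitResult",
    "em_fit",
    "laplace_log_marginal",
    "ibic",
    "compare_models",
    "fit_subject_mle",
    "assign_folds",
    "crossval_cross_task",
    "build_chain_sets",
    "make_subject_nll",
    "default_group_mean",
    "spec_and_noise",
]

_BIG_NLL = 1e10
_VAR_FLOOR = 1e-4

#: default natural-scale parameter values used to seed group means
_DEFAULTS = {
    "beta": 0.3,
    "delta": 0.01,
    "omega": 0.5,
    "k_hyp": 0.5,
    "cost_c": 5.0,
    "eta": 0.7,
    "sigma": 0.2,
}
_ALPHA_DEFAULTS = {"pre_del": 1.5, "post_del": 0.7, "post_del_pwr": 0.7, "disc_cs": 0.7}


@dataclass(frozen=True)
class ParameterTransform:
    """Bijection between natural parameters and the unconstrained fit scale.

    Kinds: ``log`` (positive), ``logit`` (unit interval), ``log_m1``
    (greater than one), ``log_gap`` (positive increment over the previous
    parameter — used to keep the quasi-hyperbolic fast rate above the slow
    rate).  Parameter order matters for ``log_gap``.
    """

    names: tuple[str, ...]
    kinds: tuple[str, ...]

    @property
    def dim(self) -> int:
        return len(self.names)

    def to_unconstrained(self, params: dict) -> np.ndarray:
        x = np.empty(self.dim)
        prev = None
        for j, (name, kind) in enumerate(zip(self.names, self.kinds)):
            v = params[name]
            if kind == "log":
                x[j] = math.log(v)
            elif kind == "logit":
                x[j] = math.log(v / (1 - v))
            elif kind == "log_m1":
                x[j] = math.log(v - 1)
            elif kind == "log_gap":
                x[j] = math.log(v - prev)
            else:
                raise ValueError(kind)
            prev = v
        return x

    def to_natural(self, x) -> dict:
        x = np.asarray(x, dtype=float)
        params: dict[str, float] = {}
        prev = None
        for j, (name, kind) in enumerate(zip(self.names, self.kinds)):
            if kind == "log":
                v = math.exp(x[j])
            elif kind == "logit":
                v = 1 / (1 + math.exp(-x[j]))
            elif kind == "log_m1":
                v = 1 + math.exp(x[j])
            elif kind == "log_gap":
                v = prev + math.exp(x[j])
            params[name] = v
            prev = v
        return params


def parameter_transform(variant: str) -> ParameterTransform:
    """Transform for a model's subject-level parameters (sigma last)."""
    if variant == "disc_quasi":
        # order delta -> beta so the gap transform enforces beta > delta
        return ParameterTransform(
            ("delta", "beta", "omega", "sigma"), ("log", "log_gap", "logit", "log")
        )
    kinds = {
        "beta": "log",
        "k_hyp": "log",
        "cost_c": "log",
        "eta": "logit",
        "sigma": "log",
    }
    if variant == "pre_del":
        kinds["alpha"] = "log_m1"
    elif variant in ("post_del", "post_del_pwr"):
        kinds["alpha"] = "logit"
    else:
        kinds["alpha"] = "log"
    names = tuple(FREE_PARAMS[variant]) + ("sigma",)
    return ParameterTransform(names, tuple(kinds[n] for n in names))


def default_group_mean(variant: str) -> np.ndarray:
    tf = parameter_transform(variant)
    params = {}
    for name in tf.names:
        params[name] = _ALPHA_DEFAULTS[variant] if name == "alpha" else _DEFAULTS[name]
    return tf.to_unconstrained(params)


def spec_and_noise(variant: str, params: dict, horizon: str = "all_future"):
    model_params = {k: v for k, v in params.items() if k != "sigma"}
    return (
        ValuationSpec(variant, horizon=horizon, **model_params),
        NoiseSpec(params["sigma"]),
    )


# ---------------------------------------------------------------------------
# per-subject likelihood assembly


def build_chain_sets(dataset: SubjectDataset) -> dict[str, list]:
    """Prebuild the task chains for each condition of a rat's experiment."""
    sets = {}
    for cond in dataset.conditions:
        durations = dataset.durations[cond]
        if dataset.task == "foraging":
            env = FORAGING_EXPERIMENTS[dataset.experiment][cond]
        else:
            env = itc_environment(cond)
        sets[cond] = enumerate_chains(env, durations)
    return sets


def make_subject_nll(
    dataset: SubjectDataset,
    variant: str,
    horizon: str = "all_future",
    observations: pd.DataFrame | None = None,
    vi_tol: float = 1e-9,
):
    """Negative log-likelihood of one rat's data as a function of the
    unconstrained parameter vector.  Chains are prebuilt once; repeated
    evaluations at the same point (finite-difference probes) are cached."""
    chain_sets = build_chain_sets(dataset)
    tf = parameter_transform(variant)
    obs = dataset.observations if observations is None else observations
    ds = SubjectDataset(dataset.task, dataset.rat_id, dataset.experiment, obs, dataset.durations)
    loglik = foraging_dataset_loglik if dataset.task == "foraging" else itc_dataset_loglik
    cache: dict[tuple, float] = {}

    def nll(x) -> float:
        key = tuple(np.round(np.asarray(x, dtype=float), 12))
        if key in cache:
            return cache[key]
        if np.max(np.abs(x)) > 50:  # guards overflow in the transforms
            return _BIG_NLL
        try:
            spec, noise = spec_and_noise(variant, tf.to_natural(x), horizon)
            val = -loglik(ds, chain_sets, spec, noise, tol=vi_tol)
        except (ValueError, RuntimeError, OverflowError):
            val = _BIG_NLL
        if not np.isfinite(val):
            val = _BIG_NLL
        cache[key] = val
        return val

    return nll, tf


def _fd_hessian(fun, x, rel_step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian."""
    x = np.asarray(x, dtype=float)
    d = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    hess = np.empty((d, d))
    f0 = fun(x)
    for j in range(d):
        ej = np.zeros(d)
        ej[j] = h[j]
        hess[j, j] = (fun(x + ej) - 2 * f0 + fun(x - ej)) / h[j] ** 2
        for k in range(j + 1, d):
            ek = np.zeros(d)
            ek[k] = h[k]
            hess[j, k] = hess[k, j] = (
                fun(x + ej + ek) - fun(x + ej - ek) - fun(x - ej + ek) + fun(x - ej - ek)
            ) / (4 * h[j] * h[k])
    return hess


def _nearest_pd(h: np.ndarray, min_eig: float = 1e-6) -> tuple[np.ndarray, bool]:
    h = 0.5 * (h + h.T)
    w, v = np.linalg.eigh(h)
    if np.all(w > min_eig):
        return h, False
    w = np.clip(w, min_eig, None)
    return (v * w) @ v.T, True


# ---------------------------------------------------------------------------
# results


@dataclass
class FitResult:
    """Converged hierarchical fit of one model to one cohort."""

    variant: str
    task: str
    horizon: str
    param_names: tuple[str, ...]
    group_mean: np.ndarray  # transformed scale
    group_var: np.ndarray  # transformed scale
    subject_ids: list[str]
    subject_params: np.ndarray  # (s, d) transformed MAP estimates
    subject_params_natural: list[dict]
    hessians: np.ndarray  # (s, d, d) of the negative log posterior
    subject_loglik: np.ndarray  # log p(D_i | theta_i) at the MAP
    n_obs: int
    n_subjects: int
    converged: bool
    trajectory: list[np.ndarray] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)
    log_marginal: float | None = None
    ibic: float | None = None

    @property
    def n_subject_params(self) -> int:
        return len(self.param_names)

    @property
    def n_group_params(self) -> int:
        # each subject-level parameter has a group mean and a group variance
        return 2 * self.n_subject_params

    def group_mean_natural(self) -> dict:
        tf = parameter_transform(self.variant)
        return tf.to_natural(self.group_mean)

    def group_se(self) -> np.ndarray:
        """Standard error of the group mean: sqrt(group variance / s)."""
        return np.sqrt(self.group_var / self.n_subjects)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "task": self.task,
            "horizon": self.horizon,
            "param_names": list(self.param_names),
            "group_mean": self.group_mean.tolist(),
            "group_var": self.group_var.tolist(),
            "group_mean_natural": self.group_mean_natural(),
            "subject_ids": self.subject_ids,
            "subject_params_natural": self.subject_params_natural,
            "subject_loglik": self.subject_loglik.tolist(),
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "n_subject_params": self.n_subject_params,
            "n_group_params": self.n_group_params,
            "converged": self.converged,
            "flags": self.flags,
            "log_marginal": self.log_marginal,
            "ibic": self.ibic,
        }


# ---------------------------------------------------------------------------
# EM


def _map_objective(nll, mu, var):
    def obj(x):
        pen = 0.5 * np.sum((x - mu) ** 2 / var)
        return nll(x) + pen

    return obj


def _minimize_multistart(obj, starts, maxiter=200):
    # transformed-scale bounds keep flat likelihood directions from running
    # to numerical extremes (e.g. an unidentified slow rate drifting to -inf)
    bounds = [(-30.0, 30.0)] * len(np.atleast_1d(starts[0]))
    best = None
    for x0 in starts:
        res = minimize(obj, x0, method="L-BFGS-B", bounds=bounds, options={"maxiter": maxiter})
        if best is None or res.fun < best.fun:
            best = res
    return best


def em_fit(
    cohort: list[SubjectDataset],
    variant: str,
    seed: int = 0,
    horizon: str = "all_future",
    tol: float = 1e-2,
    max_iter: int = 30,
    n_starts: int = 5,
    vi_tol: float = 1e-9,
    group_var0: float = 0.25,
    prior_disabled: bool = False,
) -> FitResult:
    """Hierarchical EM fit of ``variant`` to a cohort.

    E-step: per-subject MAP on the transformed scale under the Gaussian group
    prior, multi-start quasi-Newton (warm-started after the first iteration),
    with central-finite-difference Hessians.  M-step: group mean is the mean
    of subject MAPs; group variance adds the mean inverse posterior curvature
    (so shrinkage reflects per-subject uncertainty).  ``prior_disabled``
    yields independent per-subject MLEs (flat-prior limit).
    """
    if len(cohort) < 2 and not prior_disabled:
        raise ValueError("hierarchical fitting needs at least 2 subjects")
    task = cohort[0].task
    rng = np.random.default_rng(seed)
    nlls, tf = [], None
    for ds in cohort:
        f, tf = make_subject_nll(ds, variant, horizon=horizon, vi_tol=vi_tol)
        nlls.append(f)
    d = tf.dim
    s = len(cohort)
    mu = default_group_mean(variant)
    var = np.full(d, math.inf if prior_disabled else group_var0)
    theta = np.tile(mu, (s, 1))
    trajectory = [mu.copy()]
    flags: list[str] = []
    converged = False

    for it in range(max_iter):
        use_var = np.where(np.isfinite(var), np.maximum(var, _VAR_FLOOR), np.inf)
        hessians = np.empty((s, d, d))
        for i, nll in enumerate(nlls):
            obj = _map_objective(nll, mu, use_var)
            if it == 0:
                starts = [mu] + [
                    mu + np.sqrt(np.where(np.isfinite(use_var), use_var, 1.0)) * rng.standard_normal(d)
                    for _ in range(n_starts - 1)
                ]
            else:
                starts = [theta[i], mu]
            res = _minimize_multistart(obj, starts)
            theta[i] = res.x
            hessians[i] = _fd_hessian(obj, res.x)
        mu_new = theta.mean(axis=0)
        if not prior_disabled:
            inv_diag = np.empty((s, d))
            for i in range(s):
                h_pd, repaired = _nearest_pd(hessians[i])
                if repaired:
                    flags.append(f"non-PD Hessian repaired: subject {cohort[i].rat_id}")
                inv_diag[i] = np.diag(np.linalg.inv(h_pd))
            var_new = np.maximum(
                (theta**2 + inv_diag).mean(axis=0) - mu_new**2, _VAR_FLOOR
            )
        else:
            var_new = var
        delta_mu = float(np.max(np.abs(mu_new - mu)))
        mu, var = mu_new, var_new
        trajectory.append(mu.copy())
        if delta_mu < tol:
            converged = True
            break
    if not converged:
        flags.append(f"EM did not reach tol={tol} in {max_iter} iterations")

    # final per-subject quantities at the converged prior
    use_var = np.where(np.isfinite(var), np.maximum(var, _VAR_FLOOR), np.inf)
    hessians = np.empty((s, d, d))
    lls = np.empty(s)
    nat = []
    for i, nll in enumerate(nlls):
        obj = _map_objective(nll, mu, use_var)
        res = _minimize_multistart(obj, [theta[i], mu])
        theta[i] = res.x
        h, repaired = _nearest_pd(_fd_hessian(obj, res.x))
        if repaired:
            flags.append(f"final non-PD Hessian repaired: subject {cohort[i].rat_id}")
        hessians[i] = h
        lls[i] = -nll(theta[i])
        nat.append(tf.to_natural(theta[i]))

    return FitResult(
        variant=variant,
        task=task,
        horizon=horizon,
        param_names=tf.names,
        group_mean=mu,
        group_var=var,
        subject_ids=[ds.rat_id for ds in cohort],
        subject_params=theta,
        subject_params_natural=nat,
        hessians=hessians,
        subject_loglik=lls,
        n_obs=sum(ds.n_obs for ds in cohort),
        n_subjects=s,
        converged=converged,
        trajectory=trajectory,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# evidence


def laplace_log_marginal(fit: FitResult) -> float:
    """Laplace approximation to log p(D | group parameters):

    sum_i [ log p(D_i | theta_i) + log p(theta_i | theta)
            + (d/2) log 2 pi - 1/2 log det H_i ],

    H_i the Hessian of the negative log posterior at the subject MAP.
    """
    d = fit.n_subject_params
    if d == 0:
        return float(np.sum(fit.subject_loglik))
    var = np.maximum(fit.group_var, _VAR_FLOOR)
    total = 0.0
    for i in range(fit.n_subjects):
        h = fit.hessians[i]
        sign, logdet = np.linalg.slogdet(h)
        if sign <= 0:
            raise ValueError(f"non-positive-definite Hessian for subject {fit.subject_ids[i]}")
        diff = fit.subject_params[i] - fit.group_mean
        log_prior = -0.5 * float(
            np.sum(diff**2 / var) + np.sum(np.log(2 * math.pi * var))
        )
        total += fit.subject_loglik[i] + log_prior + 0.5 * d * math.log(2 * math.pi) - 0.5 * logdet
    fit.log_marginal = total
    return total


def ibic(fit: FitResult, n: int | None = None) -> float:
    """Group-level BIC: -log p(D | theta) + (k/2) log n; lower is better."""
    if fit.log_marginal is None:
        laplace_log_marginal(fit)
    n = fit.n_obs if n is None else n
    if n <= 0:
        raise ValueError("n must be positive")
    val = -fit.log_marginal + 0.5 * fit.n_group_params * math.log(n)
    fit.ibic = val
    return val


def compare_models(
    cohorts: dict[str, list[SubjectDataset]],
    variants: list[str],
    seed: int = 0,
    horizon: str = "all_future",
    **em_kwargs,
) -> pd.DataFrame:
    """Fit every variant to every experiment's cohort and rank by iBIC.

    ``cohorts`` maps experiment name -> cohort.  Returns a tidy frame with
    one row per (variant, experiment) plus per-variant across-experiment
    sums (experiment = 'total').  All models must see identical observation
    sets; this holds by construction since they share the cohorts.
    """
    counts = {exp: sum(ds.n_obs for ds in cohort) for exp, cohort in cohorts.items()}
    rows = []
    for variant in variants:
        for exp, cohort in cohorts.items():
            fit = em_fit(cohort, variant, seed=seed, horizon=horizon, **em_kwargs)
            if sum(ds.n_obs for ds in cohort) != counts[exp]:
                raise ValueError("observation sets differ between models")
            rows.append(
                {
                    "variant": variant,
                    "experiment": exp,
                    "n_obs": fit.n_obs,
                    "log_marginal": laplace_log_marginal(fit),
                    "ibic": ibic(fit),
                }
            )
    df = pd.DataFrame(rows)
    totals = (
        df.groupby("variant", sort=False)[["n_obs", "log_marginal", "ibic"]]
        .sum()
        .reset_index()
        .assign(experiment="total")
    )
    return pd.concat([df, totals], ignore_index=True)


# ---------------------------------------------------------------------------
# cross-task cross-validation


def fit_subject_mle(
    dataset: SubjectDataset,
    variant: str,
    observations: pd.DataFrame | None = None,
    fixed: dict | None = None,
    seed: int = 0,
    horizon: str = "all_future",
    n_starts: int = 3,
) -> dict:
    """Per-rat maximum-likelihood fit (no group prior); ``fixed`` pins named
    natural-scale parameters (e.g. discount parameters carried across tasks)
    so only the remaining ones — typically sigma — are optimized."""
    nll, tf = make_subject_nll(dataset, variant, horizon=horizon, observations=observations)
    rng = np.random.default_rng(seed)
    fixed = fixed or {}
    free_idx = [j for j, n in enumerate(tf.names) if n not in fixed]
    base = default_group_mean(variant)
    if fixed:
        full_fixed = {n: fixed.get(n) for n in tf.names}
        # fill free slots with defaults so the gap transform stays valid
        defaults = tf.to_natural(base)
        for n in tf.names:
            if full_fixed[n] is None:
                full_fixed[n] = defaults[n]
        base = tf.to_unconstrained(full_fixed)

    def obj(z):
        x = base.copy()
        x[free_idx] = z
        return nll(x)

    starts = [base[free_idx]] + [
        base[free_idx] + 0.5 * rng.standard_normal(len(free_idx)) for _ in range(n_starts - 1)
    ]
    res = _minimize_multistart(obj, starts)
    x = base.copy()
    x[free_idx] = res.x
    params = tf.to_natural(x)
    params["_nll"] = float(res.fun)
    return params


def assign_folds(dataset: SubjectDataset, n_folds: int = 3) -> pd.Series:
    """Round-robin fold labels: by patch index (foraging) or episode (ITC),
    within condition, so folds are balanced and disjoint."""
    if n_folds < 2:
        raise ValueError("cross-validation needs at least 2 folds")
    obs = dataset.observations
    unit = "patch_index" if dataset.task == "foraging" else "episode"
    folds = pd.Series(index=obs.index, dtype=int)
    for _, grp in obs.groupby("condition", sort=False):
        units = pd.unique(grp[unit])
        mapping = {u: i % n_folds for i, u in enumerate(units)}
        folds.loc[grp.index] = grp[unit].map(mapping)
    return folds


def crossval_cross_task(
    forage: SubjectDataset,
    itc: SubjectDataset,
    variant: str = "disc_quasi",
    n_folds: int = 3,
    seed: int = 0,
) -> dict:
    """Cross-task generalization for one rat.

    For each fold rotation, the model's discount parameters are fit by MLE
    to the training folds of each task; to evaluate a discount function on
    the other task only a fresh noise parameter is refit (the two tasks use
    different noise structures).  Held-out negative log-likelihoods are
    summed over rotations and reported as

        nll_diff = (-LL under ITC-fit parameters)
                 - (-LL under foraging-fit parameters),

    per evaluation task; positive means the foraging-fit discount function
    fit better.
    """
    if forage.rat_id != itc.rat_id:
        raise ValueError("datasets must come from the same rat")
    f_folds = assign_folds(forage, n_folds)
    i_folds = assign_folds(itc, n_folds)
    for folds, ds in ((f_folds, forage), (i_folds, itc)):
        sizes = folds.value_counts()
        if len(sizes) != n_folds:
            raise ValueError("degenerate folds: some fold is empty")
    discount_names = [n for n in parameter_transform(variant).names if n != "sigma"]
    out = {"rat_id": forage.rat_id, "nll": {}}
    acc = {
        ("foraging", "own"): 0.0,
        ("foraging", "cross"): 0.0,
        ("itc", "own"): 0.0,
        ("itc", "cross"): 0.0,
    }
    for r in range(n_folds):
        f_train = forage.observations[f_folds != r]
        f_test = forage.observations[f_folds == r]
        i_train = itc.observations[i_folds != r]
        i_test = itc.observations[i_folds == r]
        for train, test in ((f_train, f_test), (i_train, i_test)):
            if len(train.index.intersection(test.index)):
                raise ValueError("fold leakage: shared observations between train and test")
        theta_f = fit_subject_mle(forage, variant, observations=f_train, seed=seed)
        theta_i = fit_subject_mle(itc, variant, observations=i_train, seed=seed)
        disc_f = {n: theta_f[n] for n in discount_names}
        disc_i = {n: theta_i[n] for n in discount_names}
        # refit only the noise parameter on the evaluation task's training folds
        sig_f_on_i = fit_subject_mle(itc, variant, observations=i_train, fixed=disc_f, seed=seed)
        sig_i_on_f = fit_subject_mle(
            forage, variant, observations=f_train, fixed=disc_i, seed=seed
        )
        acc[("foraging", "own")] += _heldout_nll(forage, variant, f_test, theta_f)
        acc[("foraging", "cross")] += _heldout_nll(forage, variant, f_test, sig_i_on_f)
        acc[("itc", "own")] += _heldout_nll(itc, variant, i_test, theta_i)
        acc[("itc", "cross")] += _heldout_nll(itc, variant, i_test, sig_f_on_i)
    out["nll"] = {f"{task}_{kind}": v for (task, kind), v in acc.items()}
    # positive: the foraging-fit discount function explains held-out data better
    out["nll_diff_foraging"] = acc[("foraging", "cross")] - acc[("foraging", "own")]
    out["nll_diff_itc"] = acc[("itc", "own")] - acc[("itc", "cross")]
    return out


def _heldout_nll(dataset, variant, test_obs, params) -> float:
    nll, tf = make_subject_nll(dataset, variant, observations=test_obs)
    x = tf.to_unconstrained({n: params[n] for n in tf.names})
    return nll(x)
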
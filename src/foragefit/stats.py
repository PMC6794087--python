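"""Mixed-effects behavioral analyses of foraging and intertemporal choice.

Harvests per patch are analyzed with linear mixed models (REML, via
statsmodels MixedLM): starting volume and travel time with per-rat random
intercepts and uncorrelated random slopes for the travel-time experiment,
and a condition effect with correlated random intercept/slope for the
two-condition experiments.  The same condition model applied to the
difference between observed harvests and each rat's MVT-optimal count reads
overharvesting directly: an intercept of zero is optimal performance.

ITC choices are analyzed with a mixed-effects logistic regression
(Laplace/MAP fit of a binomial mixed GLM) of P(choose LL) on LL reward, LL
delay, condition and their interactions, with per-rat random intercepts and
uncorrelated random slopes, followed by three post-hoc comparisons (reward
effect per condition, delay effect per condition, between-condition delay
difference) with Holm correction.

Condition factors use sum-to-zero (+-1/2) coding so intercepts are
cross-condition means and condition coefficients are between-condition
differences; LL reward enters in units of 40 uL (the SS magnitude) and LL
delay in seconds.  Degrees-of-freedom and p-value approximations are those
of the statsmodels backend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.stats import chi2
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
from statsmodels.stats.multitest import multipletests

from .likelihood import SubjectDataset
from .task import FORAGING_EXPERIMENTS, enumerate_chains
from .valuation import mvt_prediction

__all__ = [
    "PatchSummary",
    "RegressionResult",
    "harvests_per_patch",
    "mvt_optimal_table",
    "add_difference_from_optimal",
    "fit_travel_lmm",
    "fit_condition_lmm",
    "fit_itc_glmm",
    "posthoc_contrasts",
]

PatchSummary = pd.DataFrame  # one row per patch visit; see harvests_per_patch


@dataclass
class RegressionResult:
    """Tidy fixed-effect estimates from a mixed model."""

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    stat: np.ndarray
    pvalues: np.ndarray
    cov: np.ndarray | None
    random_var: dict
    n_obs: int
    converged: bool
    backend: str
    formula: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef, "se": self.se, "stat": self.stat, "p": self.pvalues},
            index=self.terms,
        )

    def __getitem__(self, term: str) -> float:
        return float(self.coef[self.terms.index(term)])


def _code_condition(values: pd.Series, coding: str = "sum") -> pd.Series:
    """Condition coding over the (two) sorted levels: sum-to-zero +-1/2
    (default; the intercept is the cross-condition mean) or 0/1 treatment
    coding for sensitivity checks."""
    levels = sorted(values.unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 conditions, got {levels}")
    if coding == "sum":
        codes = {levels[0]: -0.5, levels[1]: 0.5}
    elif coding == "treatment":
        codes = {levels[0]: 0.0, levels[1]: 1.0}
    else:
        raise ValueError(f"unknown coding {coding!r}")
    return values.map(codes).astype(float)


# ---------------------------------------------------------------------------
# patch summaries


def harvests_per_patch(data) -> PatchSummary:
    """One row per patch visit with its harvest count.

    Accepts a list of foraging SubjectDatasets, a per-patch table (with a
    ``harvests`` column), or a trial-level table with an ``action`` column
    (stay/leave) from which harvests are counted.  Every patch visit is
    included; a patch with zero harvests is an error.
    """
    if isinstance(data, list):
        df = pd.concat([ds.observations for ds in data], ignore_index=True)
    else:
        df = data.copy()
    if df.empty:
        return pd.DataFrame(
            columns=["rat", "experiment", "condition", "patch_type", "patch_index", "harvests"]
        )
    if "harvests" not in df.columns:
        if "action" not in df.columns:
            raise ValueError("need a 'harvests' or trial-level 'action' column")
        keys = [c for c in ("rat", "experiment", "condition", "patch_type", "patch_index") if c in df.columns]
        df = (
            df.assign(_stay=(df["action"] == "stay").astype(int))
            .groupby(keys, sort=False)["_stay"]
            .sum()
            .rename("harvests")
            .reset_index()
        )
    if (df["harvests"] < 1).any():
        raise ValueError("patch visit with zero harvests")
    cols = [c for c in ("rat", "experiment", "condition", "patch_type", "patch_index", "harvests") if c in df.columns]
    return df[cols].reset_index(drop=True)


def mvt_optimal_table(datasets: list[SubjectDataset]) -> pd.DataFrame:
    """Per rat x condition x patch type MVT-optimal harvest count, using each
    rat's own mean state durations."""
    rows = []
    for ds in datasets:
        envs = FORAGING_EXPERIMENTS[ds.experiment]
        for cond in ds.conditions:
            chains = enumerate_chains(envs[cond], ds.durations[cond])
            for ptype, n_opt in mvt_prediction(chains).items():
                rows.append(
                    {
                        "rat": ds.rat_id,
                        "condition": cond,
                        "patch_type": ptype,
                        "mvt_optimal": n_opt,
                    }
                )
    return pd.DataFrame(rows)


def add_difference_from_optimal(
    summaries: PatchSummary, datasets: list[SubjectDataset]
) -> PatchSummary:
    """Join per-rat MVT predictions; difference = harvests - mvt_optimal."""
    opt = mvt_optimal_table(datasets)
    out = summaries.merge(opt, on=["rat", "condition", "patch_type"], how="left")
    if out["mvt_optimal"].isna().any():
        raise ValueError("missing MVT prediction for some rat/condition/patch type")
    out["difference_from_optimal"] = out["harvests"] - out["mvt_optimal"]
    return out


# ---------------------------------------------------------------------------
# linear mixed models


def _lmm_result(res, formula: str, n_obs: int) -> RegressionResult:
    fe = res.fe_params
    terms = list(fe.index)
    cov = np.asarray(res.cov_params())[: len(terms), : len(terms)]
    random_var = {"group": res.cov_re.to_dict()}
    vcomp = getattr(res, "vcomp", None)
    if vcomp is not None and len(vcomp):
        random_var["vc"] = dict(zip(res.model.exog_vc.names, np.asarray(vcomp)))
    return RegressionResult(
        terms=terms,
        coef=fe.to_numpy(),
        se=res.bse[: len(terms)].to_numpy(),
        stat=res.tvalues[: len(terms)].to_numpy(),
        pvalues=res.pvalues[: len(terms)].to_numpy(),
        cov=cov,
        random_var=random_var,
        n_obs=n_obs,
        converged=bool(res.converged),
        backend="statsmodels MixedLM (REML)",
        formula=formula,
    )


def fit_travel_lmm(summaries: PatchSummary, coding: str = "sum") -> RegressionResult:
    """HarvestsPerPatch ~ StartingVolume * TravelTime with per-rat random
    intercept and uncorrelated random slopes; volume in mL so the slope is
    in trials/mL."""
    df = summaries.copy()
    df["vol_ml"] = df["patch_type"].astype(float) / 1000.0
    df["travel"] = _code_condition(df["condition"], coding)
    formula = "harvests ~ vol_ml * travel"
    model = smf.mixedlm(
        formula,
        df,
        groups=df["rat"],
        re_formula="1",
        vc_formula={"vol_ml": "0 + vol_ml", "travel": "0 + travel"},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True)
    out = _lmm_result(res, formula, len(df))
    if not res.converged:
        out.backend += " [non-converged or singular fit]"
    return out


def fit_condition_lmm(
    summaries: PatchSummary, response: str = "harvests", coding: str = "sum"
) -> RegressionResult:
    """response ~ Condition with correlated per-rat random intercept and
    condition slope.  With ``response='difference_from_optimal'`` the
    intercept measures overharvesting (zero = MVT-optimal)."""
    if response not in ("harvests", "difference_from_optimal"):
        raise ValueError(f"unknown response {response!r}")
    df = summaries.copy()
    df["cond"] = _code_condition(df["condition"], coding)
    formula = f"{response} ~ cond"
    model = smf.mixedlm(formula, df, groups=df["rat"], re_formula="~cond")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True)
    return _lmm_result(res, formula, len(df))


# ---------------------------------------------------------------------------
# ITC mixed-effects logistic regression


def fit_itc_glmm(observations: pd.DataFrame, coding: str = "sum") -> RegressionResult:
    """P(choose LL) ~ RewardLL * DelayLL * Condition with per-rat random
    intercept and uncorrelated random slopes (MAP / Laplace fit).

    Free-choice trials only; reward is coded in units of 40 uL and delay in
    seconds, condition sum-to-zero.
    """
    df = observations.copy()
    if "forced" in df.columns:
        df = df[~df["forced"].astype(bool)].copy()
    if df.empty:
        raise ValueError("no free-choice trials")
    df["reward40"] = df["ll_reward"].astype(float) / 40.0
    df["delay"] = df["ll_delay"].astype(float)
    df["cond"] = _code_condition(df["condition"], coding)
    df["choice"] = df["choice"].astype(int)
    formula = "choice ~ reward40 * delay * cond"
    vc_formulas = {
        "icpt": "0 + C(rat)",
        "rew": "0 + C(rat):reward40",
        "del": "0 + C(rat):delay",
        "cnd": "0 + C(rat):cond",
    }
    model = BinomialBayesMixedGLM.from_formula(formula, vc_formulas, df)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit_map()
    k = model.k_fep
    terms = list(model.fep_names)
    coef = np.asarray(res.params[:k])
    cov = np.asarray(res.cov_params())[:k, :k]
    se = np.sqrt(np.diag(cov))
    z = coef / se
    p = chi2.sf(z**2, df=1)  # Wald chi-square, 1 df
    # separation shows up as exploding coefficients/SEs
    flagged = bool(np.any(np.abs(coef) > 50) or np.any(~np.isfinite(se)))
    return RegressionResult(
        terms=terms,
        coef=coef,
        se=se,
        stat=z,
        pvalues=p,
        cov=cov,
        random_var={
            "vcp_sd": dict(
                zip(model.vcp_names, np.exp(np.asarray(res.params[k : k + model.k_vcp])))
            )
        },
        n_obs=len(df),
        converged=not flagged,
        backend="statsmodels BinomialBayesMixedGLM (MAP/Laplace)"
        + (" [possible separation]" if flagged else ""),
        formula=formula,
    )


def posthoc_contrasts(result: RegressionResult, conditions: tuple[str, str] | None = None) -> pd.DataFrame:
    """The three post-hoc comparisons on the ITC GLMM, Holm-corrected.

    (i) the LL-reward effect within each condition, (ii) the LL-delay effect
    within each condition, (iii) the between-condition difference in the
    LL-delay effect.  With sum-to-zero +-1/2 coding the within-condition
    effect of x in condition c is beta_x + c * beta_{x:cond}.
    """
    if result.cov is None:
        raise ValueError("model must be fitted with a coefficient covariance")
    idx = {t: i for i, t in enumerate(result.terms)}
    k = len(result.terms)

    def lvec(pairs):
        L = np.zeros(k)
        for term, w in pairs:
            L[idx[term]] = w
        return L

    lo, hi = conditions if conditions else ("A", "B")
    rows = [
        ("reward_by_condition", lo, lvec([("reward40", 1), ("reward40:cond", -0.5)])),
        ("reward_by_condition", hi, lvec([("reward40", 1), ("reward40:cond", 0.5)])),
        ("delay_by_condition", lo, lvec([("delay", 1), ("delay:cond", -0.5)])),
        ("delay_by_condition", hi, lvec([("delay", 1), ("delay:cond", 0.5)])),
        ("delay_between_conditions", f"{hi}-{lo}", lvec([("delay:cond", 1)])),
    ]
    recs = []
    for name, cond, L in rows:
        est = float(L @ result.coef)
        se = float(np.sqrt(L @ result.cov @ L))
        stat = (est / se) ** 2
        recs.append(
            {
                "comparison": name,
                "condition": cond,
                "estimate": est,
                "se": se,
                "chi2": stat,
                "p": float(chi2.sf(stat, df=1)),
            }
        )
    out = pd.DataFrame(recs)
    out["p_holm"] = multipletests(out["p"], method="holm")[1]
    return out
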
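"""Hierarchical behavioural statistics for the dot-counting task.

Three families of models, all with random intercepts for animal and for
testing session nested within animal (no random slopes — with four
animals a random slope term is not identifiable):

* the actTime GLM: actTime ~ reward * dotSpeed * ITI (full factorial
  interactions) + previous-trial reward outcome + previous-trial actTime,
  on responded trials;
* the response logit: odds of responding at all from the same present
  context plus 1-back history, on all trials;
* the TUS models: GLM-style tests of how stimulation condition (ACC, BF,
  POp, sham) alters the reward->actTime relationship (interaction model)
  and the |observed - deterministic| actTime bias (main-effect model),
  each followed by planned contrasts.

Gaussian models use :class:`statsmodels.regression.mixed_linear_model.MixedLM`
(ML estimation; omnibus terms by likelihood-ratio chi-square); the
hierarchical logit uses the variational :class:`BinomialBayesMixedGLM`,
falling back to an ordinary GLM when there is no grouping structure.
Reward, dot speed and ITI enter as categorical factors (treatment coding
by default, switchable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from acttime.task import N_BACK

__all__ = [
    "prepare_behavior_table",
    "fit_acttime_glm",
    "fit_response_logit",
    "tus_reward_interaction",
    "tus_bias_model",
    "ContrastResult",
    "MixedModelFit",
    "quadratic_reward_code",
]

TUS_CONDITIONS = ("ACC", "BF", "POp", "sham")


@dataclass
class ContrastResult:
    """One planned contrast: estimate, SE, test statistic and p-value."""

    label: str
    estimate: float
    se: float
    statistic: float
    p: float

    def __post_init__(self):
        if not self.se > 0:
            raise ValueError("contrast SE must be > 0")


@dataclass
class MixedModelFit:
    """A fitted multilevel model plus omnibus and contrast summaries."""

    result: object
    omnibus: pd.DataFrame | None = None
    contrasts: list[ContrastResult] | None = None
    odds_ratios: pd.DataFrame | None = None
    singular: bool = False

    def summary(self):
        return self.result.summary()


def quadratic_reward_code(reward_level: np.ndarray) -> np.ndarray:
    """Centered quadratic contrast over reward levels.

    For the task's three levels this is the classic (+1, -2, +1) code;
    other level sets get a centered squared deviation.
    """
    r = np.asarray(reward_level, dtype=float)
    levels = np.unique(r)
    if set(levels) <= {1.0, 2.0, 3.0}:
        return np.select([r == 1, r == 2, r == 3], [1.0, -2.0, 1.0])
    v = (r - r.mean()) ** 2
    return v - v.mean()


def prepare_behavior_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Add 1-back history columns (per session) to a trial table."""
    out = trials.copy().reset_index(drop=True)
    g = out.groupby("session_id", sort=False)
    out["past_rew1"] = g["outcome_drops"].shift(1)
    out["past_act1"] = g["act_time_dots"].shift(1)
    out["quad_reward"] = quadratic_reward_code(out["reward_level"])
    return out


def _fit_mixedlm(formula: str, data: pd.DataFrame, reml: bool = False):
    """MixedLM with animal random intercept and session nested in animal.

    On a singular fit the nested session term is dropped with a warning.
    """
    singular = False
    vcf = {"session": "0 + C(session_id)"}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data["animal_id"], vc_formula=vcf)
        # lbfgs can stall on a flat spurious optimum of the variance
        # components; fit with two optimizers and keep the better llf
        res = None
        for method in ("lbfgs", "powell"):
            try:
                cand = model.fit(reml=reml, method=method)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if not np.isfinite(cand.llf):
                continue
            if res is None or cand.llf > res.llf + 1e-8:
                res = cand
        if res is None or not np.isfinite(res.llf):
            singular = True
            warnings.warn("singular fit; refitting without nested session term")
            model = smf.mixedlm(formula, data, groups=data["animal_id"])
            res = model.fit(reml=reml)
    return res, singular


def _lr_test(full_res, reduced_res) -> tuple[float, int, float]:
    lr = 2.0 * (full_res.llf - reduced_res.llf)
    df = int(len(full_res.fe_params) - len(reduced_res.fe_params))
    df = max(df, 1)
    return lr, df, float(stats.chi2.sf(max(lr, 0.0), df))


def _drop_term(formula: str, term: str) -> str:
    """Remove a term and every interaction involving it (type-III-style)."""
    lhs, rhs = formula.split("~")
    parts = [p.strip() for p in rhs.split("+")]
    parts = [p for p in parts if term not in p.split(":")]
    return f"{lhs.strip()} ~ {' + '.join(parts)}"


def fit_acttime_glm(
    trials: pd.DataFrame,
    coding: str = "Treatment",
    omnibus: bool = True,
) -> MixedModelFit:
    """Multilevel GLM for actTime on responded trials.

    Fixed effects: the reward x dotSpeed x ITI factorial (all two- and
    three-way interactions) plus the previous trial's reward outcome and
    actTime; random intercepts for animal and session-within-animal; ML
    estimation.  Omnibus term tests are likelihood-ratio chi-squares from
    refits without each term.
    """
    df = prepare_behavior_table(trials)
    df = df[df["responded"]].dropna(subset=["past_rew1", "past_act1"]).copy()
    C = f"C(reward_level, {coding})"
    D = f"C(dot_period_ms, {coding})"
    I = f"C(iti_s, {coding})"
    terms = [C, D, I, f"{C}:{D}", f"{C}:{I}", f"{D}:{I}", f"{C}:{D}:{I}",
             "past_rew1", "past_act1"]
    formula = "act_time_dots ~ " + " + ".join(terms)
    res, singular = _fit_mixedlm(formula, df)
    omni = None
    if omnibus:
        rows = []
        for term in [C, D, I, "past_rew1", "past_act1"]:
            red_formula = _drop_term(formula, term)
            red, _ = _fit_mixedlm(red_formula, df)
            lr, dof, p = _lr_test(res, red)
            rows.append(dict(term=term, lr_chi2=lr, df=dof, p=p))
        omni = pd.DataFrame(rows).set_index("term")
    return MixedModelFit(result=res, omnibus=omni, singular=singular)


def fit_response_logit(trials: pd.DataFrame) -> MixedModelFit:
    """Hierarchical logistic model for the odds of responding at all.

    logit(response) ~ reward + dotSpeed + ITI + past reward outcome +
    past actTime (linear terms, as in the printed model), random
    intercepts for session within animal when the data have grouping
    structure.  Returns odds ratios exp(beta) with 95% intervals.
    """
    df = prepare_behavior_table(trials).dropna(subset=["past_rew1", "past_act1"]).copy()
    df["response"] = df["responded"].astype(int)
    fixed = ["reward_level", "dot_period_ms", "iti_s", "past_rew1", "past_act1"]
    X = sm.add_constant(df[fixed].astype(float))
    y = df["response"]
    if y.nunique() < 2:
        raise ValueError("all responses identical: logit undefined")
    multi = df["session_id"].nunique() >= 2
    if multi:
        from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

        # z-scored fixed effects keep the variational fit well scaled
        mu = X.iloc[:, 1:].mean()
        sd = X.iloc[:, 1:].std(ddof=0).replace(0, 1.0)
        Xz = X.copy()
        Xz.iloc[:, 1:] = (X.iloc[:, 1:] - mu) / sd
        exog_vc = pd.get_dummies(df["session_id"]).to_numpy(float)
        exog_va = pd.get_dummies(df["animal_id"]).to_numpy(float)
        vc = np.hstack([exog_vc, exog_va])
        ident = np.array([0] * exog_vc.shape[1] + [1] * exog_va.shape[1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = BinomialBayesMixedGLM(
                y.to_numpy(float), Xz.to_numpy(float), vc, ident,
                vcp_p=2.0, fe_p=2.0,
            )
            res = model.fit_vb()
        k = X.shape[1]
        coefs = res.fe_mean[:k] / np.concatenate([[1.0], sd.to_numpy()])
        ses = res.fe_sd[:k] / np.concatenate([[1.0], sd.to_numpy()])
        names = X.columns
    else:
        glm = sm.GLM(y, X, family=sm.families.Binomial())
        try:
            fit = glm.fit()
        except Exception as err:  # perfect separation
            raise ValueError(f"logistic fit failed (separation?): {err}") from err
        if not np.all(np.isfinite(fit.bse)) or np.any(np.abs(fit.params) > 30):
            raise ValueError("complete separation detected in logistic model")
        res = fit
        coefs, ses, names = fit.params.to_numpy(), fit.bse.to_numpy(), X.columns
    or_tab = pd.DataFrame(
        {
            "coef": coefs,
            "se": ses,
            "odds_ratio": np.exp(coefs),
            "or_ci_lo": np.exp(coefs - 1.96 * ses),
            "or_ci_hi": np.exp(coefs + 1.96 * ses),
        },
        index=names,
    )
    return MixedModelFit(result=res, odds_ratios=or_tab)


def _planned_contrast(res, labels_weights: dict[str, float], label: str) -> ContrastResult:
    """Wald contrast on fixed-effect parameters of a MixedLM result."""
    names = list(res.model.exog_names)
    L = np.zeros(len(names))
    for name, w in labels_weights.items():
        if name not in names:
            raise KeyError(f"parameter {name!r} not in model ({names})")
        L[names.index(name)] = w
    t = res.t_test(np.atleast_2d(L))
    est = float(np.atleast_1d(t.effect)[0])
    se = float(np.atleast_1d(t.sd).ravel()[0])
    z = est / se
    return ContrastResult(label=label, estimate=est, se=se, statistic=z,
                          p=float(2 * stats.norm.sf(abs(z))))


def _require_conditions(df: pd.DataFrame):
    present = set(df["condition"].unique())
    missing = [c for c in TUS_CONDITIONS if c not in present]
    if missing:
        raise ValueError(f"missing TUS condition(s): {missing}")


def tus_reward_interaction(trials: pd.DataFrame, coding: str = "Treatment") -> MixedModelFit:
    """TUS condition x reward interaction model for observed actTime.

    actTime ~ condition * reward with random intercepts; the omnibus is
    the likelihood-ratio chi-square of the interaction block.  Planned
    contrasts compare ACC against each other condition within the
    medium-vs-small and large-vs-small reward effects.
    """
    df = prepare_behavior_table(trials)
    df = df[df["responded"]].copy()
    _require_conditions(df)
    base = "C(condition, Treatment('sham'))"
    rew = f"C(reward_level, {coding})"
    formula = f"act_time_dots ~ {base} + {rew} + {base}:{rew}"
    res, singular = _fit_mixedlm(formula, df)
    red, _ = _fit_mixedlm(f"act_time_dots ~ {base} + {rew}", df)
    lr, dof, p = _lr_test(res, red)
    omni = pd.DataFrame([dict(term="condition:reward", lr_chi2=lr, df=dof, p=p)]).set_index("term")

    def iterm(cond, lvl):
        return f"{base}[T.{cond}]:{rew}[T.{lvl}]"

    contrasts = []
    for lvl, lvl_label in ((2, "medium-vs-small"), (3, "large-vs-small")):
        for other in ("BF", "POp", "sham"):
            if other == "sham":
                weights = {iterm("ACC", lvl): 1.0}
            else:
                weights = {iterm("ACC", lvl): 1.0, iterm(other, lvl): -1.0}
            contrasts.append(
                _planned_contrast(res, weights, f"ACC-vs-{other} @ {lvl_label}")
            )
    return MixedModelFit(result=res, omnibus=omni, contrasts=contrasts, singular=singular)


def tus_bias_model(trials: pd.DataFrame, det: pd.DataFrame) -> MixedModelFit:
    """TUS main-effect model for the actTime bias |observed - deterministic|.

    ``det`` is the per-trial deterministic table from
    :func:`acttime.survival.deterministic_table` computed with the
    all-lags (10-back) coefficients.  Planned contrasts compare BF
    against ACC, POp and sham.
    """
    df = trials.merge(
        det[["session_id", "trial_index", "det_full"]],
        on=["session_id", "trial_index"],
        how="inner",
    )
    df = df[df["responded"]].copy()
    _require_conditions(df)
    df["bias"] = np.abs(df["act_time_dots"] - df["det_full"])
    if np.allclose(df["bias"].to_numpy(), df["bias"].iloc[0]):
        raise ValueError("degenerate bias column (constant): model undefined")
    base = "C(condition, Treatment('sham'))"
    formula = f"bias ~ {base}"
    res, singular = _fit_mixedlm(formula, df)
    red, _ = _fit_mixedlm("bias ~ 1", df)
    lr, dof, p = _lr_test(res, red)
    omni = pd.DataFrame([dict(term="condition", lr_chi2=lr, df=dof, p=p)]).set_index("term")
    contrasts = []
    for other in ("ACC", "POp", "sham"):
        name_bf = f"{base}[T.BF]"
        if other == "sham":
            weights = {name_bf: 1.0}
        else:
            weights = {name_bf: 1.0, f"{base}[T.{other}]": -1.0}
        contrasts.append(_planned_contrast(res, weights, f"BF-vs-{other}"))
    return MixedModelFit(result=res, omnibus=omni, contrasts=contrasts, singular=singular)
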
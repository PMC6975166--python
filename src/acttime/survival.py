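"""Censored Cox hazard model of action time and its survival integral.

The number of dots on screen at response ("actTime", 1..25) is treated as
a discrete time-to-event outcome; no-response trials are censored at the
final dot.  A Cox proportional-hazards model

    lambda(t) = lambda0(t) * exp(beta . x)

is fitted per testing session with 23 covariates: the current trial's
reward magnitude, dot period and ITI (present context) plus the reward
outcomes and actTimes of the past 10 trials (past context).  From a fit,
each trial's predicted survival function

    S_x(t) = exp(-Lambda0(t) * exp(beta . x))

is integrated over the dot grid to yield the *deterministic actTime*, the
expected actTime implied by context alone.  The module also computes
Schemper's V (proportion of explained variation for survival models) and
the TUS outcome statistic |observed - deterministic| ("actTime bias").

Fitting is delegated to :class:`lifelines.CoxPHFitter` (Efron tie
correction, Breslow baseline hazard); everything downstream of the fit is
implemented here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError

from acttime.task import N_BACK

__all__ = [
    "CoxDesign",
    "build_cox_design",
    "CoxActTimeModel",
    "CoxActTimeResults",
    "survival_curve",
    "deterministic_act_time",
    "schemper_v",
    "PEVResult",
    "act_time_bias",
    "EmptyDesignError",
    "CoxFitError",
]

logger = logging.getLogger(__name__)

VARIANTS = ("full", "present", "past")

PRESENT_COLS = ["reward", "dot_period", "iti"]
PAST_REW_COLS = [f"past_rew{k}" for k in range(1, N_BACK + 1)]
PAST_ACT_COLS = [f"past_act{k}" for k in range(1, N_BACK + 1)]
FULL_COLS = PRESENT_COLS + PAST_REW_COLS + PAST_ACT_COLS


class EmptyDesignError(ValueError):
    """Session too short (or empty) to build a usable design."""


class CoxFitError(RuntimeError):
    """Partial-likelihood maximization failed (non-convergence/separation)."""


@dataclass
class CoxDesign:
    """Standardized per-session design for the Cox actTime model.

    ``X`` holds z-scored covariates (per session, over included rows),
    ``duration`` the actTime in dots, ``event`` True for responded
    trials (censored trials enter at the final dot with event False).
    ``center``/``scale`` retain the standardization so predictions can be
    mapped back to raw covariates.
    """

    X: pd.DataFrame
    duration: np.ndarray
    event: np.ndarray
    center: pd.Series
    scale: pd.Series
    trial_index: np.ndarray  # positional index into the source table
    max_dots: int = 25

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)


def _raw_covariates(trials: pd.DataFrame, n_back: int) -> pd.DataFrame:
    """Unstandardized covariate block for one time-ordered session.

    Past actTime of a censored past trial is entered as the censoring
    time (the final dot): the animal observably waited the full window.
    """
    out = pd.DataFrame(
        {
            "reward": trials["reward_level"].to_numpy(float),
            "dot_period": trials["dot_period_ms"].to_numpy(float),
            "iti": trials["iti_s"].to_numpy(float),
        }
    )
    drops = trials["outcome_drops"].to_numpy(float)
    acts = trials["act_time_dots"].to_numpy(float)
    for k in range(1, n_back + 1):
        out[f"past_rew{k}"] = pd.Series(drops).shift(k).to_numpy()
        out[f"past_act{k}"] = pd.Series(acts).shift(k).to_numpy()
    return out


def build_cox_design(
    trials: pd.DataFrame,
    n_back: int = N_BACK,
    variant: str = "full",
    standardize: bool = True,
) -> CoxDesign:
    """Build the (standardized) Cox design for one session.

    The first ``n_back`` trials are dropped (incomplete history); both
    responded and censored trials are retained.  ``variant`` selects the
    covariate block: ``full`` (3 + 2*n_back columns), ``present`` (3) or
    ``past`` (2*n_back).
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    if len(trials) <= n_back:
        raise EmptyDesignError(
            f"session has {len(trials)} trials; need more than n_back={n_back}"
        )
    trials = trials.reset_index(drop=True)
    raw = _raw_covariates(trials, n_back)
    keep = np.arange(n_back, len(trials))
    raw = raw.iloc[keep].reset_index(drop=True)

    past_cols = [f"past_rew{k}" for k in range(1, n_back + 1)] + [
        f"past_act{k}" for k in range(1, n_back + 1)
    ]
    if variant == "present":
        raw = raw[PRESENT_COLS]
    elif variant == "past":
        raw = raw[past_cols]
    else:
        raw = raw[PRESENT_COLS + past_cols]

    assert not raw.isna().any().any()
    center = raw.mean()
    scale = raw.std(ddof=0)
    if standardize:
        safe = scale.replace(0.0, 1.0)
        X = (raw - center) / safe
    else:
        X = raw.copy()
        center = center * 0.0
        scale = scale * 0.0 + 1.0

    max_dots = int(trials["act_time_dots"].max()) if len(trials) else 25
    max_dots = max(max_dots, 25)
    duration = trials["act_time_dots"].to_numpy(float)[keep]
    event = trials["responded"].to_numpy(bool)[keep]
    return CoxDesign(
        X=X,
        duration=duration,
        event=event,
        center=center,
        scale=scale,
        trial_index=keep,
        max_dots=max_dots,
    )


def _check_design(design: CoxDesign) -> None:
    if design.n_events < 1:
        raise CoxFitError("no events in design (all trials censored); refusing to fit")
    variances = design.X.var(axis=0).to_numpy()
    if np.any(variances == 0):
        cols = [c for c, v in zip(design.columns, variances) if v == 0]
        raise CoxFitError(f"constant covariate column(s): {cols}")


class CoxActTimeModel:
    """Cox proportional-hazards model of actTime for one session.

    Parameters
    ----------
    trials : DataFrame
        Time-ordered trial table of a single session (columns as written
        by :func:`acttime.task.write_trials`).
    variant : {"full", "present", "past"}
        Covariate block: present + past-10 context (23 columns), present
        context only (3), or past context only (20).
    n_back : int
        History depth for past-context covariates.
    tie_method : {"efron", "breslow"}
        Partial-likelihood tie correction.  Discrete dot times produce
        massive ties; Efron is the default.
    """

    def __init__(
        self,
        trials: pd.DataFrame,
        variant: str = "full",
        n_back: int = N_BACK,
        tie_method: str = "efron",
    ):
        self.trials = trials.reset_index(drop=True)
        self.variant = variant
        self.n_back = n_back
        self.tie_method = tie_method
        self.design = build_cox_design(self.trials, n_back=n_back, variant=variant)

    @classmethod
    def from_design(cls, design: CoxDesign, tie_method: str = "efron") -> "CoxActTimeModel":
        obj = cls.__new__(cls)
        obj.trials = None
        obj.variant = "custom"
        obj.n_back = N_BACK
        obj.tie_method = tie_method
        obj.design = design
        return obj

    def fit(self) -> "CoxActTimeResults":
        design = self.design
        _check_design(design)
        df = design.X.copy()
        df["_duration"] = design.duration
        df["_event"] = design.event.astype(int)
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="_duration", event_col="_event")
        except ConvergenceError as err:
            raise CoxFitError(f"partial likelihood did not converge: {err}") from err
        beta = cph.params_.to_numpy()
        if not np.all(np.isfinite(beta)) or np.any(np.abs(beta) > 50):
            raise CoxFitError("separation suspected: unbounded coefficient estimate")
        # lifelines' baseline is evaluated at the column means; the design
        # is z-scored so this is exactly the x = 0 baseline.
        bch = cph.baseline_cumulative_hazard_.iloc[:, 0]
        grid = np.arange(0, design.max_dots + 1, dtype=float)
        # forward-fill step function onto the integer dot grid
        idx = np.searchsorted(bch.index.to_numpy(float), grid, side="right") - 1
        cum0 = np.where(idx >= 0, bch.to_numpy()[np.clip(idx, 0, None)], 0.0)
        return CoxActTimeResults(
            model=self,
            fit_center=design.X.mean().to_numpy(),
            beta=pd.Series(beta, index=design.columns, name="coef"),
            se=pd.Series(cph.standard_errors_.to_numpy(), index=design.columns, name="se"),
            baseline_cum_hazard=cum0,
            grid=grid,
            log_likelihood=float(cph.log_likelihood_),
            n_events=design.n_events,
            tie_method=self.tie_method,
            _lifelines_fit=cph,
        )


@dataclass
class PEVResult:
    """Schemper's proportion of explained variation for one fit."""

    V: float
    D: float
    Dx: float

    def __repr__(self) -> str:  # pragma: no cover
        return f"PEVResult(V={self.V:.4f}, D={self.D:.4f}, Dx={self.Dx:.4f})"


@dataclass
class CoxActTimeResults:
    """Fitted Cox actTime model: coefficients, baseline hazard, derivations.

    ``baseline_cum_hazard`` is the Breslow cumulative hazard evaluated on
    the integer dot grid 0..max_dots at covariates 0 (the session mean on
    the standardized scale).
    """

    model: CoxActTimeModel
    fit_center: np.ndarray
    beta: pd.Series
    se: pd.Series
    baseline_cum_hazard: np.ndarray
    grid: np.ndarray
    log_likelihood: float
    n_events: int
    tie_method: str
    _lifelines_fit: object = field(default=None, repr=False)

    @property
    def design(self) -> CoxDesign:
        return self.model.design

    def linear_predictor(self, X: np.ndarray | None = None, which: str = "all") -> np.ndarray:
        """beta . (x - x_bar) per trial, optionally restricted to a subset.

        Centering on the fit's covariate means matches the baseline
        hazard, which is estimated at the mean covariates (identically 0
        for the z-scored session designs).  ``which``: "all" uses every
        fitted coefficient; "1back" restricts past-context coefficients
        to the immediately preceding trial (the fMRI-facing deterministic
        actTime); "present" and "past" restrict to the respective block.
        """
        if X is None:
            X = self.design.X.to_numpy()
        X = np.atleast_2d(np.asarray(X, dtype=float)) - self.fit_center[None, :]
        beta = self.beta.copy()
        cols = list(beta.index)
        if which == "1back":
            keep = set(PRESENT_COLS) | {"past_rew1", "past_act1"}
            mask = np.array([c in keep for c in cols])
            beta = beta.where(pd.Series(mask, index=beta.index), 0.0)
        elif which == "present":
            mask = np.array([c in PRESENT_COLS for c in cols])
            beta = beta.where(pd.Series(mask, index=beta.index), 0.0)
        elif which == "past":
            mask = np.array([c not in PRESENT_COLS for c in cols])
            beta = beta.where(pd.Series(mask, index=beta.index), 0.0)
        elif which != "all":
            raise ValueError(f"unknown coefficient subset {which!r}")
        return X @ beta.to_numpy()

    def survival_curve(self, x: np.ndarray, which: str = "all") -> np.ndarray:
        """Predicted survival S_x(t) on the dot grid for covariates ``x``
        (one curve for a single vector, rows for a matrix)."""
        S = survival_curve(self.baseline_cum_hazard, self.linear_predictor(x, which))
        if np.asarray(x).ndim == 1:
            return S[0]
        return S

    def deterministic_act_time(self, which: str = "all", X: np.ndarray | None = None) -> np.ndarray:
        """Per-trial deterministic actTime (expected dots) for this fit.

        ``which="1back"`` reproduces the fMRI-facing variant (present +
        immediately preceding trial only); ``which="all"`` the TUS-facing
        variant using all fitted lags.
        """
        lp = self.linear_predictor(X, which)
        S = survival_curve(self.baseline_cum_hazard, lp)
        return deterministic_act_time(S)

    def schemper_v(self) -> PEVResult:
        """Schemper's V for this fit on its own design.

        Predicted per-trial curves use the product-limit transform of
        the Breslow increments, S_i(t) = prod_{t_j<=t} (1 - dLambda0(t_j)
        exp(beta.x_i)): with heavy ties this is the discrete-consistent
        form that reduces exactly to the Kaplan-Meier curve when beta=0,
        so a null fit yields V ~ 0.
        """
        dL = np.diff(self.baseline_cum_hazard)
        risk = np.exp(self.linear_predictor())
        factors = np.clip(1.0 - risk[:, None] * dL[None, :], 0.0, 1.0)
        S = np.concatenate(
            [np.ones((len(risk), 1)), np.cumprod(factors, axis=1)], axis=1
        )
        return schemper_v(self.design, S)

    def summary(self) -> pd.DataFrame:
        z = self.beta / self.se
        from scipy.stats import norm

        return pd.DataFrame(
            {
                "coef": self.beta,
                "se": self.se,
                "z": z,
                "p": 2 * norm.sf(np.abs(z)),
            }
        )

    def plot_survival(self, x=None, ax=None, which: str = "all", **kwargs):
        """Plot predicted survival curves for covariate rows ``x``."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        X = self.design.X.to_numpy() if x is None else np.atleast_2d(x)
        S = self.survival_curve(X, which)
        for row in S:
            ax.step(self.grid, row, where="post", **kwargs)
        ax.set_xlabel("dots")
        ax.set_ylabel("S(t)")
        return ax


def survival_curve(baseline_cum_hazard: np.ndarray, linear_predictor) -> np.ndarray:
    """S_x(t) = exp(-Lambda0(t) exp(beta.x)) on the dot grid.

    ``linear_predictor`` may be a scalar (one curve) or a vector (one
    curve per trial, returned as rows).
    """
    lp = np.asarray(linear_predictor, dtype=float)
    scalar = lp.ndim == 0
    lam = np.atleast_1d(np.exp(lp))[:, None] * baseline_cum_hazard[None, :]
    S = np.exp(-lam)
    return S[0] if scalar else S


def deterministic_act_time(S: np.ndarray) -> np.ndarray | float:
    """Expected actTime: the survival integral on the discrete dot grid.

    For T in {1..max_dots}, E[T] = sum_{t=0}^{max_dots-1} P(T > t), i.e.
    the sum of S over all grid points but the last.
    """
    S = np.asarray(S, dtype=float)
    vec = S.ndim == 1
    S2 = np.atleast_2d(S)
    out = S2[:, :-1].sum(axis=1)
    return float(out[0]) if vec else out


def _km_survival(duration, event, grid) -> np.ndarray:
    kmf = KaplanMeierFitter()
    kmf.fit(duration, event_observed=event)
    sf = kmf.survival_function_.iloc[:, 0]
    idx = np.searchsorted(sf.index.to_numpy(float), grid, side="right") - 1
    return np.where(idx >= 0, sf.to_numpy()[np.clip(idx, 0, None)], 1.0)


def schemper_v(design: CoxDesign, S_pred: np.ndarray) -> PEVResult:
    """Schemper's V: explained variation of a survival fit.

    At each distinct event time t_j the absolute distance between each
    trial's empirical survival process S_i(t_j) (1 while alive, 0 after
    an event; undefined past a censoring time) and a model curve is
    averaged over the trials still defined there.  D-hat uses the
    covariate-free Kaplan-Meier curve, D-hat_x the per-trial predicted
    curves ``S_pred`` (rows aligned with the design); pooling weights
    each event time by the number of defined trials.
    """
    S_pred = np.atleast_2d(np.asarray(S_pred, dtype=float))
    n = len(design.duration)
    if S_pred.shape[0] != n:
        raise ValueError("S_pred rows must align with design rows")
    times = np.unique(design.duration[design.event])
    if times.size == 0:
        raise ValueError("no events: Schemper's V undefined")
    km = _km_survival(design.duration, design.event, times)
    # S_pred columns are the integer grid 0..max_dots; times are integers
    pred_at = S_pred[:, times.astype(int)]

    T = design.duration[:, None]  # (n, 1)
    ev = design.event[:, None]
    tj = times[None, :]  # (1, k)
    alive = (tj < T).astype(float)  # S_i(t_j) = 1 while t_j < T_i
    # defined: events always; censored only up to the censoring time
    defined = ev | (tj <= T)
    km_dist = np.abs(alive - km[None, :])
    x_dist = np.abs(alive - pred_at)
    w = defined.astype(float)
    denom = w.sum()
    if denom == 0:
        raise ValueError("no defined (trial, time) pairs")
    D = float((km_dist * w).sum() / denom)
    Dx = float((x_dist * w).sum() / denom)
    if D <= 0:
        raise ValueError("D-hat is zero: V undefined")
    return PEVResult(V=(D - Dx) / D, D=D, Dx=Dx)


def act_time_bias(observed: np.ndarray, deterministic: np.ndarray, responded=None) -> np.ndarray:
    """|observed - deterministic| actTime per responded trial.

    Censored trials (``responded`` False) are excluded and logged.
    """
    observed = np.asarray(observed, dtype=float)
    deterministic = np.asarray(deterministic, dtype=float)
    if responded is not None:
        responded = np.asarray(responded, dtype=bool)
        n_drop = int((~responded).sum())
        if n_drop:
            logger.info("act_time_bias: excluding %d censored trials", n_drop)
        observed = observed[responded]
        deterministic = deterministic[responded]
    return np.abs(observed - deterministic)


def fit_sessions(
    trials: pd.DataFrame,
    variant: str = "full",
    n_back: int = N_BACK,
    on_error: str = "raise",
) -> dict[str, CoxActTimeResults]:
    """Fit the Cox actTime model independently for every session."""
    out: dict[str, CoxActTimeResults] = {}
    for sid, sess in trials.groupby("session_id", sort=False):
        try:
            out[sid] = CoxActTimeModel(sess, variant=variant, n_back=n_back).fit()
        except (CoxFitError, EmptyDesignError):
            if on_error == "raise":
                raise
            logger.warning("session %s skipped (fit failed)", sid)
    return out


def deterministic_table(
    trials: pd.DataFrame,
    which_past: str = "1back",
    n_back: int = N_BACK,
) -> pd.DataFrame:
    """Per-trial deterministic actTime for all three model variants.

    ``which_past="1back"`` uses only the immediately preceding trial's
    past coefficients (fMRI-facing); ``"all"`` uses every fitted lag
    (TUS-facing).  Returns one row per design trial with columns
    ``det_full``, ``det_present``, ``det_past`` plus identifiers.
    """
    rows = []
    for sid, sess in trials.groupby("session_id", sort=False):
        sess = sess.reset_index(drop=True)
        res_full = CoxActTimeModel(sess, variant="full", n_back=n_back).fit()
        res_pres = CoxActTimeModel(sess, variant="present", n_back=n_back).fit()
        res_past = CoxActTimeModel(sess, variant="past", n_back=n_back).fit()
        which_full = "all" if which_past == "all" else "1back"
        which_p = "all" if which_past == "all" else "1back"
        det_full = res_full.deterministic_act_time(which=which_full)
        det_pres = res_pres.deterministic_act_time(which="all")
        det_past = res_past.deterministic_act_time(which=which_p)
        idx = res_full.design.trial_index
        sub = sess.iloc[idx]
        rows.append(
            pd.DataFrame(
                {
                    "animal_id": sub["animal_id"].to_numpy(),
                    "session_id": sid,
                    "trial_index": sub["trial_index"].to_numpy(),
                    "act_time_dots": sub["act_time_dots"].to_numpy(),
                    "responded": sub["responded"].to_numpy(),
                    "det_full": det_full,
                    "det_present": det_pres,
                    "det_past": det_past,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
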
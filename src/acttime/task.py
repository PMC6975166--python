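"""Generative simulator of the dot-counting self-initiated-action task.

A trial presents dots one at a time (up to 25) at one of three speeds; the
probability that a response is rewarded grows with the number of dots on
screen following a fixed sigmoid (midpoint dot 12, steepness 0.5).  Offered
reward magnitude (1-3 drops), dot period (100/200/300 ms) and inter-trial
interval (3/5/7 s, constant over 30-trial blocks) vary pseudo-randomly.
The simulated animal decides *when* to respond through a discrete per-dot
hazard: at dot ``t`` it responds with probability

    p_t = min(1, lambda0(t) * exp(beta . x + eps)),

where ``x`` holds the standardized present context (reward, dot period,
ITI) and the past 10 trials' reward outcomes and action times, matching
the covariate structure of the downstream Cox model, and ``eps`` is a
per-trial log-hazard jitter representing unmodelled variability.  Trials
with no response by dot 25 are censored; an additional context-dependent
probability of withholding reproduces the experiment's ~16% no-response
rate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TaskConfig",
    "AgentParams",
    "default_agent",
    "reward_probability",
    "sample_act_time",
    "generate_session",
    "generate_cohort",
    "generate_tus_cohort",
    "read_trials",
    "write_trials",
    "TrialTableError",
    "N_BACK",
    "TRIAL_COLUMNS",
]

N_BACK = 10
N_COVARIATES = 3 + 2 * N_BACK

#: Column order of the on-disk trial table (tab separated, one row per trial).
TRIAL_COLUMNS = [
    "animal_id",
    "session_id",
    "trial_index",
    "condition",
    "reward_level",
    "dot_period_ms",
    "iti_s",
    "side",
    "responded",
    "act_time_dots",
    "act_time_s",
    "rewarded",
    "outcome_drops",
    "t_onset_s",
]


class TrialTableError(ValueError):
    """Raised when a trial table on disk cannot be parsed."""


@dataclass(frozen=True)
class TaskConfig:
    """Structural parameters of the dot-counting task.

    Defaults reproduce the experiment: 25 dots maximum, reward sigmoid
    with midpoint at dot 12 and steepness 0.5, factorial context levels,
    30-trial ITI blocks, a 4 s action-outcome delay and 40-minute
    sessions.
    """

    max_dots: int = 25
    sigmoid_midpoint: float = 12.0
    sigmoid_steepness: float = 0.5
    reward_levels: tuple[int, ...] = (1, 2, 3)
    dot_periods_ms: tuple[int, ...] = (100, 200, 300)
    iti_levels_s: tuple[float, ...] = (3.0, 5.0, 7.0)
    iti_block_length: int = 30
    ao_delay_s: float = 4.0
    outcome_display_s: float = 2.0
    session_budget_s: float = 2400.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.max_dots < 1:
            raise ValueError("max_dots must be >= 1")
        if self.sigmoid_steepness <= 0:
            raise ValueError("sigmoid_steepness must be > 0")
        if self.session_budget_s <= 0:
            raise ValueError("session_budget_s must be > 0")
        for name in ("reward_levels", "dot_periods_ms", "iti_levels_s"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")

    @classmethod
    def from_yaml(cls, path) -> "TaskConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
        return cls(**raw)


# Fixed standardization moments used by the generating agent.  The fitter
# z-scores covariates empirically per session; the agent needs a causal
# (history-independent) scaling, so it uses the theoretical moments of the
# factorial design and round central values for the past-trial covariates.
_COV_CENTER = np.array([2.0, 200.0, 5.0] + [1.0] * N_BACK + [14.0] * N_BACK)
_COV_SCALE = np.array(
    [np.sqrt(2.0 / 3.0), 100.0 * np.sqrt(2.0 / 3.0), 2.0 * np.sqrt(2.0 / 3.0)]
    + [1.0] * N_BACK
    + [8.5] * N_BACK
)


@dataclass
class AgentParams:
    """Ground-truth hazard agent generating action times.

    ``beta_truth`` holds 23 log-hazard coefficients on the standardized
    covariate scale, ordered [reward, dot period, ITI,
    past reward 1..10 back, past actTime 1..10 back].  ``baseline_hazard``
    is the per-dot response probability when all covariates sit at their
    central values.  ``nonresponse_prob`` may be a constant or a callable
    ``(reward_level, dot_period_ms, iti_s) -> probability`` of withholding
    the response outright.  ``noise_sd`` is the SD of a per-trial Gaussian
    jitter on the log hazard (unexplained variability).
    """

    beta_truth: np.ndarray
    baseline_hazard: np.ndarray
    nonresponse_prob: float | Callable[[int, int, float], float] = 0.02
    noise_sd: float = 0.25

    def __post_init__(self) -> None:
        self.beta_truth = np.asarray(self.beta_truth, dtype=float)
        self.baseline_hazard = np.asarray(self.baseline_hazard, dtype=float)
        if not np.all(np.isfinite(self.beta_truth)):
            raise ValueError("beta_truth must be finite")
        if np.any(self.baseline_hazard < 0) or np.any(self.baseline_hazard > 1):
            raise ValueError("baseline_hazard entries must lie in [0, 1]")

    def withhold_probability(self, reward_level, dot_period_ms, iti_s) -> float:
        if callable(self.nonresponse_prob):
            return float(self.nonresponse_prob(reward_level, dot_period_ms, iti_s))
        return float(self.nonresponse_prob)

    def replace(self, **kwargs) -> "AgentParams":
        return dataclasses.replace(self, **kwargs)


def default_baseline_hazard(max_dots: int = 25) -> np.ndarray:
    """Per-dot baseline hazard: ramp to a 0.12 plateau by dot 12, then a
    late rise from dot 18 as the response window closes.

    Kept low enough that per-dot response probabilities stay well below 1
    for typical contexts (so the clipped discrete hazard remains close to
    its proportional-hazards continuum limit and clipping is negligible)
    while residual survival past the final dot plus a small deliberate
    withholding rate yields the experiment's ~16% censored trials.  Most
    censoring therefore arises from the hazard process itself, which is
    what the downstream Cox model assumes of censored trials.
    """
    dots = np.arange(1, max_dots + 1, dtype=float)
    ramp = np.clip((dots - 1.0) / 11.0, 0.0, 1.0)
    late = np.clip((dots - 18.0) / 7.0, 0.0, 1.0)
    return 0.018 + 0.102 * ramp + 0.45 * late


def default_agent(beta_truth: np.ndarray | None = None, **kwargs) -> AgentParams:
    """Agent reproducing the sign pattern of the fitted hazard model.

    Positive effect of offered reward and of the previous trial's reward
    outcome; negative effects of dot period, ITI and the previous trial's
    actTime; all other past lags zero.
    """
    if beta_truth is None:
        beta_truth = np.zeros(N_COVARIATES)
        beta_truth[0] = 0.5    # reward magnitude
        beta_truth[1] = -1.0   # dot period (slower dots -> lower per-dot hazard)
        beta_truth[2] = -0.3   # ITI
        beta_truth[3] = 0.5    # reward outcome, 1 back
        beta_truth[3 + N_BACK] = -0.2  # actTime, 1 back
    return AgentParams(
        beta_truth=np.asarray(beta_truth, dtype=float),
        baseline_hazard=default_baseline_hazard(),
        **kwargs,
    )


def reward_probability(d, cfg: TaskConfig | None = None):
    """Probability that a response at dot ``d`` is rewarded.

    The schedule is the task's fixed sigmoid
    ``1 / (1 + exp(-k (d - d0)))`` with midpoint ``d0`` (default dot 12)
    and steepness ``k`` (default 0.5); strictly increasing in ``d``.
    """
    cfg = cfg or TaskConfig()
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 1) or np.any(d_arr > cfg.max_dots):
        raise ValueError(f"dot count must lie in [1, {cfg.max_dots}]")
    p = 1.0 / (1.0 + np.exp(-cfg.sigmoid_steepness * (d_arr - cfg.sigmoid_midpoint)))
    return float(p) if np.isscalar(d) or d_arr.ndim == 0 else p


def standardize_covariates(x_raw: np.ndarray) -> np.ndarray:
    """Map raw covariates onto the agent's fixed standardized scale."""
    return (np.asarray(x_raw, dtype=float) - _COV_CENTER) / _COV_SCALE


def sample_act_time(
    x: np.ndarray,
    agent: AgentParams,
    rng: np.random.Generator,
    max_dots: int = 25,
    log_hazard_offset: float = 0.0,
) -> tuple[int, bool, int]:
    """Draw a single action time from the agent's discrete hazard.

    ``x`` is the standardized 23-covariate vector.  Returns
    ``(act_time_dots, censored, n_clipped)`` where ``censored`` marks no
    response by the final dot and ``n_clipped`` counts dots whose hazard
    exceeded 1 before clipping.
    """
    x = np.asarray(x, dtype=float)
    eta = float(agent.beta_truth @ x) + log_hazard_offset
    if agent.noise_sd > 0:
        eta += agent.noise_sd * rng.standard_normal()
    haz = agent.baseline_hazard[:max_dots] * np.exp(eta)
    n_clipped = int(np.sum(haz > 1.0))
    p = np.minimum(haz, 1.0)
    u = rng.random(max_dots)
    hits = np.nonzero(u < p)[0]
    if hits.size:
        return int(hits[0]) + 1, False, n_clipped
    return max_dots, True, n_clipped


def _iti_schedule(n_blocks: int, levels: Sequence[float], rng) -> np.ndarray:
    """Pseudo-randomized block schedule: shuffled copies of the level set."""
    reps = int(np.ceil(n_blocks / len(levels)))
    out = []
    for _ in range(reps):
        perm = list(levels)
        rng.shuffle(perm)
        out.extend(perm)
    return np.asarray(out[:n_blocks], dtype=float)


def generate_session(
    cfg: TaskConfig,
    agent: AgentParams,
    rng: np.random.Generator,
    animal_id: str = "A1",
    session_id: str = "S1",
    n_trials: int | None = None,
    condition: str = "none",
    log_hazard_offset: float = 0.0,
    bias_noise_scale: float = 1.0,
    reward_hazard_boost: Callable[[int], float] | None = None,
) -> pd.DataFrame:
    """Simulate one testing session as a trial table.

    Reward level and dot period are randomized per trial, ITI per
    30-trial block; past-context covariates feed back from the generated
    history.  The session stops once cumulative time would exceed the
    budget (default 40 min), or after ``n_trials`` trials if given.
    ``condition``, ``log_hazard_offset``, ``bias_noise_scale`` and
    ``reward_hazard_boost`` support TUS-style perturbation experiments;
    they leave the default behaviour untouched.
    """
    max_blocks = 200 if n_trials is None else int(np.ceil(n_trials / cfg.iti_block_length))
    itis = _iti_schedule(max_blocks, cfg.iti_levels_s, rng)

    past_rew: list[float] = []
    past_act: list[float] = []
    rows = []
    t = 0.0
    k = 0
    local_agent = agent
    if bias_noise_scale != 1.0:
        local_agent = agent.replace(noise_sd=agent.noise_sd * bias_noise_scale)
    while True:
        if n_trials is not None:
            if k >= n_trials:
                break
        elif t >= cfg.session_budget_s:
            break
        reward = int(rng.choice(cfg.reward_levels))
        period = int(rng.choice(cfg.dot_periods_ms))
        iti = float(itis[k // cfg.iti_block_length])
        side = "L" if rng.random() < 0.5 else "R"

        x_raw = np.empty(N_COVARIATES)
        x_raw[:3] = (reward, period, iti)
        for lag in range(N_BACK):
            x_raw[3 + lag] = past_rew[-1 - lag] if lag < len(past_rew) else _COV_CENTER[3]
            x_raw[3 + N_BACK + lag] = (
                past_act[-1 - lag] if lag < len(past_act) else _COV_CENTER[3 + N_BACK]
            )
        x = standardize_covariates(x_raw)

        offset = log_hazard_offset
        if reward_hazard_boost is not None:
            offset += float(reward_hazard_boost(reward))

        if rng.random() < agent.withhold_probability(reward, period, iti):
            dots, censored = cfg.max_dots, True
        else:
            dots, censored, _ = sample_act_time(
                x, local_agent, rng, cfg.max_dots, log_hazard_offset=offset
            )
        act_s = dots * period / 1000.0
        if censored:
            rewarded = False
            drops = 0
        else:
            rewarded = bool(rng.random() < reward_probability(dots, cfg))
            drops = reward if rewarded else 0

        rows.append(
            dict(
                animal_id=animal_id,
                session_id=session_id,
                trial_index=k + 1,
                condition=condition,
                reward_level=reward,
                dot_period_ms=period,
                iti_s=iti,
                side=side,
                responded=not censored,
                act_time_dots=dots,
                act_time_s=act_s,
                rewarded=rewarded,
                outcome_drops=drops,
                t_onset_s=t,
            )
        )
        past_rew.append(float(drops))
        past_act.append(float(dots))
        # dots on screen + action-outcome delay + outcome display + ITI
        t += act_s + cfg.ao_delay_s + cfg.outcome_display_s + iti
        k += 1
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def generate_cohort(
    n_animals: int = 4,
    sessions_per_animal: int = 11,
    cfg: TaskConfig | None = None,
    agent: AgentParams | None = None,
    rng: np.random.Generator | int | None = None,
    animal_beta_sd: float = 0.0,
    n_trials: int | None = None,
) -> pd.DataFrame:
    """Simulate a hierarchical cohort (trials within sessions within animals).

    ``animal_beta_sd`` adds iid Gaussian offsets to ``beta_truth`` per
    animal; with the default 0 all animals share the exact ground truth.
    Each session draws from a named child stream of the cohort RNG, so a
    cohort is reproducible from a single seed.
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    cfg = cfg or TaskConfig()
    agent = agent or default_agent()
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(cfg.rng_seed if rng is None else rng)
    tables = []
    for a in range(n_animals):
        beta_a = agent.beta_truth
        if animal_beta_sd > 0:
            beta_a = beta_a + animal_beta_sd * rng.standard_normal(beta_a.size)
        agent_a = agent.replace(beta_truth=beta_a)
        for s in range(sessions_per_animal):
            sess_rng = np.random.default_rng(rng.integers(2**31))
            tables.append(
                generate_session(
                    cfg,
                    agent_a,
                    sess_rng,
                    animal_id=f"A{a + 1}",
                    session_id=f"A{a + 1}-S{s + 1}",
                    n_trials=n_trials,
                )
            )
    return pd.concat(tables, ignore_index=True)


def generate_tus_cohort(
    conditions: Sequence[str] = ("sham", "ACC", "BF", "POp"),
    n_animals: int = 4,
    sessions_per_condition: int = 5,
    cfg: TaskConfig | None = None,
    agent: AgentParams | None = None,
    rng: np.random.Generator | int | None = None,
    acc_reward_boost: float = 0.0,
    bf_noise_scale: float = 1.0,
    n_trials: int | None = None,
) -> pd.DataFrame:
    """Simulate a stimulation cohort with per-session TUS conditions.

    ``acc_reward_boost`` adds that amount to the log hazard on medium and
    large reward trials under the ACC condition (animals act sooner for
    bigger rewards after ACC TUS); ``bf_noise_scale`` multiplies the
    agent's log-hazard jitter SD under the BF condition (BF TUS tightens
    the coupling between deterministic and observed actTime).  With the
    neutral defaults all conditions are statistically identical.
    """
    cfg = cfg or TaskConfig()
    agent = agent or default_agent()
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(cfg.rng_seed if rng is None else rng)
    tables = []
    for a in range(n_animals):
        for rep in range(sessions_per_condition):
            order = list(conditions)
            rng.shuffle(order)
            for cond in order:
                sess_rng = np.random.default_rng(rng.integers(2**31))
                boost = None
                if cond == "ACC" and acc_reward_boost != 0.0:
                    boost = lambda r: acc_reward_boost if r >= 2 else 0.0  # noqa: E731
                tables.append(
                    generate_session(
                        cfg,
                        agent,
                        sess_rng,
                        animal_id=f"A{a + 1}",
                        session_id=f"A{a + 1}-{cond}-{rep + 1}",
                        n_trials=n_trials,
                        condition=cond,
                        bias_noise_scale=bf_noise_scale if cond == "BF" else 1.0,
                        reward_hazard_boost=boost,
                    )
                )
    return pd.concat(tables, ignore_index=True)


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as tab-separated text with header."""
    cols = [c for c in TRIAL_COLUMNS if c in trials.columns]
    trials.to_csv(path, sep="\t", index=False, columns=cols)


def read_trials(path) -> pd.DataFrame:
    """Read a tab-separated trial table, validating shape and dtypes."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as err:
        raise TrialTableError(f"malformed trial table {path}: {err}") from err
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns and c != "condition"]
    if missing:
        raise TrialTableError(f"trial table {path} missing columns: {missing}")
    n_fields = len(df.columns)
    bad = df.isna().any(axis=1)
    if bad.any():
        line = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # 1-based + header
        raise TrialTableError(f"malformed row at line {line} of {path} ({n_fields} fields expected)")
    df["responded"] = df["responded"].astype(bool)
    df["rewarded"] = df["rewarded"].astype(bool)
    return df
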
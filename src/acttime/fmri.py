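"""fMRI design construction and ROI time-course statistics.

Builds the session-level BOLD design matrix (task regressors as 500 ms
boxcars convolved with a macaque haemodynamic response function that
peaks ~3 s after neural activity), epoched ROI time-course GLMs in
-2..+6 s windows around the response, psychophysiological-interaction
(PPI) regressors, a leave-one-out group-peak procedure that avoids
temporal selection bias, and the connectome-scaling regression comparing
whole-brain coupling profiles between conditions.  Image preprocessing
(registration, smoothing, reconstruction) is out of scope; the module
operates on (synthetic) arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "monkey_hrf",
    "build_glm1",
    "DesignMatrix",
    "simulate_bold",
    "epoch_timecourse",
    "EpochedSeries",
    "timecourse_glm",
    "glm2_regressors",
    "ppi_glm",
    "TimecourseBetas",
    "loo_peak_betas",
    "naive_peak_betas",
    "connectome_scaling",
    "RankDeficiencyError",
]

TR_DEFAULT = 2.28  # s, the study's EPI repetition time


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient (names the offending columns)."""


def monkey_hrf(dt: float = 0.1, duration: float = 20.0) -> np.ndarray:
    """Macaque double-gamma HRF kernel sampled every ``dt`` seconds.

    Main response peaks at 3.0 s (gamma shape 6, scale 0.6) with an
    undershoot around 6 s at one sixth the amplitude; the kernel is
    normalized to unit area (sum * dt = 1) so convolving a constant
    leaves it unchanged.  The 3 s peak is the empirical constraint for
    monkey BOLD; the remaining shape parameters are conventional.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    t = np.arange(0.0, duration, dt)
    peak = stats.gamma.pdf(t, a=6.0, scale=0.6)
    under = stats.gamma.pdf(t, a=11.0, scale=0.6)
    h = peak - under / 6.0
    return h / (h.sum() * dt)


def _convolve(x: np.ndarray, kernel: np.ndarray, dt: float) -> np.ndarray:
    return np.convolve(x, kernel)[: len(x)] * dt


@dataclass
class DesignMatrix:
    """Named fMRI regressors sampled on the volume (TR) grid.

    ``frame`` holds one column per regressor; ``convolved`` flags which
    columns went through the HRF; ``events`` retains the high-resolution
    unconvolved event trains (pre-convolution) for verification.
    """

    frame: pd.DataFrame
    convolved: dict[str, bool]
    tr: float
    dt: float
    events: pd.DataFrame = field(repr=False, default=None)
    hrf: np.ndarray = field(repr=False, default=None)
    n_clipped_events: int = 0

    @property
    def names(self) -> list[str]:
        return list(self.frame.columns)

    def to_tsv(self, path, sidecar: str | None = None) -> None:
        """Write the TR-grid design as TSV plus a JSON convolution sidecar."""
        self.frame.to_csv(path, sep="\t", index=False)
        if sidecar:
            import json

            with open(sidecar, "w") as fh:
                json.dump({"TR": self.tr, "convolved": self.convolved}, fh, indent=1)


GLM1_CONVOLVED = [
    "resp", "reward", "dotSpeed", "ITI", "pastRew", "pastactTime", "actTime",
    "time", "rightconv", "leftconv", "mainOut", "levelOut",
]
GLM1_UNCONVOLVED = ["rightunconv", "leftunconv", "mouth"]


def build_glm1(
    trials: pd.DataFrame,
    scan_duration_s: float | None = None,
    tr: float = TR_DEFAULT,
    dt: float = 0.1,
    past_weights: tuple[float, float] = (1.0, 1.0),
    hrf: np.ndarray | None = None,
) -> DesignMatrix:
    """Session-level whole-brain design matrix (15 named regressors).

    Task regressors (500 ms boxcars, HRF-convolved): trial-onset-locked
    main effect of stimulus (``resp``), parametric reward, dot speed,
    ITI, previous-trial reward outcome and actTime (the latter two
    multiplied by ``past_weights``, their behavioural-GLM coefficients),
    and ``actTime`` locked from 500 ms before the response for 500 ms.
    Confounds: session time, response-hand regressors (convolved),
    outcome main effect and level (convolved, locked to juice delivery),
    plus unconvolved hand/mouth distortion regressors aligned to TR
    boundaries.  Only responded trials enter; events that fall outside
    the scan are clipped with a count.
    """
    df = trials[trials["responded"]].reset_index(drop=True)
    if scan_duration_s is None:
        last = trials["t_onset_s"].max() + 40.0
        scan_duration_s = float(np.ceil(last / tr) * tr)
    n_hi = int(np.round(scan_duration_s / dt))
    n_tr = int(np.floor(scan_duration_s / tr))
    hrf = monkey_hrf(dt) if hrf is None else hrf

    trains = {name: np.zeros(n_hi) for name in GLM1_CONVOLVED + GLM1_UNCONVOLVED}
    n_clipped = 0

    def add_box(name, t0, dur, amp):
        nonlocal n_clipped
        i0, i1 = int(np.round(t0 / dt)), int(np.round((t0 + dur) / dt))
        if i0 >= n_hi or i1 <= 0:
            n_clipped += 1
            return
        trains[name][max(i0, 0): min(i1, n_hi)] += amp

    box = 0.5  # s
    w_rew, w_act = past_weights
    prev = df.shift(1)
    for i, row in df.iterrows():
        onset = row["t_onset_s"]
        resp_t = onset + row["act_time_s"]
        out_t = resp_t + 4.0
        add_box("resp", onset, box, 1.0)
        add_box("reward", onset, box, row["reward_level"])
        add_box("dotSpeed", onset, box, row["dot_period_ms"] / 100.0)
        add_box("ITI", onset, box, row["iti_s"])
        if i > 0:
            add_box("pastRew", onset, box, w_rew * prev.loc[i, "outcome_drops"])
            add_box("pastactTime", onset, box, w_act * prev.loc[i, "act_time_dots"])
        add_box("actTime", resp_t - box, box, row["act_time_dots"])
        add_box("time", onset, box, onset)
        hand = "rightconv" if row["side"] == "R" else "leftconv"
        add_box(hand, resp_t - box, box, 1.0)
        add_box("mainOut", out_t, box, 1.0)
        add_box("levelOut", out_t, box, row["outcome_drops"])
        # unconvolved distortion regressors on TR boundaries
        tr_resp = np.floor(resp_t / tr) * tr
        uhand = "rightunconv" if row["side"] == "R" else "leftunconv"
        add_box(uhand, tr_resp, tr, 1.0)
        if row["outcome_drops"] > 0:
            tr_out = np.floor(out_t / tr) * tr
            add_box("mouth", tr_out, tr, 1.0)

    t_hi = np.arange(n_hi) * dt
    t_tr = np.arange(n_tr) * tr
    cols = {}
    convolved = {}
    for name in GLM1_CONVOLVED:
        sig = _convolve(trains[name], hrf, dt)
        cols[name] = np.interp(t_tr, t_hi, sig)
        convolved[name] = True
    for name in GLM1_UNCONVOLVED:
        cols[name] = np.interp(t_tr, t_hi, trains[name])
        convolved[name] = False
    frame = pd.DataFrame(cols)
    events = pd.DataFrame(trains)
    return DesignMatrix(
        frame=frame, convolved=convolved, tr=tr, dt=dt, events=events,
        hrf=hrf, n_clipped_events=n_clipped,
    )


def simulate_bold(
    design: DesignMatrix,
    beta: dict[str, float] | np.ndarray,
    noise_sd: float = 1.0,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Synthetic voxel time series: design @ beta + white noise."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if isinstance(beta, dict):
        b = np.array([beta.get(c, 0.0) for c in design.frame.columns])
    else:
        b = np.asarray(beta, dtype=float)
    y = design.frame.to_numpy() @ b
    return y + noise_sd * rng.standard_normal(len(y))


@dataclass
class EpochedSeries:
    """Trial x time matrix of an ROI signal around the response."""

    data: np.ndarray  # (n_trials, n_steps)
    t: np.ndarray     # relative times, s
    dt: float
    n_dropped: int = 0
    kept: np.ndarray | None = None  # indices of retained events


def epoch_timecourse(
    signal: np.ndarray,
    tr: float,
    event_times_s: np.ndarray,
    dt_up: float = 0.1,
    window: tuple[float, float] = (-2.0, 6.0),
    normalize: bool = True,
) -> EpochedSeries:
    """Epoch a (ROI-averaged) session signal around events.

    The signal is z-scored session-wise, linearly up-sampled to ``dt_up``
    and cut into ``window`` epochs relative to each event (default
    -2..+6 s, time zero = response).  If ``signal`` is 2-D
    (voxels x time) it is averaged across voxels first.  Events whose
    window leaves the scan are dropped and counted.
    """
    sig = np.asarray(signal, dtype=float)
    if sig.ndim == 2:
        sig = sig.mean(axis=0)
    if normalize:
        sd = sig.std()
        sig = (sig - sig.mean()) / (sd if sd > 0 else 1.0)
    t_scan = np.arange(len(sig)) * tr
    t_up = np.arange(0.0, t_scan[-1] + 1e-9, dt_up)
    sig_up = np.interp(t_up, t_scan, sig)
    rel = np.arange(window[0], window[1] + 1e-9, dt_up)
    n_steps = len(rel)
    rows, kept = [], []
    n_dropped = 0
    for i, ev in enumerate(np.asarray(event_times_s, dtype=float)):
        i0 = int(np.round((ev + window[0]) / dt_up))
        if i0 < 0 or i0 + n_steps > len(sig_up):
            n_dropped += 1
            continue
        rows.append(sig_up[i0: i0 + n_steps])
        kept.append(i)
    if not rows:
        raise ValueError("no events with complete windows")
    return EpochedSeries(
        data=np.asarray(rows), t=rel, dt=dt_up, n_dropped=n_dropped,
        kept=np.asarray(kept, dtype=int),
    )


def glm2_regressors(det: pd.DataFrame, glm: str = "2.3") -> pd.DataFrame:
    """Trial-level regressor table for the epoched time-course GLMs.

    ``det`` is a per-trial table (responded trials, aligned with the
    epochs) with columns ``act_time_dots``, ``act_time_s``, ``t_onset_s``
    and the deterministic variants ``det_full``/``det_present``/
    ``det_past``.  Variants: "2.1" observed actTime (dots) + session
    time; "2.2" adds log actTime in seconds; "2.3" adds the full
    deterministic actTime as the variable of interest; "2.4" splits it
    into present and past components.
    """
    base = {
        "actTime_dots": det["act_time_dots"].to_numpy(float),
        "time": det["t_onset_s"].to_numpy(float),
    }
    if glm == "2.1":
        cols = base
    elif glm == "2.2":
        cols = {**base, "log_actTime_s": np.log(det["act_time_s"].to_numpy(float))}
    elif glm == "2.3":
        cols = {
            "det_actTime": det["det_full"].to_numpy(float),
            **base,
            "log_actTime_s": np.log(det["act_time_s"].to_numpy(float)),
        }
    elif glm == "2.4":
        cols = {
            "det_present": det["det_present"].to_numpy(float),
            "det_past": det["det_past"].to_numpy(float),
            **base,
            "log_actTime_s": np.log(det["act_time_s"].to_numpy(float)),
        }
    else:
        raise ValueError(f"unknown GLM variant {glm!r}")
    return pd.DataFrame(cols)


@dataclass
class TimecourseBetas:
    """Per-time-step OLS coefficients across trials (one trajectory per
    regressor)."""

    betas: pd.DataFrame     # (n_steps, n_regressors)
    se: pd.DataFrame
    t: np.ndarray

    def trajectory(self, name: str) -> np.ndarray:
        return self.betas[name].to_numpy()

    def plot(self, names=None, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name in names or self.betas.columns:
            ax.plot(self.t, self.betas[name], label=name)
        ax.axvline(0, color="k", lw=0.5)
        ax.set_xlabel("time from response (s)")
        ax.set_ylabel("beta")
        ax.legend()
        return ax


def _check_rank(X: np.ndarray, names: list[str]):
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name near-collinear columns via QR diagnostics
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [names[i] for i in np.nonzero(diag < 1e-8 * max(diag.max(), 1.0))[0]]
        raise RankDeficiencyError(f"rank-deficient design; collinear columns: {bad or names}")


def timecourse_glm(epochs: EpochedSeries, regressors: pd.DataFrame) -> TimecourseBetas:
    """OLS of the epoched signal on trial-level regressors at each step.

    ``regressors`` has one row per (kept) trial; an intercept is added.
    Columns may also be (n_trials, n_steps) arrays passed via a dict —
    see :func:`ppi_glm` for the time-varying case.
    """
    Y = epochs.data
    X = np.column_stack([np.ones(len(Y)), regressors.to_numpy(float)])
    names = ["intercept", *regressors.columns]
    if len(regressors) != len(Y):
        raise ValueError("regressor rows must match epoch trials")
    _check_rank(X, names)
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y  # (p, n_steps)
    resid = Y - X @ B
    dof = max(X.shape[0] - X.shape[1], 1)
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    return TimecourseBetas(
        betas=pd.DataFrame(B.T, columns=names),
        se=pd.DataFrame(se.T, columns=names),
        t=epochs.t,
    )


def ppi_glm(
    target: EpochedSeries,
    seed: EpochedSeries,
    psych: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> TimecourseBetas:
    """Psychophysiological interaction GLM on epoched data.

    At each time step the design is [1, seed BOLD, psychological
    regressor, PPI, covariates], where PPI is the elementwise product of
    the demeaned seed signal (per step) and the demeaned psychological
    variable.  Raises on a constant psychological regressor (PPI would
    be identically the seed scaled).
    """
    psych = np.asarray(psych, dtype=float)
    if np.ptp(psych) == 0:
        raise ValueError("constant psychological regressor: PPI undefined")
    if target.data.shape != seed.data.shape:
        raise ValueError("seed and target epochs must be aligned")
    Y = target.data
    n, n_steps = Y.shape
    psych_d = psych - psych.mean()
    cov = covariates.to_numpy(float) if covariates is not None else np.empty((n, 0))
    cov_names = list(covariates.columns) if covariates is not None else []
    names = ["intercept", "seed", "psych", "PPI", *cov_names]
    B = np.empty((len(names), n_steps))
    SE = np.empty_like(B)
    for j in range(n_steps):
        s = seed.data[:, j]
        ppi = (s - s.mean()) * psych_d
        X = np.column_stack([np.ones(n), s, psych, ppi, cov])
        _check_rank(X, names)
        XtX_inv = np.linalg.inv(X.T @ X)
        b = XtX_inv @ X.T @ Y[:, j]
        r = Y[:, j] - X @ b
        sigma2 = float(r @ r) / max(n - X.shape[1], 1)
        B[:, j] = b
        SE[:, j] = np.sqrt(sigma2 * np.diag(XtX_inv))
    return TimecourseBetas(
        betas=pd.DataFrame(B.T, columns=names),
        se=pd.DataFrame(SE.T, columns=names),
        t=target.t,
    )


def loo_peak_betas(betas: np.ndarray, t: np.ndarray | None = None):
    """Leave-one-out group-peak selection over session beta trajectories.

    For each session the (positive or negative) extremum time of the
    mean trajectory over the *other* sessions is found within the epoch
    window, and that session's beta is read off there, so each peak beta
    is selected independently of its own time course.  Returns
    ``(peak_betas, peak_times)``.
    """
    B = np.asarray(betas, dtype=float)
    n = B.shape[0]
    if n < 3:
        raise ValueError("need at least 3 sessions for leave-one-out peaks")
    peaks = np.empty(n)
    idx = np.empty(n, dtype=int)
    total = B.sum(axis=0)
    for i in range(n):
        mean_others = (total - B[i]) / (n - 1)
        j = int(np.argmax(np.abs(mean_others)))
        idx[i] = j
        peaks[i] = B[i, j]
    times = t[idx] if t is not None else idx
    return peaks, times


def naive_peak_betas(betas: np.ndarray, t: np.ndarray | None = None):
    """Same-session peak picking (biased positive control for LOO)."""
    B = np.asarray(betas, dtype=float)
    idx = np.argmax(np.abs(B), axis=1)
    peaks = B[np.arange(B.shape[0]), idx]
    times = t[idx] if t is not None else idx
    return peaks, times


def connectome_scaling(map_a: np.ndarray, map_b: np.ndarray) -> np.ndarray:
    """Whole-brain coupling scaling factors between two conditions.

    For every seed voxel the whole-brain correlation profile (its row of
    the voxel x voxel correlation matrix, self excluded) is computed
    under condition A and condition B, and B's profile is regressed on
    A's; the slope is that seed's scaling factor (1 = unchanged coupling,
    >1 enhanced, ~0 abolished).  Inputs are (voxels, time) arrays or 4-D
    (x, y, z, time) volumes sharing a grid; zero-variance seeds are
    returned as NaN.
    """
    A = np.asarray(map_a, dtype=float)
    B = np.asarray(map_b, dtype=float)
    shape_out = None
    if A.ndim == 4:
        shape_out = A.shape[:3]
        A = A.reshape(-1, A.shape[-1])
        B = B.reshape(-1, B.shape[-1])
    if A.shape[0] != B.shape[0]:
        raise ValueError("conditions must share the voxel grid")
    va = A.std(axis=1) > 0
    vb = B.std(axis=1) > 0
    valid = va & vb
    n = A.shape[0]
    slopes = np.full(n, np.nan)
    with np.errstate(invalid="ignore"):
        Ca = np.corrcoef(A)
        Cb = np.corrcoef(B)
    off = ~np.eye(n, dtype=bool)
    for i in np.nonzero(valid)[0]:
        cols = off[i] & valid
        xa = Ca[i, cols]
        xb = Cb[i, cols]
        xa_d = xa - xa.mean()
        denom = float(xa_d @ xa_d)
        if denom == 0:
            continue
        slopes[i] = float(xa_d @ (xb - xb.mean())) / denom
    if shape_out is not None:
        return slopes.reshape(shape_out)
    return slopes
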
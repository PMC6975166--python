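"""Multilevel mediation with hierarchical bootstrap inference.

Tests whether a per-trial brain signal M (e.g. the positive epoch peak of
an ROI BOLD time course) mediates the relationship between a contextual
variable X (e.g. the quadratic reward code) and the outcome Y (actTime in
dots).  Per session, three OLS regressions give the classic paths:

    M = i1 + a X  (+ covariates)          path a
    Y = i2 + c' X + b M (+ covariates)    paths b, c'
    Y = i3 + c X  (+ covariates)          total effect c

For OLS with identical covariate sets c = c' + a*b exactly.  Session
estimates are combined by precision (inverse-variance) weighting within
animal and then across animals.  Inference on the indirect effect a*b
uses a hierarchical bootstrap: sessions are resampled with replacement
within each animal, then trials within each resampled session (with only
four animals the animal level is left fixed).  The default p-value for
a*b is the bias-corrected bootstrap p (the standard inference for
indirect effects, whose null distribution has a point-mass spike at 0
that makes the plain percentile test very conservative); the simple
two-sided tail p 2*min(P(ab* <= 0), P(ab* >= 0)) is also reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MultilevelMediation", "MediationResults", "MediationError"]

PATHS = ("a", "b", "c", "cprime", "ab")


class MediationError(ValueError):
    pass


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS coefficients and their variances; raises on singular design."""
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError as err:
        raise MediationError("singular session design") from err
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    if dof <= 0:
        raise MediationError("too few trials for session regression")
    sigma2 = float(resid @ resid) / dof
    return beta, sigma2 * np.diag(XtX_inv)


@dataclass
class _SessionFit:
    a: float
    var_a: float
    b: float
    var_b: float
    c: float
    var_c: float
    cprime: float
    var_cprime: float

    @property
    def ab(self) -> float:
        return self.a * self.b

    @property
    def var_ab(self) -> float:
        # first-order delta method
        return self.a**2 * self.var_b + self.b**2 * self.var_a


def _fit_session(X, M, Y, C) -> _SessionFit:
    n = len(Y)
    ones = np.ones((n, 1))
    A = np.hstack([ones, X[:, None], C])
    a_hat, a_var = _ols(A, M)
    B = np.hstack([ones, X[:, None], M[:, None], C])
    b_hat, b_var = _ols(B, Y)
    c_hat, c_var = _ols(A, Y)
    return _SessionFit(
        a=a_hat[1], var_a=a_var[1],
        b=b_hat[2], var_b=b_var[2],
        c=c_hat[1], var_c=c_var[1],
        cprime=b_hat[1], var_cprime=b_var[1],
    )


def _combine(est: np.ndarray, var: np.ndarray, animal: np.ndarray) -> tuple[float, float]:
    """Precision-weighted mean within animal, then across animals."""
    var = np.maximum(var, 1e-300)
    means, variances = [], []
    for a in np.unique(animal):
        m = animal == a
        w = 1.0 / var[m]
        means.append(float(np.sum(w * est[m]) / np.sum(w)))
        variances.append(1.0 / float(np.sum(w)))
    means = np.asarray(means)
    variances = np.asarray(variances)
    w = 1.0 / variances
    return float(np.sum(w * means) / np.sum(w)), 1.0 / float(np.sum(w))


class MultilevelMediation:
    """Multilevel mediation model X -> M -> Y on nested trial data.

    Parameters
    ----------
    data : DataFrame with one row per trial (complete cases).
    x, m, y : column names of initial variable, mediator and outcome.
    covariates : columns entered as nuisance regressors in every path.
    session_col, animal_col : grouping columns (sessions nested in
        animals; at least 2 sessions required).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        x: str,
        m: str,
        y: str,
        covariates: list[str] | None = None,
        session_col: str = "session_id",
        animal_col: str = "animal_id",
    ):
        covariates = covariates or []
        cols = [x, m, y, *covariates, session_col, animal_col]
        data = data[cols].dropna().reset_index(drop=True)
        if data[session_col].nunique() < 2:
            raise MediationError("need at least 2 sessions")
        self.x, self.m, self.y = x, m, y
        self.covariates = covariates
        self.session_col, self.animal_col = session_col, animal_col
        self.sessions = []
        self.n_dropped = 0
        for sid, g in data.groupby(session_col, sort=False):
            X = g[x].to_numpy(float)
            M = g[m].to_numpy(float)
            if np.var(X) == 0 or np.var(M) == 0:
                raise MediationError(f"zero-variance X or M in session {sid}")
            self.sessions.append(
                dict(
                    id=sid,
                    animal=g[animal_col].iloc[0],
                    X=X,
                    M=M,
                    Y=g[y].to_numpy(float),
                    C=g[covariates].to_numpy(float) if covariates else np.empty((len(g), 0)),
                )
            )

    # -- point estimates -------------------------------------------------

    def _session_fits(self) -> list[_SessionFit]:
        fits = []
        self.n_dropped = 0
        for s in self.sessions:
            try:
                fits.append(_fit_session(s["X"], s["M"], s["Y"], s["C"]))
            except MediationError:
                self.n_dropped += 1
                fits.append(None)
        if all(f is None for f in fits):
            raise MediationError("all session designs singular")
        return fits

    def path_estimates(self) -> pd.DataFrame:
        """Combined path estimates (a, b, c, c', a*b) with variances."""
        fits = self._session_fits()
        keep = [i for i, f in enumerate(fits) if f is not None]
        animal = np.asarray([self.sessions[i]["animal"] for i in keep])
        rows = {}
        for name, attr, vattr in [
            ("a", "a", "var_a"),
            ("b", "b", "var_b"),
            ("c", "c", "var_c"),
            ("cprime", "cprime", "var_cprime"),
            ("ab", "ab", "var_ab"),
        ]:
            est = np.asarray([getattr(fits[i], attr) for i in keep])
            var = np.asarray([getattr(fits[i], vattr) for i in keep])
            e, v = _combine(est, var, animal)
            rows[name] = (e, v)
        return pd.DataFrame(
            {"estimate": {k: v[0] for k, v in rows.items()},
             "var": {k: v[1] for k, v in rows.items()}}
        ).loc[list(PATHS)]

    # -- bootstrap -------------------------------------------------------

    def _batched_session_stats(self, s: dict, idx: np.ndarray) -> np.ndarray:
        """a, var_a, b, var_b for a batch of trial resamples of one session.

        ``idx`` has shape (batch, n_trials).  Returns (batch, 4); rows
        with singular/degenerate designs are NaN (caller redraws).
        """
        n = len(s["Y"])
        ones = np.ones((idx.shape[0], n, 1))
        Xb = s["X"][idx][:, :, None]
        Mb = s["M"][idx]
        Yb = s["Y"][idx]
        Cb = s["C"][idx] if s["C"].shape[1] else np.empty((idx.shape[0], n, 0))
        A = np.concatenate([ones, Xb, Cb], axis=2)
        B = np.concatenate([ones, Xb, Mb[:, :, None], Cb], axis=2)
        out = np.full((idx.shape[0], 4), np.nan)
        for design, yv, (j_est, j_out) in ((A, Mb, (1, 0)), (B, Yb, (2, 2))):
            p = design.shape[2]
            XtX = np.einsum("bnp,bnq->bpq", design, design)
            Xty = np.einsum("bnp,bn->bp", design, yv)
            ok = np.abs(np.linalg.det(XtX)) > 1e-12
            beta = np.full((idx.shape[0], p), np.nan)
            diag = np.full((idx.shape[0], p), np.nan)
            if ok.any():
                inv = np.linalg.inv(XtX[ok])
                beta[ok] = np.einsum("bpq,bq->bp", inv, Xty[ok])
                resid = yv[ok] - np.einsum("bnp,bp->bn", design[ok], beta[ok])
                sigma2 = np.sum(resid**2, axis=1) / (n - p)
                diag[ok] = sigma2[:, None] * np.einsum("bpp->bp", inv)
            out[:, j_out] = beta[:, j_est]
            out[:, j_out + 1] = diag[:, j_est]
        return out

    def fit(self, n_boot: int = 10000, seed: int | np.random.Generator = 0) -> "MediationResults":
        """Point estimates plus hierarchical bootstrap for the indirect effect."""
        if n_boot < 100:
            raise MediationError("n_boot must be >= 100")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        paths = self.path_estimates()

        sessions = self.sessions
        animal_ids = np.asarray([s["animal"] for s in sessions])
        animals = np.unique(animal_ids)
        # session selection per replicate, resampled within animal
        sel: list[np.ndarray] = []  # per replicate: array of session indices
        per_animal_idx = {a: np.nonzero(animal_ids == a)[0] for a in animals}
        choice = {
            a: rng.integers(0, len(per_animal_idx[a]), size=(n_boot, len(per_animal_idx[a])))
            for a in animals
        }
        counts = np.zeros(len(sessions), dtype=int)
        for a in animals:
            picked = per_animal_idx[a][choice[a]]
            counts += np.bincount(picked.ravel(), minlength=len(sessions))

        # pre-generate trial-resampled fits per session
        pools = []
        n_redrawn = 0
        for s_i, s in enumerate(sessions):
            c = int(counts[s_i])
            if c == 0:
                pools.append(np.empty((0, 4)))
                continue
            n = len(s["Y"])
            stats = self._batched_session_stats(s, rng.integers(0, n, size=(c, n)))
            for _ in range(20):
                bad = ~np.isfinite(stats).all(axis=1)
                if not bad.any():
                    break
                n_redrawn += int(bad.sum())
                stats[bad] = self._batched_session_stats(
                    s, rng.integers(0, n, size=(int(bad.sum()), n))
                )
            pools.append(stats)
        cursor = np.zeros(len(sessions), dtype=int)

        ab_star = np.empty(n_boot)
        for b in range(n_boot):
            est_l, var_l, an_l = [], [], []
            for a in animals:
                picked = per_animal_idx[a][choice[a][b]]
                for s_i in picked:
                    st = pools[s_i][cursor[s_i]]
                    cursor[s_i] += 1
                    a_hat, va, b_hat, vb = st
                    est_l.append(a_hat * b_hat)
                    var_l.append(a_hat**2 * vb + b_hat**2 * va)
                    an_l.append(a)
            ab_star[b], _ = _combine(
                np.asarray(est_l), np.asarray(var_l), np.asarray(an_l)
            )

        p_lo = float(np.mean(ab_star <= 0))
        p_hi = float(np.mean(ab_star >= 0))
        p_tail = max(min(1.0, 2.0 * min(p_lo, p_hi)), 1.0 / n_boot)
        # bias-corrected bootstrap p (the toolbox-standard inference for
        # indirect effects; the plain tail p is very conservative under
        # the complete null because a*b has a point mass spike at 0)
        from scipy.stats import norm

        ab_hat = float(paths.loc["ab", "estimate"])
        eps = 1e-6
        F0 = np.clip(np.mean(ab_star <= 0), eps, 1 - eps)
        frac = 0.5 * (np.mean(ab_star < ab_hat) + np.mean(ab_star <= ab_hat))
        z0 = norm.ppf(np.clip(frac, eps, 1 - eps))
        z = norm.ppf(F0) - 2.0 * z0
        p_bc = max(min(1.0, 2.0 * float(min(norm.cdf(z), norm.sf(z)))), 1.0 / n_boot)
        ci = np.percentile(ab_star, [2.5, 97.5])
        return MediationResults(
            paths=paths,
            ab_boot=ab_star,
            p_ab=p_bc,
            p_ab_tail=p_tail,
            ci_ab=(float(ci[0]), float(ci[1])),
            n_boot=n_boot,
            n_redrawn=n_redrawn,
            n_dropped_sessions=self.n_dropped,
        )


@dataclass
class MediationResults:
    """Combined path estimates and bootstrap inference for a*b."""

    paths: pd.DataFrame
    ab_boot: np.ndarray = field(repr=False)
    p_ab: float                 # bias-corrected bootstrap p for a*b
    p_ab_tail: float            # plain two-sided tail p (conservative)
    ci_ab: tuple[float, float]
    n_boot: int
    n_redrawn: int = 0
    n_dropped_sessions: int = 0

    def summary(self) -> pd.DataFrame:
        tab = self.paths.copy()
        tab["se"] = np.sqrt(tab.pop("var"))
        tab.loc["ab", "ci_lo"] = self.ci_ab[0]
        tab.loc["ab", "ci_hi"] = self.ci_ab[1]
        tab.loc["ab", "p_boot"] = self.p_ab
        return tab

    def plot_bootstrap(self, ax=None, bins=50):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.ab_boot, bins=bins, color="steelblue", alpha=0.8)
        ax.axvline(0.0, color="k", lw=1)
        ax.set_xlabel("bootstrap indirect effect a*b")
        ax.set_ylabel("count")
        return ax
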
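"""Band-power summaries and the task x laterality x contact mixed model.

summarize() reduces participant-level dB maps to one mean value per
participant x hemisphere x contact x task x band x window (delta/theta
1-8 Hz and beta 13-30 Hz; prespeech [-500, 0) ms and during-speech
[0, 1000] ms). fit_model() fits, per band x window, the linear mixed model

    mean_power ~ task * laterality * contact + (1 | participant)

by REML (statsmodels MixedLM does the fit) and reports Type-3 F tests with
Satterthwaite denominator degrees of freedom. Fixed factors use sum-to-zero
coding, which Type-3 tests require. The Satterthwaite approximation and the
follow-up (Bonferroni-corrected) pairwise task contrasts are computed here:
for a contrast a, df = 2*(a'Ca)^2 / Var(a'Ca), with C = (X'V^-1 X)^-1,
the variance obtained from the gradient of a'Ca with respect to the two
variance components and the asymptotic covariance of their REML estimates
(inverse Hessian of the restricted deviance). Multi-row terms combine
per-eigenvector dfs as in the standard mixed-model ANOVA practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .containers import BANDS_HZ, EVAL_WINDOW_MS, TASKS, WINDOWS_MS, TFMap

FORMULA = "mean_power ~ C(task, Sum) * C(hemisphere, Sum) * C(contact, Sum)"


def _window_mask(times_ms: np.ndarray, window_ms, name: str) -> np.ndarray:
    lo, hi = window_ms
    if hi >= EVAL_WINDOW_MS[1]:  # terminal window keeps its right edge
        return (times_ms >= lo) & (times_ms <= hi)
    return (times_ms >= lo) & (times_ms < hi)


def summarize(maps: list[TFMap], bands: dict | None = None,
              windows: dict | None = None) -> pd.DataFrame:
    """Tidy band-power table from participant-level task maps.

    maps: one TFMap per participant x hemisphere x task, with the four
    contacts on the channel axis. Returns one row per participant x
    hemisphere x contact x task x band x window; mean_power is the
    arithmetic mean of dB pixels with frequency inside the (inclusive) band
    and time inside the window.
    """
    bands = BANDS_HZ if bands is None else bands
    windows = WINDOWS_MS if windows is None else windows
    rows = []
    for m in maps:
        for band_name, (f_lo, f_hi) in bands.items():
            fmask = (m.freqs_hz >= f_lo) & (m.freqs_hz <= f_hi)
            if not fmask.any():
                raise ValueError(f"no frequencies inside band {band_name}")
            for win_name, win in windows.items():
                tmask = _window_mask(m.times_ms, win, win_name)
                block = m.data[:, fmask][:, :, tmask]
                for ci, contact in enumerate(m.channels):
                    rows.append({
                        "participant_id": m.participant_id,
                        "hemisphere": m.hemisphere,
                        "contact": contact,
                        "task": m.condition,
                        "band": band_name,
                        "window": win_name,
                        "mean_power": float(block[ci].mean()),
                    })
    df = pd.DataFrame(rows)
    keys = ["participant_id", "hemisphere", "contact", "task", "band", "window"]
    if df.duplicated(keys).any():
        raise ValueError("duplicate band-power keys (same map passed twice?)")
    return df.sort_values(keys, ignore_index=True)


# ---------------------------------------------------------------------------
# REML machinery for the random-intercept model


class _RandomInterceptREML:
    """Closed-form pieces of the random-intercept LMM for given variances."""

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        self.y, self.X = y, X
        self.group_rows = [np.flatnonzero(groups == g) for g in pd.unique(groups)]
        self.n, self.p = X.shape

    def _moments(self, s_b: float, s_e: float):
        """X'V^-1 X, X'V^-1 y, y'V^-1 y, log|V| for V = s_e I + s_b ZZ'."""
        p = self.p
        xtvx = np.zeros((p, p))
        xtvy = np.zeros(p)
        ytvy = 0.0
        logdet = 0.0
        for rows in self.group_rows:
            Xg, yg = self.X[rows], self.y[rows]
            ng = rows.size
            w = s_b / (s_e + ng * s_b)
            xs, ys = Xg.sum(axis=0), yg.sum()
            xtvx += (Xg.T @ Xg - w * np.outer(xs, xs)) / s_e
            xtvy += (Xg.T @ yg - w * xs * ys) / s_e
            ytvy += (yg @ yg - w * ys * ys) / s_e
            logdet += (ng - 1) * np.log(s_e) + np.log(s_e + ng * s_b)
        return xtvx, xtvy, ytvy, logdet

    def beta_cov(self, s_b: float, s_e: float):
        """GLS fixed effects and their covariance C = (X'V^-1 X)^-1."""
        xtvx, xtvy, _, _ = self._moments(s_b, s_e)
        C = np.linalg.inv(xtvx)
        return C @ xtvy, C

    def neg2_reml(self, s_b: float, s_e: float) -> float:
        xtvx, xtvy, ytvy, logdet = self._moments(s_b, s_e)
        C = np.linalg.inv(xtvx)
        beta = C @ xtvy
        rss = ytvy - beta @ xtvy
        return logdet + np.linalg.slogdet(xtvx)[1] + rss

    def varcomp_cov(self, s_b: float, s_e: float) -> np.ndarray:
        """Asymptotic covariance of (s_b, s_e): 2 * inv(Hessian of -2*REML)."""
        h = np.array([max(abs(s_b), 1e-6) * 1e-4, max(abs(s_e), 1e-6) * 1e-4])

        def f(t):
            return self.neg2_reml(max(t[0], 1e-12), max(t[1], 1e-12))

        t0 = np.array([s_b, s_e])
        H = np.empty((2, 2))
        for i in range(2):
            for j in range(i, 2):
                ei = np.eye(2)[i] * h[i]
                ej = np.eye(2)[j] * h[j]
                H[i, j] = H[j, i] = (
                    f(t0 + ei + ej) - f(t0 + ei - ej)
                    - f(t0 - ei + ej) + f(t0 - ei - ej)
                ) / (4 * h[i] * h[j])
        return 2.0 * np.linalg.inv(H)

    def contrast_var_grad(self, a: np.ndarray, s_b: float, s_e: float) -> np.ndarray:
        """Gradient of a' C(theta) a with respect to (s_b, s_e)."""
        h = np.array([max(abs(s_b), 1e-6) * 1e-4, max(abs(s_e), 1e-6) * 1e-4])

        def v(t):
            _, C = self.beta_cov(max(t[0], 1e-12), max(t[1], 1e-12))
            return a @ C @ a

        t0 = np.array([s_b, s_e])
        return np.array([
            (v(t0 + np.eye(2)[i] * h[i]) - v(t0 - np.eye(2)[i] * h[i])) / (2 * h[i])
            for i in range(2)])


@dataclass
class LmeResult:
    """Fitted mixed model for one band x window cell."""

    band: str
    window: str
    anova: pd.DataFrame  # term, F, df_num, df_den, p
    params: pd.Series
    participant_var: float
    residual_var: float
    singular: bool
    n_obs: int
    _reml: _RandomInterceptREML = field(repr=False, default=None)
    _design_info: object = field(repr=False, default=None)
    _beta: np.ndarray = field(repr=False, default=None)
    _C: np.ndarray = field(repr=False, default=None)
    _A: np.ndarray = field(repr=False, default=None)


def _satterthwaite_df(reml: _RandomInterceptREML, L: np.ndarray, C: np.ndarray,
                      A: np.ndarray, s_b: float, s_e: float) -> float:
    """Denominator df for the F test of L*beta = 0 (L is q x p)."""
    q = L.shape[0]
    M = L @ C @ L.T
    d, P = np.linalg.eigh(M)
    nus = []
    for m in range(q):
        a = L.T @ P[:, m]
        g = reml.contrast_var_grad(a, s_b, s_e)
        denom = g @ A @ g
        nus.append(2.0 * d[m] ** 2 / denom if denom > 0 else np.inf)
    terms = [nu / (nu - 2.0) for nu in nus if nu > 2.0]
    if not terms:
        return float("inf")
    E = float(np.sum(terms))
    return 2.0 * E / (E - q) if E > q else float("inf")


def fit_model(table: pd.DataFrame, band: str, window: str) -> LmeResult:
    """REML mixed model with Type-3 Satterthwaite F tests for one cell.

    table is a summarize() output (or any frame with the same columns);
    rows are filtered to the requested band and window.
    """
    sub = table[(table["band"] == band) & (table["window"] == window)].copy()
    if sub.empty:
        raise ValueError(f"no rows for band={band!r}, window={window!r}")
    if sub["participant_id"].nunique() < 2:
        raise ValueError("need >= 2 participants to fit a mixed model")
    for col, levels in (("task", set(TASKS)), ("hemisphere", {"left", "right"})):
        if set(sub[col].unique()) != levels:
            raise ValueError(f"all {col} levels must be present")
    sub = sub.sort_values(["participant_id", "hemisphere", "contact", "task"],
                          ignore_index=True)

    y_dm, X_dm = patsy.dmatrices(FORMULA, sub, return_type="dataframe")
    y = np.asarray(y_dm).ravel()
    X = np.asarray(X_dm)
    groups = sub["participant_id"].to_numpy()

    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    ols_var = float(resid @ resid) / max(len(y) - X.shape[1], 1)
    if ols_var <= 1e-12 * max(1.0, float(np.var(y))):
        # noiseless table: both variance components vanish; REML is degenerate
        s_b, s_e = 0.0, max(ols_var, 1e-12)
    else:
        with warnings.catch_warnings():
            # boundary fits (participant variance -> 0) spam retry warnings;
            # we detect and flag that case as `singular` below instead
            warnings.simplefilter("ignore", ConvergenceWarning)
            fit = sm.MixedLM(y, X, groups=groups).fit(reml=True)
        s_b = float(np.asarray(fit.cov_re).ravel()[0])
        s_e = float(fit.scale)
        if not np.isfinite(s_e) or s_e <= 0:
            s_e = 1e-12
        if not np.isfinite(s_b) or s_b < 0:
            s_b = 0.0
    singular = s_b <= 1e-8 * s_e
    if singular:
        s_b = max(s_b, 0.0)
        warnings.warn("participant variance component is ~0 (singular fit); "
                      "reported as 0", UserWarning, stacklevel=2)

    reml = _RandomInterceptREML(y, X, groups)
    beta, C = reml.beta_cov(max(s_b, 1e-12), s_e)
    try:
        A = reml.varcomp_cov(max(s_b, 1e-10 * s_e), s_e)
    except np.linalg.LinAlgError:
        A = np.zeros((2, 2))  # degenerate fit: df falls back to +inf

    design_info = X_dm.design_info
    rows = []
    p_cols = X.shape[1]
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        cols = list(range(p_cols))[sl]
        L = np.zeros((len(cols), p_cols))
        for i, c in enumerate(cols):
            L[i, c] = 1.0
        q = L.shape[0]
        M = L @ C @ L.T
        Lb = L @ beta
        F = float(Lb @ np.linalg.solve(M, Lb) / q)
        df_den = _satterthwaite_df(reml, L, C, A, s_b, s_e)
        p_val = float(stats.f.sf(F, q, df_den)) if np.isfinite(df_den) else float("nan")
        rows.append({"term": term, "F": F, "df_num": q, "df_den": df_den, "p": p_val})

    anova = pd.DataFrame(rows)
    params = pd.Series(beta, index=design_info.column_names)
    return LmeResult(band, window, anova, params,
                     participant_var=0.0 if singular else s_b,
                     residual_var=s_e, singular=singular, n_obs=len(sub),
                     _reml=reml, _design_info=design_info, _beta=beta, _C=C, _A=A)


def _marginal_row(design_info, task: str) -> np.ndarray:
    """Design row for the marginal mean of a task (averaged over the grid)."""
    grid = pd.DataFrame([
        {"task": task, "hemisphere": h, "contact": c}
        for h in ("left", "right") for c in ("1", "2", "3", "4")])
    (mat,) = patsy.build_design_matrices([design_info], grid)
    return np.asarray(mat).mean(axis=0)


def followups(result: LmeResult, family: str = "task") -> pd.DataFrame:
    """Bonferroni-corrected pairwise task contrasts on marginal means.

    Each contrast reports estimate, SE, Satterthwaite df, t, raw and
    adjusted p (raw p times the family size of 3, capped at 1).
    """
    if family != "task":
        raise ValueError("only the pairwise-task family is implemented")
    pairs = [("sentence", "vowel"), ("ddk", "vowel"), ("sentence", "ddk")]
    s_b, s_e = result.participant_var, result.residual_var
    rows = []
    for a_task, b_task in pairs:
        l_vec = _marginal_row(result._design_info, a_task) \
            - _marginal_row(result._design_info, b_task)
        est = float(l_vec @ result._beta)
        var = float(l_vec @ result._C @ l_vec)
        df = _satterthwaite_df(result._reml, l_vec[None, :], result._C, result._A,
                               s_b, s_e)
        t_val = est / np.sqrt(var) if var > 0 else float("nan")
        p_raw = (float(2.0 * stats.t.sf(abs(t_val), df))
                 if np.isfinite(df) and np.isfinite(t_val) else float("nan"))
        rows.append({"contrast": f"{a_task}-{b_task}", "estimate": est,
                     "se": float(np.sqrt(var)), "df": df, "t": t_val,
                     "p_raw": p_raw, "p_bonferroni": min(1.0, p_raw * len(pairs))})
    return pd.DataFrame(rows)
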
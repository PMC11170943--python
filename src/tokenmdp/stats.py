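"""Regressions linking MDP state values to motivated behavior, and the
associated group statistics.

Three headline models are fit per session: log fixation-acquisition RT on
the fixation-state value, log choice RT on the cue-state value and its
within-trial change dV = V_cue - V_fix, and a logistic regression of trial
aborts on the same two regressors.  Feature-level (multivariate) variants
regress directly on NTk, TSCO, NObs and cue condition.  Inference follows
the two-level scheme: one-sample t tests across sessions within each
animal, then an exact one-sided Wilcoxon signed-rank test on the per-animal
mean coefficients across animals (for n = 5 animals, a coherent sign
pattern gives p = 1/32 = 0.0312).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .mdp import ValueTable
from .task import SessionData, TaskConfig

__all__ = [
    "RegressionResult",
    "GroupStats",
    "tukey_filter",
    "fit_fixation_rt",
    "fit_choice_rt",
    "fit_abort_logistic",
    "marginalize_values",
    "multivariate_feature_regressions",
    "group_tests",
    "compare_correlations",
    "kernel_smooth",
]


@dataclass
class RegressionResult:
    """Per-session coefficients of one behavioral regression."""

    model: str                      # fix_rt | choice_rt | abort | multivariate | rw_chosen_value
    params: dict[str, float]
    bse: dict[str, float]
    n: int
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n <= len(self.params):
            raise ValueError("more coefficients than observations")


@dataclass
class GroupStats:
    """Two-level inference on one coefficient across sessions and animals."""

    coef: str
    per_animal_t: dict[str, float]
    per_animal_dof: dict[str, int]
    per_animal_p: dict[str, float]
    animal_means: dict[str, float]
    group_statistic: Optional[float]
    group_p: Optional[float]
    direction: str  # 'less' | 'greater' | 'two-sided'


def tukey_filter(rts: Sequence[float]) -> np.ndarray:
    """Drop RTs outside the Tukey fences q25 - 1.5 IQR, q75 + 1.5 IQR."""
    rts = np.asarray(rts, dtype=float)
    if rts.size < 4:
        warnings.warn("fewer than 4 RTs: Tukey filter passes data through")
        return rts
    q25, q75 = np.percentile(rts, [25, 75])
    iqr = q75 - q25
    keep = (rts >= q25 - 1.5 * iqr) & (rts <= q75 + 1.5 * iqr)
    return rts[keep]


def _tukey_mask(values: np.ndarray) -> np.ndarray:
    if values.size < 4:
        return np.ones(values.size, dtype=bool)
    q25, q75 = np.percentile(values, [25, 75])
    iqr = q75 - q25
    return (values >= q25 - 1.5 * iqr) & (values <= q75 + 1.5 * iqr)


def _trial_values(session: SessionData, values: ValueTable, completed_only=True):
    """Per-attempt frame with V_fix, V_cue, dV and task features."""
    rows = []
    for r in session.records:
        if completed_only and not r.completed:
            continue
        nobs = r.trial // values.config.n_conditions + 1
        v_fix = values.fixation_value(r.tokens_before, r.tsco, nobs)
        v_cue = values.cue_value(r.condition, r.tokens_before, r.tsco, nobs)
        rows.append(
            {
                "v_fix": v_fix,
                "v_cue": v_cue,
                "dv": v_cue - v_fix,
                "ntk": r.tokens_before,
                "tsco": r.tsco,
                "nobs": nobs,
                "condition": r.condition,
                "rt_fix": r.rt_fix if r.rt_fix is not None else np.nan,
                "rt_choice": r.rt_choice if r.rt_choice is not None else np.nan,
                "abort": 0 if r.completed else 1,
                "abort_code": r.abort_code,
                "choice": r.choice,
            }
        )
    return pd.DataFrame(rows)


def _ols(y: np.ndarray, X: pd.DataFrame, model: str) -> RegressionResult:
    for col in X.columns:
        if np.ptp(X[col].to_numpy()) == 0:
            raise ValueError(f"singular design: regressor {col!r} is constant")
    flags = []
    if X.shape[1] == 2:
        r = np.corrcoef(X.iloc[:, 0], X.iloc[:, 1])[0, 1]
        if abs(r) > 0.999:
            flags.append("collinear_regressors")
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    return RegressionResult(
        model=model,
        params=dict(fit.params),
        bse=dict(fit.bse),
        n=int(fit.nobs),
        flags=flags,
    )


def fit_fixation_rt(session: SessionData, values: ValueTable) -> RegressionResult:
    """OLS of log fixation-acquisition RT on the fixation-state value."""
    df = _trial_values(session, values).dropna(subset=["rt_fix"])
    keep = _tukey_mask(df["rt_fix"].to_numpy())
    df = df[keep]
    return _ols(np.log(df["rt_fix"].to_numpy()), df[["v_fix"]], "fix_rt")


def fit_choice_rt(session: SessionData, values: ValueTable) -> RegressionResult:
    """OLS of log choice RT on the cue-state value and dV = V_cue - V_fix."""
    df = _trial_values(session, values).dropna(subset=["rt_choice"])
    keep = _tukey_mask(df["rt_choice"].to_numpy())
    df = df[keep]
    return _ols(np.log(df["rt_choice"].to_numpy()), df[["v_cue", "dv"]], "choice_rt")


def _logistic(y: np.ndarray, X: pd.DataFrame, model: str) -> RegressionResult:
    if y.min() == y.max():
        raise ValueError("outcome has no variation (e.g., zero aborts): separation")
    Xc = sm.add_constant(X)
    flags: list[str] = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        params = dict(fit.params)
        bse = dict(fit.bse)
    except Exception:
        # ridge fallback on (quasi-)separation
        params_arr, bse_arr = _ridge_logit(y, Xc.to_numpy())
        params = dict(zip(Xc.columns, params_arr))
        bse = dict(zip(Xc.columns, bse_arr))
        flags.append("separation_penalized")
    return RegressionResult(model=model, params=params, bse=bse, n=len(y), flags=flags)


def _ridge_logit(y: np.ndarray, X: np.ndarray, lam: float = 1e-6):
    """Newton iterations on the ridge-penalized logistic log-likelihood."""
    beta = np.zeros(X.shape[1])
    for _ in range(100):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p)
        grad = X.T @ (y - p) - lam * beta
        H = (X.T * W) @ X + lam * np.eye(X.shape[1])
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    cov = np.linalg.inv(H)
    return beta, np.sqrt(np.diag(cov))


def fit_abort_logistic(session: SessionData, values: ValueTable) -> RegressionResult:
    """Logistic regression of the abort indicator on V_cue and dV, over all
    attempts (completed and aborted)."""
    df = _trial_values(session, values, completed_only=False)
    return _logistic(df["abort"].to_numpy(), df[["v_cue", "dv"]], "abort")


def marginalize_values(values: ValueTable, feature: str) -> ValueTable:
    """Average state values over one feature's feasible range.

    Removing a feature replaces u at each state with the mean over all
    feasible levels of that feature given the co-features; feasibility
    limits NTk to at most 2 * TSCO.  Marginalizing the cue condition ('TE')
    averages the six cue epochs into each of them, leaving the other epochs
    untouched.
    """
    u = values.u
    K, S, E, N = u.shape
    cfg = values.config
    gain = max(d for d in cfg.cue_deltas if d > 0)
    out = u.copy()
    if feature == "NTk":
        for s in range(S):
            kmax = min(gain * (s + 1), K - 1)
            out[:, s, :, :] = u[: kmax + 1, s, :, :].mean(axis=0, keepdims=True)
    elif feature == "TSCO":
        for k in range(K):
            smin = max(int(np.ceil(k / gain)), 1)
            out[k, :, :, :] = u[k, smin - 1 :, :, :].mean(axis=0, keepdims=True)
    elif feature == "NObs":
        out[:] = u.mean(axis=3, keepdims=True)
    elif feature == "TE":
        cue_slice = slice(1, 1 + cfg.n_conditions)
        out[:, :, cue_slice, :] = u[:, :, cue_slice, :].mean(axis=2, keepdims=True)
    else:
        raise ValueError(f"unknown feature {feature!r}")
    return ValueTable(
        u=out, config=cfg, gamma=values.gamma,
        sweeps_run=values.sweeps_run, converged=values.converged,
    )


def multivariate_feature_regressions(
    session: SessionData,
    values: Optional[ValueTable] = None,
    rw_params=None,
    config: Optional[TaskConfig] = None,
) -> dict[str, RegressionResult]:
    """The five feature-level regressions.

    1. log fixation RT ~ NTk + TSCO + NObs (OLS)
    2. log choice RT ~ NTk + TSCO + NObs + condition (OLS, condition 1 ref)
    3. log choice RT ~ RW chosen value (OLS; needs ``rw_params``)
    4. fixation aborts ~ NTk + TSCO + NObs (logistic)
    5. choice aborts ~ NTk + TSCO + NObs + condition (logistic)

    Aborts are split by stage because before cue onset the condition is
    unknown to the animal.  Missing submodels are flagged, not raised.
    """
    config = config or (values.config if values is not None else TaskConfig())
    dummy_table = values or ValueTable(
        u=np.zeros(
            (config.max_tokens + 1, config.tsco_max, config.n_epochs, config.nobs_max)
        ),
        config=config, gamma=0.0, sweeps_run=0, converged=True,
    )
    df = _trial_values(session, dummy_table, completed_only=False)
    results: dict[str, RegressionResult] = {}

    def cond_dummies(frame: pd.DataFrame) -> pd.DataFrame:
        X = frame[["ntk", "tsco", "nobs"]].astype(float).copy()
        for c in range(2, config.n_conditions + 1):
            X[f"cond{c}"] = (frame["condition"] == c).astype(float)
        return X

    comp = df[df["abort"] == 0]
    fix_ok = comp.dropna(subset=["rt_fix"])
    keep = _tukey_mask(fix_ok["rt_fix"].to_numpy())
    fix_ok = fix_ok[keep]
    results["fix_rt_features"] = _ols(
        np.log(fix_ok["rt_fix"].to_numpy()),
        fix_ok[["ntk", "tsco", "nobs"]].astype(float),
        "multivariate",
    )
    ch_ok = comp.dropna(subset=["rt_choice"])
    keep = _tukey_mask(ch_ok["rt_choice"].to_numpy())
    ch_ok = ch_ok[keep]
    results["choice_rt_features"] = _ols(
        np.log(ch_ok["rt_choice"].to_numpy()), cond_dummies(ch_ok), "multivariate"
    )
    if rw_params is not None:
        chosen_v = _rw_chosen_values(session, rw_params, config)
        sub = comp.dropna(subset=["rt_choice"]).copy()
        sub["rw_chosen"] = chosen_v[sub.index]
        keep = _tukey_mask(sub["rt_choice"].to_numpy())
        sub = sub[keep]
        results["choice_rt_rw_chosen"] = _ols(
            np.log(sub["rt_choice"].to_numpy()),
            sub[["rw_chosen"]],
            "rw_chosen_value",
        )
    # fixation-stage aborts: fixation aborts vs attempts that acquired fixation
    fix_stage = df.copy()
    fix_stage["y"] = (fix_stage["abort_code"] == "fixation_abort").astype(int)
    try:
        results["fixation_abort_features"] = _logistic(
            fix_stage["y"].to_numpy(),
            fix_stage[["ntk", "tsco", "nobs"]].astype(float),
            "multivariate",
        )
    except ValueError:
        pass
    # choice-stage aborts among attempts that reached cue onset
    cue_stage = df[df["abort_code"] != "fixation_abort"].copy()
    cue_stage["y"] = (cue_stage["abort_code"] == "choice_abort").astype(int)
    try:
        results["choice_abort_features"] = _logistic(
            cue_stage["y"].to_numpy(), cond_dummies(cue_stage), "multivariate"
        )
    except ValueError:
        pass
    return results


def _rw_chosen_values(session: SessionData, rw_params, config: TaskConfig) -> np.ndarray:
    """Model-derived value of the chosen option per attempt (NaN on aborts)."""
    alpha = np.asarray(rw_params.alpha)
    out = np.full(len(session.records), np.nan)
    current_block = -1
    v = np.zeros(len(config.cue_deltas))
    for idx, r in enumerate(session.records):
        if r.block != current_block:
            v = np.zeros(len(config.cue_deltas))
            current_block = r.block
        if not r.completed:
            continue
        out[idx] = v[r.choice]
        R = r.delta_tokens if r.delivered else 0.0
        v[r.choice] += alpha[r.choice] * (R - v[r.choice])
    return out


def group_tests(
    coefs_by_animal: dict[str, Sequence[float]],
    coef: str = "",
    direction: str = "less",
) -> GroupStats:
    """Per-animal one-sample t tests across sessions, then an exact
    one-sided Wilcoxon signed-rank test on the per-animal means."""
    per_t, per_dof, per_p, means = {}, {}, {}, {}
    for animal, vals in coefs_by_animal.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 2:
            raise ValueError("need >= 2 sessions per animal for the t test")
        t, p = sps.ttest_1samp(vals, 0.0)
        per_t[animal] = float(t)
        per_dof[animal] = int(vals.size - 1)
        per_p[animal] = float(p)
        means[animal] = float(vals.mean())
    if len(means) >= 2:
        res = sps.wilcoxon(
            list(means.values()), alternative=direction, method="exact"
        )
        g_stat, g_p = float(res.statistic), float(res.pvalue)
    else:
        g_stat = g_p = None
    return GroupStats(
        coef=coef,
        per_animal_t=per_t,
        per_animal_dof=per_dof,
        per_animal_p=per_p,
        animal_means=means,
        group_statistic=g_stat,
        group_p=g_p,
        direction=direction,
    )


def compare_correlations(r1: float, r2: float, n: int) -> float:
    """Two-sided p for a difference between two correlations via Fisher z."""
    if not (abs(r1) < 1 and abs(r2) < 1):
        raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n <= 3:
        raise ValueError("need n > 3")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(2.0 / (n - 3))
    return float(2.0 * sps.norm.sf(abs(z)))


def kernel_smooth(
    x: Sequence[float],
    y: Sequence[float],
    grid: Optional[Sequence[float]] = None,
    bandwidth: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Nadaraya-Watson estimate with a Gaussian kernel (bandwidth in value
    units).  Returns (grid, smoothed)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 50) if x.size > 1 else x.copy()
    grid = np.asarray(grid, dtype=float)
    w = np.exp(-0.5 * ((grid[:, None] - x[None, :]) / bandwidth) ** 2)
    return grid, (w @ y) / w.sum(axis=1)
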
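"""Calibration of the MDP's two free parameters and the discount sweep.

The cue -> outcome transition probabilities inherit learning speed from the
Rescorla-Wagner mean cue-value curves; a scale factor k on those means
(which modulates their separation relative to the fixed per-stage sigma)
and a softmax inverse temperature beta jointly determine how fast the
model's choice-probability curves rise.  Both are fit by minimizing the
RMSE between the model's 6 x 18 choice-probability matrix and the
empirical fraction of better-option choices, then the state values are
re-solved at the fitted k.  The discount factor is not fit freely: a small
candidate set is swept and scored by the residual error of the three
behavioral regressions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .mdp import Policy, TransitionModel, ValueTable, build_transition_model, value_iteration
from .rw import CueValueCurves
from .task import SessionData, TaskConfig

__all__ = [
    "MDPFitParams",
    "empirical_choice_curves",
    "model_choice_curves",
    "fit_k_beta",
    "sweep_gamma",
    "better_action",
]

GAMMA_CANDIDATES = (0.8, 0.85, 0.9, 0.95, 0.99, 0.999)


@dataclass
class MDPFitParams:
    """Fitted scale k, inverse temperature beta, discount and fit error."""

    k: float
    beta_mdp: float
    gamma: float
    rmse: float

    def __post_init__(self) -> None:
        if self.k <= 0 or self.beta_mdp < 0 or not (0 < self.gamma < 1) or self.rmse < 0:
            raise ValueError("invalid MDP fit parameters")


def better_action(condition: int, config: TaskConfig) -> int:
    """Index (0 or 1) within the condition's cue pair of the higher-delta cue."""
    pair = config.condition_pairs()[condition]
    return int(np.argmax([config.cue_deltas[c] for c in pair]))


def empirical_choice_curves(
    sessions: Sequence[SessionData], config: Optional[TaskConfig] = None
) -> np.ndarray:
    """Fraction of better-option choices per condition per NObs.

    Presentations are indexed by occurrence order within each block (1-18),
    averaged across blocks, then across sessions.  Cells with no trials are
    NaN (flagged missing).
    """
    config = config or TaskConfig()
    if not any(s.completed_trials() for s in sessions):
        raise ValueError("no completed trials in any session")
    pairs = config.condition_pairs()
    C, N = config.n_conditions, config.nobs_max
    per_session = []
    for session in sessions:
        num = np.zeros((C, N))
        den = np.zeros((C, N))
        for b in range(session.n_blocks()):
            seen = {c: 0 for c in pairs}
            for r in session.block_records(b):
                if not r.completed:
                    continue
                c = r.condition
                n = seen[c]
                seen[c] += 1
                if n >= N:
                    continue
                pair = pairs[c]
                best = pair[better_action(c, config)]
                num[c - 1, n] += 1.0 if r.choice == best else 0.0
                den[c - 1, n] += 1.0
        with np.errstate(invalid="ignore"):
            per_session.append(np.where(den > 0, num / den, np.nan))
    return np.nanmean(np.stack(per_session), axis=0)


def model_choice_curves(
    policy: Policy, beta_mdp: float, config: Optional[TaskConfig] = None
) -> np.ndarray:
    """MDP choice-probability matrix: P(better option) per condition per
    NObs, softmax over action values, averaged uniformly over the feasible
    (NTk, TSCO) cells."""
    config = config or policy.config
    C, N = config.n_conditions, config.nobs_max
    K = config.max_tokens + 1
    S = config.tsco_max
    gain = max(d for d in config.cue_deltas if d > 0)
    ntk = np.arange(K)[:, None]
    tsco = np.arange(1, S + 1)[None, :]
    feasible = ntk <= gain * tsco  # [K, S]
    out = np.empty((C, N))
    for c in range(C):
        a_best = better_action(c + 1, config)
        dq = policy.q[c, a_best] - policy.q[c, 1 - a_best]  # [K, S, N]
        p = 1.0 / (1.0 + np.exp(-beta_mdp * dq))
        out[c] = p[feasible].mean(axis=0)
    return out


def _rmse(model: np.ndarray, empirical: np.ndarray) -> float:
    mask = ~np.isnan(empirical)
    return float(np.sqrt(np.mean((model[mask] - empirical[mask]) ** 2)))


def fit_k_beta(
    curves: CueValueCurves,
    empirical: np.ndarray,
    gamma: float = 0.999,
    config: Optional[TaskConfig] = None,
    sweeps: int = 100,
    n_restarts: int = 4,
    k_bounds: tuple[float, float] = (0.05, 5.0),
    beta_bounds: tuple[float, float] = (0.0, 20.0),
) -> tuple[MDPFitParams, ValueTable, Policy, TransitionModel]:
    """Joint RMSE fit of (k, beta) by bounded Nelder-Mead with restarts,
    then re-solve the MDP at the fitted k until policy and values are
    stable again."""
    config = config or curves.config or TaskConfig()
    if np.all(np.isnan(empirical)):
        raise ValueError("empirical choice matrix is entirely missing")

    cache: dict[float, tuple[ValueTable, Policy]] = {}

    def solve(k: float) -> tuple[ValueTable, Policy]:
        if k not in cache:
            tm = build_transition_model(curves, k=k, config=config)
            cache[k] = value_iteration(tm, gamma=gamma, sweeps=sweeps)
        return cache[k]

    def objective(x: np.ndarray) -> float:
        k = float(np.clip(x[0], *k_bounds))
        beta = float(np.clip(x[1], *beta_bounds))
        _, policy = solve(k)
        return _rmse(model_choice_curves(policy, beta, config), empirical)

    starts = [(0.5, 2.0), (1.0, 1.0), (1.5, 4.0), (0.25, 6.0)][:n_restarts]
    best = None
    for x0 in starts:
        res = minimize(
            objective,
            np.asarray(x0),
            method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 300},
        )
        if best is None or res.fun < best.fun:
            best = res
    k = float(np.clip(best.x[0], *k_bounds))
    beta = float(np.clip(best.x[1], *beta_bounds))

    # Reconverge at the fitted parameters: alternate transition rebuild and
    # value iteration until the greedy policy stops changing.
    tm = build_transition_model(curves, k=k, config=config)
    table, policy = value_iteration(tm, gamma=gamma, sweeps=sweeps)
    for _ in range(4):
        table2, policy2 = value_iteration(tm, gamma=gamma, sweeps=sweeps)
        stable = np.array_equal(policy2.greedy, policy.greedy)
        table, policy = table2, policy2
        if stable:
            break
    rmse = _rmse(model_choice_curves(policy, beta, config), empirical)
    return MDPFitParams(k=k, beta_mdp=beta, gamma=gamma, rmse=rmse), table, policy, tm


def sweep_gamma(
    sessions: Sequence[SessionData],
    curves: CueValueCurves,
    candidates: Sequence[float] = GAMMA_CANDIDATES,
    config: Optional[TaskConfig] = None,
) -> tuple[float, dict]:
    """Fit an MDP per candidate discount and score each by the mean residual
    variance of the three behavioral regressions; return the best candidate
    and per-candidate diagnostics."""
    from .stats import fit_abort_logistic, fit_choice_rt, fit_fixation_rt

    if not candidates:
        raise ValueError("empty candidate list")
    config = config or curves.config or TaskConfig()
    empirical = empirical_choice_curves(sessions, config)
    diagnostics: dict[float, dict] = {}
    best_gamma, best_err = None, np.inf
    for gamma in candidates:
        fitp, table, policy, _ = fit_k_beta(curves, empirical, gamma=gamma, config=config)
        residvars = []
        for session in sessions:
            for fit_fn, rt_col in (
                (fit_fixation_rt, "rt_fix"),
                (fit_choice_rt, "rt_choice"),
            ):
                res = fit_fn(session, table)
                residvars.append(_regression_residual_variance(session, table, res))
            try:
                res_a = fit_abort_logistic(session, table)
                residvars.append(_abort_residual_variance(session, table, res_a))
            except ValueError:
                pass
        err = float(np.mean(residvars))
        diagnostics[gamma] = {"fit": fitp, "regression_error": err}
        if err < best_err:
            best_gamma, best_err = gamma, err
    return best_gamma, diagnostics


def _regression_residual_variance(session, table, res) -> float:
    from .stats import _trial_values, _tukey_mask

    df = _trial_values(session, table)
    col = "rt_fix" if res.model == "fix_rt" else "rt_choice"
    df = df.dropna(subset=[col])
    df = df[_tukey_mask(df[col].to_numpy())]
    y = np.log(df[col].to_numpy())
    if res.model == "fix_rt":
        pred = res.params["const"] + res.params["v_fix"] * df["v_fix"].to_numpy()
    else:
        pred = (
            res.params["const"]
            + res.params["v_cue"] * df["v_cue"].to_numpy()
            + res.params["dv"] * df["dv"].to_numpy()
        )
    return float(np.var(y - pred))


def _abort_residual_variance(session, table, res) -> float:
    from .stats import _trial_values

    df = _trial_values(session, table, completed_only=False)
    eta = (
        res.params["const"]
        + res.params["v_cue"] * df["v_cue"].to_numpy()
        + res.params["dv"] * df["dv"].to_numpy()
    )
    p = 1.0 / (1.0 + np.exp(-eta))
    return float(np.var(df["abort"].to_numpy() - p))
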
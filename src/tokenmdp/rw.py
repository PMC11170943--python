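"""Rescorla-Wagner learning model: per-cue value updates, softmax choice,
maximum-likelihood fitting, and extraction of the mean cue-value curves
that parameterize the MDP's cue -> token-outcome transitions.

The model carries one value estimate per cue image, updated only for the
chosen cue with a cue-specific learning rate,

    v_i(t+1) = v_i(t) + alpha_i (R - v_i(t)),

where R is the realized token change (zero on the 25% of trials where the
outcome is not delivered).  Choices between the two displayed cues follow a
logistic softmax with a single inverse temperature shared across the six
conditions.  Values reset to zero at every block start because each block
uses four novel images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .task import SessionData, TaskConfig

__all__ = [
    "RWParams",
    "CueValueCurves",
    "rw_update",
    "choice_prob",
    "negative_log_likelihood",
    "fit_rw",
    "cue_observation_trajectories",
    "extract_mean_curves",
]


@dataclass(frozen=True)
class RWParams:
    """Learning rates (one per cue, in cue order +2, +1, -1, -2) and the
    softmax inverse temperature."""

    alpha: tuple[float, float, float, float]
    beta: float

    def __post_init__(self) -> None:
        if any(not (0.0 <= a <= 1.0) for a in self.alpha):
            raise ValueError("learning rates must lie in [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")


@dataclass
class CueValueCurves:
    """Mean cue-value learning curves.

    ``raw`` is [n_cues, 54]: the value estimate averaged across blocks at
    each per-cue observation count (each cue appears in three of the six
    conditions, hence 3 x 18 observations per block).  ``collapsed`` is
    [n_cues, 18]: consecutive triples averaged, indexing learning by the
    number of times a cue *pair* has been seen.  ``sigma`` is the per-index
    dispersion (across-block SD, averaged over cues) shared by all cues in
    the Gaussian outcome likelihood.
    """

    raw: np.ndarray
    collapsed: np.ndarray
    sigma: np.ndarray
    config: Optional[TaskConfig] = None

    def __post_init__(self) -> None:
        if self.collapsed.shape[1] != self.sigma.shape[0]:
            raise ValueError("sigma length must match collapsed curve length")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")


def rw_update(v: float, R: float, alpha: float) -> float:
    """Single delta-rule update of the chosen cue's value."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    return v + alpha * (R - v)


def choice_prob(v_i: float, v_j: float, beta: float) -> tuple[float, float]:
    """Softmax probabilities (d_i, d_j) of choosing options i and j."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    d_j = 1.0 / (1.0 + np.exp(beta * (v_i - v_j)))
    return 1.0 - d_j, d_j


def _session_arrays(session: SessionData, config: TaskConfig):
    """Per-block arrays (cue_a, cue_b, chosen, R) over completed trials."""
    pairs = config.condition_pairs()
    blocks = []
    for b in range(session.n_blocks()):
        recs = [r for r in session.block_records(b) if r.completed]
        if not recs:
            continue
        cue_a = np.array([pairs[r.condition][0] for r in recs])
        cue_b = np.array([pairs[r.condition][1] for r in recs])
        chosen = np.array([r.choice for r in recs])
        R = np.array(
            [r.delta_tokens if r.delivered else 0.0 for r in recs], dtype=float
        )
        blocks.append((cue_a, cue_b, chosen, R))
    return blocks


def negative_log_likelihood(
    params: np.ndarray, blocks, n_cues: int = 4, eps: float = 1e-12
) -> float:
    """-log f(D | alpha, beta) over all completed trials, values resetting
    to zero at each block start."""
    alpha = params[:n_cues]
    beta = params[n_cues]
    nll = 0.0
    for cue_a, cue_b, chosen, R in blocks:
        v = np.zeros(n_cues)
        for t in range(len(chosen)):
            i, j, ch = cue_a[t], cue_b[t], chosen[t]
            d_j = 1.0 / (1.0 + np.exp(beta * (v[i] - v[j])))
            p = d_j if ch == j else 1.0 - d_j
            nll -= np.log(max(p, eps))
            v[ch] += alpha[ch] * (R[t] - v[ch])
    return nll


def fit_rw(
    session: SessionData,
    config: Optional[TaskConfig] = None,
    n_starts: int = 5,
    seed: int = 0,
    beta_max: float = 50.0,
) -> tuple[RWParams, float]:
    """Maximum-likelihood fit of (alpha_1..4, beta) to one session.

    Multi-start bounded quasi-Newton (L-BFGS-B); the starting points are
    drawn from a fixed-seed generator so the fit is deterministic.  Returns
    the parameters and the maximized log-likelihood.
    """
    config = config or TaskConfig()
    blocks = _session_arrays(session, config)
    if not blocks:
        raise ValueError("session contains no completed trials")
    n_cues = len(config.cue_deltas)
    bounds = [(0.0, 1.0)] * n_cues + [(0.0, beta_max)]
    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        if s == 0:
            x0 = np.array([0.2] * n_cues + [2.0])
        else:
            x0 = np.concatenate(
                [rng.uniform(0.02, 0.8, n_cues), rng.uniform(0.2, 8.0, 1)]
            )
        res = minimize(
            negative_log_likelihood,
            x0,
            args=(blocks, n_cues),
            method="L-BFGS-B",
            bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    params = RWParams(alpha=tuple(best.x[:n_cues]), beta=float(best.x[n_cues]))
    return params, -float(best.fun)


def cue_observation_trajectories(
    session: SessionData, params: RWParams, config: Optional[TaskConfig] = None
) -> np.ndarray:
    """Replay a session under fitted parameters, recording each cue's value
    at the moment of its n-th presentation (before that trial's update).

    Returns [n_blocks, n_cues, n_obs_per_cue]; blocks whose schedule did not
    complete are padded with NaN.
    """
    config = config or TaskConfig()
    pairs = config.condition_pairs()
    n_cues = len(config.cue_deltas)
    appearances = [
        sum(1 for p in pairs.values() if cue in p) * config.presentations_per_condition
        for cue in range(n_cues)
    ]
    per_cue = max(appearances)
    n_blocks = session.n_blocks()
    traj = np.full((n_blocks, n_cues, per_cue), np.nan)
    alpha = np.asarray(params.alpha)
    for b in range(n_blocks):
        v = np.zeros(n_cues)
        seen = np.zeros(n_cues, dtype=int)
        for r in session.block_records(b):
            if not r.completed:
                continue
            for cue in pairs[r.condition]:
                if seen[cue] < per_cue:
                    traj[b, cue, seen[cue]] = v[cue]
                seen[cue] += 1
            R = r.delta_tokens if r.delivered else 0.0
            ch = r.choice
            v[ch] += alpha[ch] * (R - v[ch])
    return traj


def extract_mean_curves(
    trajectories: np.ndarray, config: Optional[TaskConfig] = None
) -> CueValueCurves:
    """Average per-cue value trajectories into mean curves and collapse the
    three per-condition observations onto the cue-pair observation index.

    ``trajectories`` is [n_blocks, n_cues, 54] (stack blocks across sessions
    before calling).  The dispersion at each collapsed index is the standard
    deviation across blocks of the collapsed value, averaged over cues --
    one sigma per learning stage, shared by all cues.
    """
    config = config or TaskConfig()
    traj = np.asarray(trajectories, dtype=float)
    if traj.ndim != 3:
        raise ValueError("trajectories must be [n_blocks, n_cues, n_obs]")
    n_blocks, n_cues, n_obs = traj.shape
    n_collapsed = config.nobs_max
    fold = n_obs // n_collapsed
    if fold * n_collapsed != n_obs:
        raise ValueError("observation count not divisible by collapsed length")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        raw = np.nanmean(traj, axis=0)  # [n_cues, n_obs]
        per_block = traj.reshape(n_blocks, n_cues, n_collapsed, fold)
        collapsed_blocks = np.nanmean(per_block, axis=3)  # [n_blocks, n_cues, 18]
        collapsed = np.nanmean(collapsed_blocks, axis=0)
        if n_blocks > 1:
            sd = np.nanstd(collapsed_blocks, axis=0, ddof=1)  # [n_cues, 18]
            sigma = np.nanmean(sd, axis=0)
        else:
            sigma = np.zeros(n_collapsed)
    sigma = np.nan_to_num(sigma, nan=0.0)
    return CueValueCurves(raw=raw, collapsed=collapsed, sigma=sigma, config=config)
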
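"""Tabular MDP of the tokens task and its value-iteration solver.

A task state is the tuple (NTk, TSCO, TE, NObs): accumulated tokens (0-12),
trials since the last cash-out (1-6), task epoch (fixation, one of the six
cue conditions, token outcome, cash-out, ITI) and the number of times each
cue pair has been observed in the block (1-18).  Juice is delivered only in
the cash-out epoch (one drop per token), so every other state inherits its
value from discounted future cash-outs.

Transitions are fixed by the task design (fixation -> cue pair with
probability 1/6 each; outcome -> cash-out with the TSCO hazard) except for
the cue -> token-outcome step, which encodes the animal's *learned* mapping
of cue images to outcomes: a Bayesian posterior over the four non-zero token
changes, built from the Rescorla-Wagner mean cue-value curves, rescaled by
the 0.75 delivery probability (the no-change outcome always has
probability 0.25).

Within the table, the TSCO stored in ITI states is the *upcoming* trial's
TSCO (it has already been incremented, or reset to 1 after a cash-out);
fixation, cue and outcome epochs carry the current trial's TSCO, which is
what the cash-out hazard and the behavioral regressions use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .task import TaskConfig, cashout_hazard

__all__ = [
    "MDPState",
    "TransitionModel",
    "ValueTable",
    "Policy",
    "enumerate_states",
    "outcome_posterior",
    "build_transition_model",
    "value_iteration",
    "value_iteration_dense",
    "mdp_choice_prob",
]


@dataclass(frozen=True)
class MDPState:
    """One task state; fields use the task's 1-based TE convention
    (1 = fixation, 2-7 = cue conditions, 8 = outcome, 9 = cash-out,
    10 = ITI for the default six-condition task)."""

    ntk: int
    tsco: int
    te: int
    nobs: int


def _max_gain(config: TaskConfig) -> int:
    return max(d for d in config.cue_deltas if d > 0)


def enumerate_states(config: TaskConfig, prune_infeasible: bool = False) -> list[MDPState]:
    """All (NTk, TSCO, TE, NObs) combinations; optionally drop states the
    token dynamics cannot reach (NTk exceeding ``max_gain * TSCO``)."""
    gain = _max_gain(config)
    states = []
    for ntk in range(config.max_tokens + 1):
        for tsco in range(1, config.tsco_max + 1):
            if prune_infeasible and ntk > gain * tsco:
                continue
            for te in range(1, config.n_epochs + 1):
                for nobs in range(1, config.nobs_max + 1):
                    states.append(MDPState(ntk, tsco, te, nobs))
    return states


def _outcome_deltas(config: TaskConfig) -> tuple[int, ...]:
    """Token-change support in display order, zero included: (+2, +1, 0, -1, -2)."""
    return tuple(sorted(set(config.cue_deltas) | {0}, reverse=True))


def outcome_posterior(
    mu: np.ndarray,
    sigma: float,
    choice: int,
    deliver_prob: float = 0.75,
    cue_deltas: Sequence[int] = (2, 1, -1, -2),
) -> np.ndarray:
    """Posterior over token outcomes given the chosen cue's learned value.

    ``mu`` holds the (already k-scaled) mean cue values in delta-descending
    cue order (+2, +1, -1, -2); ``choice`` indexes the chosen cue.  An
    outcome is delivered at all with probability ``deliver_prob``;
    conditional on delivery the non-zero outcomes carry uniform priors, and
    the likelihood of the chosen cue's value under outcome j is Gaussian
    around cue j's mean with a common standard deviation ``sigma`` (the
    priors cancel in the ratio).  Returns probabilities in the order
    (+2, +1, 0, -1, -2), with p(0) = 1 - deliver_prob exactly.
    """
    mu = np.asarray(mu, dtype=float)
    if sigma <= 0:
        raise ValueError("sigma must be positive (degenerate likelihood otherwise)")
    x = mu[choice]
    log_like = -0.5 * ((x - mu) / sigma) ** 2
    like = np.exp(log_like - log_like.max())
    post = like / like.sum()
    n_gain = sum(1 for d in cue_deltas if d > 0)
    out = np.empty(len(mu) + 1)
    out[:n_gain] = deliver_prob * post[:n_gain]
    out[n_gain] = 1.0 - deliver_prob
    out[n_gain + 1 :] = deliver_prob * post[n_gain:]
    return out


@dataclass
class TransitionModel:
    """All state-transition distributions of the task MDP.

    ``outcome_dist[cue, nobs-1]`` is p(token change | chosen cue, NObs) in
    the order (+2, +1, 0, -1, -2).  At NObs = 1 the animal has not yet seen
    any outcome for the new images, so the distribution is the uninformed
    prior (0.25 for no change, 0.75/4 for each non-zero outcome).
    """

    config: TaskConfig
    outcome_dist: np.ndarray          # [n_cues, nobs_max, n_deltas+1]
    k: float = 1.0
    nobs_wrap: bool = False
    nobs_advance_prob: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.nobs_advance_prob is None:
            self.nobs_advance_prob = 1.0 / self.config.n_conditions
        rows = self.outcome_dist.reshape(-1, self.outcome_dist.shape[-1])
        if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("non-stochastic outcome-transition row")

    @property
    def p_cues(self) -> float:
        return 1.0 / self.config.n_conditions

    def hazard(self, tsco: int) -> float:
        return cashout_hazard(tsco, self.config.cashout_support)

    @property
    def deltas(self) -> tuple[int, ...]:
        return _outcome_deltas(self.config)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "p_cues": self.p_cues,
            "nobs_wrap": self.nobs_wrap,
            "nobs_advance_prob": self.nobs_advance_prob,
            "hazards": {t: self.hazard(t) for t in range(1, self.config.tsco_max + 1)},
            "deltas": list(self.deltas),
            "outcome_dist": self.outcome_dist.tolist(),
        }


def build_transition_model(
    curves,
    k: float,
    config: Optional[TaskConfig] = None,
    nobs_wrap: bool = False,
) -> TransitionModel:
    """Assemble the full transition model from collapsed mean cue-value
    curves (see :class:`tokenmdp.rw.CueValueCurves`).

    The cue means at each NObs are scaled by ``k`` before entering the
    Gaussian likelihood; the per-NObs standard deviation comes from the
    curves and is shared across cues.
    """
    config = config or curves.config or TaskConfig()
    n_cues = curves.collapsed.shape[0]
    n_out = len(_outcome_deltas(config))
    dist = np.empty((n_cues, config.nobs_max, n_out))
    p_del = config.outcome_deliver_prob
    n_gain = sum(1 for d in config.cue_deltas if d > 0)
    uniform = np.full(n_out, p_del / n_cues)
    uniform[n_gain] = 1.0 - p_del  # the 0-change slot
    for n in range(config.nobs_max):
        if n == 0:
            dist[:, 0, :] = uniform  # no outcomes observed yet for new images
            continue
        mu = k * curves.collapsed[:, n]
        sigma = float(curves.sigma[n])
        if sigma <= 0 or np.allclose(mu, mu[0]):
            dist[:, n, :] = uniform
            continue
        for cue in range(n_cues):
            dist[cue, n, :] = outcome_posterior(mu, sigma, cue, p_del, config.cue_deltas)
    return TransitionModel(config=config, outcome_dist=dist, k=k, nobs_wrap=nobs_wrap)


@dataclass
class ValueTable:
    """Converged (or sweep-capped) state utilities u(s) in juice-drop units.

    ``u`` is indexed [NTk, TSCO-1, TE-1, NObs-1]; accessors take the 1-based
    task conventions.
    """

    u: np.ndarray
    config: TaskConfig
    gamma: float
    sweeps_run: int
    converged: bool

    def value(self, ntk: int, tsco: int, te: int, nobs: int) -> float:
        return float(self.u[ntk, tsco - 1, te - 1, nobs - 1])

    def fixation_value(self, ntk: int, tsco: int, nobs: int) -> float:
        return self.value(ntk, tsco, 1, nobs)

    def cue_value(self, condition: int, ntk: int, tsco: int, nobs: int) -> float:
        return self.value(ntk, tsco, 1 + condition, nobs)

    def to_frame(self):
        import pandas as pd

        K, S, E, N = self.u.shape
        idx = np.indices((K, S, E, N)).reshape(4, -1)
        return pd.DataFrame(
            {
                "ntk": idx[0],
                "tsco": idx[1] + 1,
                "te": idx[2] + 1,
                "nobs": idx[3] + 1,
                "u": self.u.ravel(),
            }
        )


@dataclass
class Policy:
    """Greedy policy and action values at the cue states.

    ``q[c, a, ntk, tsco-1, nobs-1]`` is the value of choosing the a-th cue
    of condition c+1's pair; ``greedy`` holds the argmax action index.
    """

    q: np.ndarray
    greedy: np.ndarray
    config: TaskConfig

    def action_values(self, condition: int, ntk: int, tsco: int, nobs: int) -> np.ndarray:
        return self.q[condition - 1, :, ntk, tsco - 1, nobs - 1]


def _epoch_indices(config: TaskConfig) -> dict[str, int]:
    c = config.n_conditions
    return {"fix": 0, "out": c + 1, "cash": c + 2, "iti": c + 3}


def value_iteration(
    transitions: TransitionModel,
    gamma: float,
    reward: Optional[np.ndarray] = None,
    sweeps: int = 100,
    tol: float = 1e-9,
    span_tol: Optional[float] = None,
) -> tuple[ValueTable, Policy]:
    """Synchronous Bellman backups over the full state grid.

    Stops at the earlier of ``sweeps`` sweeps or (policy stable and maximum
    value change below ``tol``).  With gamma near 1 the utilities scale with
    the sweep cap rather than converging in absolute terms; everything
    downstream is invariant to that affine scale.

    ``span_tol`` enables an additional difference-stability stop: once the
    per-sweep increment is uniform across states to within ``span_tol`` (and
    the greedy policy is stable), all value *differences* -- hence the
    policy, choice probabilities and every regression statistic -- are at
    their fixed points, even though the absolute level still drifts by a
    near-constant per sweep.

    ``reward`` may override the default immediate reward (NTk juice drops in
    the cash-out epoch, zero elsewhere) with an array shaped like the table.
    """
    if not (0.0 <= gamma < 1.0):
        raise ValueError("gamma must be in [0, 1)")
    if sweeps < 1:
        raise ValueError("sweeps must be >= 1")
    cfg = transitions.config
    K = cfg.max_tokens + 1
    S = cfg.tsco_max
    C = cfg.n_conditions
    E = cfg.n_epochs
    N = cfg.nobs_max
    ep = _epoch_indices(cfg)
    pairs = cfg.condition_pairs()
    deltas = transitions.deltas

    if reward is None:
        reward = np.zeros((K, S, E, N))
        reward[:, :, ep["cash"], :] = np.arange(K)[:, None, None]
    else:
        reward = np.asarray(reward, dtype=float)
        if reward.shape != (K, S, E, N):
            raise ValueError("reward array has wrong shape")

    # Precomputed index helpers.
    ntk_idx = np.arange(K)
    clip_idx = {d: np.clip(ntk_idx + d, 0, K - 1) for d in deltas}
    hazards = np.array([transitions.hazard(t) for t in range(1, S + 1)])
    next_tsco = np.minimum(np.arange(1, S + 1), S - 1)  # 0-based index of tsco+1
    p_adv = transitions.nobs_advance_prob
    nobs_next = np.arange(1, N + 1)
    nobs_next[-1] = 0 if transitions.nobs_wrap else N - 1

    u = np.zeros((K, S, E, N))
    q = np.zeros((C, 2, K, S, N))
    greedy = np.zeros((C, K, S, N), dtype=int)
    prev_greedy = greedy.copy()

    it = 0
    converged = False
    for it in range(1, sweeps + 1):
        new_u = np.empty_like(u)
        # fixation -> average over the C cue epochs
        new_u[:, :, ep["fix"], :] = reward[:, :, ep["fix"], :] + gamma * u[
            :, :, 1 : 1 + C, :
        ].mean(axis=2)
        # cue epochs: two actions, outcome distribution per chosen cue
        u_out = u[:, :, ep["out"], :]  # [K, S, N]
        for c in range(C):
            cue_a, cue_b = pairs[c + 1]
            for a, cue in enumerate((cue_a, cue_b)):
                exp_next = np.zeros((K, S, N))
                for di, d in enumerate(deltas):
                    p = transitions.outcome_dist[cue, :, di]  # [N]
                    exp_next += p[None, None, :] * u_out[clip_idx[d], :, :]
                q[c, a] = gamma * exp_next
            new_u[:, :, 1 + c, :] = reward[:, :, 1 + c, :] + q[c].max(axis=0)
            greedy[c] = q[c].argmax(axis=0)
        # outcome -> cash-out (hazard) or ITI with incremented TSCO
        u_cash = u[:, :, ep["cash"], :]
        u_iti = u[:, :, ep["iti"], :]
        cont = u_iti[:, next_tsco, :]
        new_u[:, :, ep["out"], :] = reward[:, :, ep["out"], :] + gamma * (
            hazards[None, :, None] * u_cash + (1.0 - hazards[None, :, None]) * cont
        )
        # cash-out -> ITI with zero tokens, TSCO reset to 1
        new_u[:, :, ep["cash"], :] = reward[:, :, ep["cash"], :] + gamma * u_iti[
            0, 0, :
        ][None, None, :]
        # ITI -> next fixation; NObs advances with prob 1/C, wrapping at block end
        u_fix = u[:, :, ep["fix"], :]
        new_u[:, :, ep["iti"], :] = reward[:, :, ep["iti"], :] + gamma * (
            (1.0 - p_adv) * u_fix + p_adv * u_fix[:, :, nobs_next]
        )
        diff = new_u - u
        delta_max = float(np.max(np.abs(diff)))
        span = float(diff.max() - diff.min())
        u = new_u
        policy_stable = np.array_equal(greedy, prev_greedy)
        if delta_max < tol and policy_stable:
            converged = True
            break
        if span_tol is not None and span < span_tol and policy_stable:
            converged = True
            break
        prev_greedy = greedy.copy()

    table = ValueTable(u=u, config=cfg, gamma=gamma, sweeps_run=it, converged=converged)
    policy = Policy(q=q.copy(), greedy=greedy.copy(), config=cfg)
    return table, policy


def value_iteration_dense(
    P: np.ndarray,
    r: np.ndarray,
    gamma: float,
    sweeps: int = 10_000,
    tol: float = 1e-13,
) -> np.ndarray:
    """Generic tabular value iteration for an arbitrary finite MDP.

    ``P`` is [n_actions, n_states, n_states] (or [n_states, n_states] for a
    single-action chain), ``r`` the state reward.  Used as an independent
    solver for closed-form and miniature-task cross-checks.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim == 2:
        P = P[None]
    if not np.allclose(P.sum(axis=2), 1.0, atol=1e-10):
        raise ValueError("non-stochastic transition row")
    r = np.asarray(r, dtype=float)
    u = np.zeros(P.shape[1])
    for _ in range(sweeps):
        new_u = r + gamma * (P @ u).max(axis=0)
        if np.max(np.abs(new_u - u)) < tol:
            u = new_u
            break
        u = new_u
    return u


def mdp_choice_prob(action_values: Sequence[float], beta_mdp: float) -> np.ndarray:
    """Softmax over the two action values of a cue state."""
    if beta_mdp < 0:
        raise ValueError("beta_mdp must be non-negative")
    q = np.asarray(action_values, dtype=float)
    z = beta_mdp * (q - q.max())
    e = np.exp(z)
    return e / e.sum()
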
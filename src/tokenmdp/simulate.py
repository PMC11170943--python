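"""Synthetic monkey-like behavior with known ground truth.

Sessions are generated by a Rescorla-Wagner agent playing the tokens task:
choices come from a softmax over online-updated cue values, token outcomes
are delivered with probability 0.75, and tokens are cashed out for juice on
the task's uniform 4-6-trial schedule.  Motivation-linked behaviors are
coupled to latent MDP state values: log reaction times are linear in the
fixation-state value (trial initiation) and in the cue-state value and its
within-trial change (choice), with Gaussian noise on the log scale, and
trial aborts are Bernoulli draws from a logistic function of the state
value, with aborted attempts repeated immediately under the same condition
and side assignment.

The task dynamics follow the experiment; the reaction-time and abort
couplings are a generative stand-in chosen so that the downstream
regressions are well-specified and their slopes recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .task import (
    SessionData,
    TaskConfig,
    TrialRecord,
    apply_outcome,
    build_schedule,
    cashout_hazard,
)
from .mdp import ValueTable

__all__ = ["BehaviorGroundTruth", "simulate_session", "recover_parameters_harness"]


def _sigmoid(z: float) -> float:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class BehaviorGroundTruth:
    """Generative parameters for one synthetic animal.

    ``alpha``/``beta_rw`` drive the choice process; ``rt_fix_coefs`` (b0, b1)
    set log fixation RT = b0 + b1 * V_fix; ``rt_choice_coefs`` (c0, c1, c2)
    set log choice RT = c0 + c1 * V_cue + c2 * (V_cue - V_fix);
    ``abort_coefs`` (a0, a1) set the logistic abort hazard on V_fix (before
    cue onset) and V_cue (after).  ``rt_noise_sd`` is the log-scale noise.
    """

    alpha: tuple[float, float, float, float] = (0.35, 0.3, 0.1, 0.1)
    beta_rw: float = 2.5
    rt_fix_coefs: tuple[float, float] = (-1.2, -0.05)
    rt_choice_coefs: tuple[float, float, float] = (-1.5, -0.04, -0.04)
    abort_coefs: tuple[float, float] = (0.5, -0.15)
    rt_noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rt_noise_sd < 0:
            raise ValueError("rt_noise_sd must be non-negative")
        if any(not (0.0 <= a <= 1.0) for a in self.alpha):
            raise ValueError("alpha components must lie in [0, 1]")


def simulate_session(
    config: TaskConfig,
    truth: BehaviorGroundTruth,
    value_table: Optional[ValueTable] = None,
    n_blocks: int = 9,
    seed: Optional[int] = None,
    session_id: str = "session0",
    subject_id: str = "subject0",
) -> SessionData:
    """Generate one session of ``n_blocks`` completed 108-trial blocks.

    Tokens and the cash-out cycle persist across block boundaries; cue
    values and the observation counter reset with each block's novel images.
    A ``value_table`` is required whenever any value-coupling slope is
    nonzero, since the latent motivation signal is a state value.
    """
    coupled = (
        truth.rt_fix_coefs[1] != 0
        or truth.rt_choice_coefs[1] != 0
        or truth.rt_choice_coefs[2] != 0
        or truth.abort_coefs[1] != 0
    )
    if coupled and value_table is None:
        raise ValueError("value couplings are nonzero but no ValueTable was supplied")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    pairs = config.condition_pairs()
    alpha = np.asarray(truth.alpha)
    b0, b1 = truth.rt_fix_coefs
    c0, c1, c2 = truth.rt_choice_coefs
    a0, a1 = truth.abort_coefs

    session = SessionData(session_id=session_id, subject_id=subject_id)
    tokens = 0
    tsco = 1
    for block in range(n_blocks):
        schedule = build_schedule(config, seed=int(rng.integers(2**31)))
        v = np.zeros(len(config.cue_deltas))
        for t in range(len(schedule)):
            cond = schedule.conditions[t]
            side = schedule.sides[t]
            nobs = t // config.n_conditions + 1
            if value_table is not None:
                v_fix = value_table.fixation_value(tokens, tsco, nobs)
                v_cue = value_table.cue_value(cond, tokens, tsco, nobs)
            else:
                v_fix = v_cue = 0.0
            attempt = 0
            while True:
                # fixation stage: abort before cue onset, condition unknown
                if rng.random() < _sigmoid(a0 + a1 * v_fix):
                    session.records.append(
                        TrialRecord(
                            block=block, trial=t, attempt=attempt,
                            condition=cond, side_first_left=side,
                            choice=None, delivered=False, delta_tokens=0,
                            tokens_before=tokens, tokens_after=tokens,
                            tsco=tsco, cashout=False, juice_drops=0,
                            rt_fix=None, rt_choice=None,
                            abort_code="fixation_abort",
                        )
                    )
                    attempt += 1
                    continue
                rt_fix = float(
                    np.exp(b0 + b1 * v_fix + truth.rt_noise_sd * rng.standard_normal())
                )
                # choice stage: abort after cue onset, condition known
                if rng.random() < _sigmoid(a0 + a1 * v_cue):
                    session.records.append(
                        TrialRecord(
                            block=block, trial=t, attempt=attempt,
                            condition=cond, side_first_left=side,
                            choice=None, delivered=False, delta_tokens=0,
                            tokens_before=tokens, tokens_after=tokens,
                            tsco=tsco, cashout=False, juice_drops=0,
                            rt_fix=rt_fix, rt_choice=None,
                            abort_code="choice_abort",
                        )
                    )
                    attempt += 1
                    continue
                break
            cue_i, cue_j = pairs[cond]
            d_j = 1.0 / (1.0 + np.exp(truth.beta_rw * (v[cue_i] - v[cue_j])))
            choice = cue_j if rng.random() < d_j else cue_i
            delivered = bool(rng.random() < config.outcome_deliver_prob)
            delta = config.cue_deltas[choice]
            after = apply_outcome(tokens, delta, delivered)
            rt_choice = float(
                np.exp(
                    c0 + c1 * v_cue + c2 * (v_cue - v_fix)
                    + truth.rt_noise_sd * rng.standard_normal()
                )
            )
            cashout = bool(
                rng.random() < cashout_hazard(tsco, config.cashout_support)
            )
            session.records.append(
                TrialRecord(
                    block=block, trial=t, attempt=attempt,
                    condition=cond, side_first_left=side,
                    choice=int(choice), delivered=delivered,
                    delta_tokens=delta if delivered else 0,
                    tokens_before=tokens, tokens_after=after,
                    tsco=tsco, cashout=cashout,
                    juice_drops=after if cashout else 0,
                    rt_fix=rt_fix, rt_choice=rt_choice,
                    abort_code="none",
                )
            )
            R = delta if delivered else 0.0
            v[choice] += alpha[choice] * (R - v[choice])
            if cashout:
                tokens = 0
                tsco = 1
            else:
                tokens = after
                tsco += 1
    return session


def recover_parameters_harness(
    truth: BehaviorGroundTruth,
    n_seeds: int,
    config: Optional[TaskConfig] = None,
    value_table: Optional[ValueTable] = None,
    n_blocks: int = 9,
    fit_learning: bool = True,
    refit_values: bool = False,
) -> dict:
    """Simulate-and-refit loop: per seed, generate a session, fit the RW
    model and the three value regressions, and report recovery.

    With ``refit_values`` the regressions use a value table rebuilt from the
    seed's own fitted curves (the full pipeline); otherwise they reuse the
    generator's table, isolating regression recovery from MDP refitting.
    Returns a report with per-seed estimates, bias for alpha/beta, and sign
    agreement for the regression slopes.
    """
    from .rw import cue_observation_trajectories, extract_mean_curves, fit_rw
    from .mdp import build_transition_model, value_iteration
    from .stats import fit_abort_logistic, fit_choice_rt, fit_fixation_rt

    if n_seeds < 2:
        raise ValueError("n_seeds must be >= 2")
    config = config or TaskConfig()
    report: dict = {
        "alpha": [], "beta": [],
        "b1": [], "c1": [], "c2": [], "a1": [],
        "truth": truth,
    }
    for s in range(n_seeds):
        seed_truth = replace(truth, seed=truth.seed + 1000 + s)
        session = simulate_session(
            config, seed_truth, value_table=value_table, n_blocks=n_blocks,
            session_id=f"seed{s}",
        )
        if fit_learning:
            params, _ = fit_rw(session, config)
            report["alpha"].append(params.alpha)
            report["beta"].append(params.beta)
        table = value_table
        if refit_values and fit_learning:
            traj = cue_observation_trajectories(session, params, config)
            curves = extract_mean_curves(traj, config)
            tm = build_transition_model(curves, k=1.0, config=config)
            table, _ = value_iteration(tm, gamma=0.999)
        if table is not None:
            report["b1"].append(fit_fixation_rt(session, table).params["v_fix"])
            res_c = fit_choice_rt(session, table)
            report["c1"].append(res_c.params["v_cue"])
            report["c2"].append(res_c.params["dv"])
            try:
                res_a = fit_abort_logistic(session, table)
                report["a1"].append(res_a.params["v_cue"])
            except ValueError:
                report["a1"].append(np.nan)
    if report["alpha"]:
        a = np.array(report["alpha"])
        report["alpha_bias"] = (a - np.asarray(truth.alpha)).mean(axis=0)
        report["beta_bias"] = float(np.mean(report["beta"]) - truth.beta_rw)
    for key, true_val in (
        ("b1", truth.rt_fix_coefs[1]),
        ("c1", truth.rt_choice_coefs[1]),
        ("c2", truth.rt_choice_coefs[2]),
        ("a1", truth.abort_coefs[1]),
    ):
        vals = np.asarray(report[key], dtype=float)
        if vals.size:
            report[f"{key}_sign_match"] = float(
                np.mean(np.sign(vals[~np.isnan(vals)]) == np.sign(true_val))
            ) if true_val != 0 else np.nan
    return report
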
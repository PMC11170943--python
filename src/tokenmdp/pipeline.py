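"""Seeded end-to-end orchestration: simulate -> fit learning -> curves ->
build and calibrate the MDP -> behavioral regressions -> group statistics.

Every stage derives its randomness from the master seed, so a pipeline run
is fully reproducible; the manifest records per-stage status and content
hashes of the written artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .calibration import empirical_choice_curves, fit_k_beta
from .io import write_results, write_sessions
from .mdp import ValueTable, build_transition_model, value_iteration
from .rw import cue_observation_trajectories, extract_mean_curves, fit_rw
from .simulate import BehaviorGroundTruth, simulate_session
from .stats import (
    fit_abort_logistic,
    fit_choice_rt,
    fit_fixation_rt,
    group_tests,
)
from .task import TaskConfig

__all__ = ["PipelineConfig", "reference_value_table", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Settings for a full synthetic-study run."""

    task: TaskConfig = field(default_factory=TaskConfig)
    truth: BehaviorGroundTruth = field(default_factory=BehaviorGroundTruth)
    n_animals: int = 5
    n_sessions: int = 10
    n_blocks: int = 9
    gamma: float = 0.999
    out_dir: str = "pipeline_out"
    master_seed: int = 0


def reference_value_table(
    config: TaskConfig,
    truth: BehaviorGroundTruth,
    gamma: float = 0.999,
    n_blocks: int = 30,
    k: float = 1.0,
    seed: Optional[int] = None,
) -> ValueTable:
    """Ground-truth latent state values for the generator.

    Simulates a choices-only agent under the truth's learning parameters,
    extracts its mean cue-value curves, and solves the MDP; the resulting
    table supplies the latent motivation signal that couples to reaction
    times and aborts.
    """
    calib_truth = replace(
        truth,
        rt_fix_coefs=(truth.rt_fix_coefs[0], 0.0),
        rt_choice_coefs=(truth.rt_choice_coefs[0], 0.0, 0.0),
        abort_coefs=(-20.0, 0.0),
        seed=truth.seed if seed is None else seed,
    )
    session = simulate_session(config, calib_truth, value_table=None, n_blocks=n_blocks)
    from .rw import RWParams

    params = RWParams(alpha=truth.alpha, beta=truth.beta_rw)
    traj = cue_observation_trajectories(session, params, config)
    curves = extract_mean_curves(traj, config)
    tm = build_transition_model(curves, k=k, config=config)
    table, _ = value_iteration(tm, gamma=gamma)
    return table


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.master_seed)
    manifest: dict = {"stages": [], "master_seed": config.master_seed}

    def stage(name: str):
        entry = {"stage": name, "status": "running", "t_start": time.time()}
        manifest["stages"].append(entry)
        return entry

    try:
        # 1. simulate all animals and sessions (the reference model built
        #    first supplies the latent motivation signal)
        entry = stage("simulate")
        table = reference_value_table(
            config.task, config.truth, gamma=config.gamma,
            seed=int(rng.integers(2**31)),
        )
        sessions_by_animal: dict[str, list] = {}
        for a in range(config.n_animals):
            animal = f"animal{a}"
            sessions_by_animal[animal] = []
            for s in range(config.n_sessions):
                truth = replace(config.truth, seed=int(rng.integers(2**31)))
                sessions_by_animal[animal].append(
                    simulate_session(
                        config.task, truth, value_table=table,
                        n_blocks=config.n_blocks,
                        session_id=f"{animal}_s{s}", subject_id=animal,
                    )
                )
        all_sessions = [s for v in sessions_by_animal.values() for s in v]
        sess_path = out / "sessions.csv"
        write_sessions(all_sessions, sess_path)
        entry.update(status="ok", t_end=time.time(), sha256=_sha256(sess_path))

        # 3. learning fits and mean cue-value curves (pooled)
        entry = stage("fit-rw")
        fit_session = all_sessions[0]
        rw_params, loglik = fit_rw(fit_session, config.task)
        write_results(
            {"alpha": rw_params.alpha, "beta": rw_params.beta, "loglik": loglik},
            out / "rw_fit.json",
        )
        entry.update(status="ok", t_end=time.time(), sha256=_sha256(out / "rw_fit.json"))

        entry = stage("curves")
        traj = np.concatenate(
            [
                cue_observation_trajectories(s, rw_params, config.task)
                for s in all_sessions
            ]
        )
        curves = extract_mean_curves(traj, config.task)
        entry.update(status="ok", t_end=time.time())

        # 4. calibrate the MDP to pooled choice behavior
        entry = stage("fit-mdp")
        empirical = empirical_choice_curves(all_sessions, config.task)
        fitp, fitted_table, policy, tm = fit_k_beta(
            curves, empirical, gamma=config.gamma, config=config.task
        )
        write_results(dataclasses.asdict(fitp), out / "mdp_fit.json")
        fitted_table.to_frame().to_csv(out / "values.csv", index=False)
        entry.update(status="ok", t_end=time.time(), sha256=_sha256(out / "mdp_fit.json"))

        # 5. behavioral regressions per session
        entry = stage("regress")
        coefs: dict[str, dict[str, list]] = {
            "b_vfix": {}, "b_vcue": {}, "b_dv": {}, "a_vcue": {},
        }
        for animal, sess_list in sessions_by_animal.items():
            for d in coefs.values():
                d[animal] = []
            for session in sess_list:
                coefs["b_vfix"][animal].append(
                    fit_fixation_rt(session, fitted_table).params["v_fix"]
                )
                rc = fit_choice_rt(session, fitted_table)
                coefs["b_vcue"][animal].append(rc.params["v_cue"])
                coefs["b_dv"][animal].append(rc.params["dv"])
                try:
                    ra = fit_abort_logistic(session, fitted_table)
                    coefs["a_vcue"][animal].append(ra.params["v_cue"])
                except ValueError:
                    pass
        write_results(coefs, out / "regressions.json")
        entry.update(
            status="ok", t_end=time.time(), sha256=_sha256(out / "regressions.json")
        )

        # 6. group statistics
        entry = stage("group-stats")
        group = {
            name: dataclasses.asdict(group_tests(by_animal, coef=name))
            for name, by_animal in coefs.items()
            if all(len(v) >= 2 for v in by_animal.values())
        }
        write_results(group, out / "group_stats.json")
        entry.update(
            status="ok", t_end=time.time(), sha256=_sha256(out / "group_stats.json")
        )
    except Exception as exc:  # tag the failing stage, keep partial outputs
        manifest["stages"][-1].update(status="failed", error=f"{type(exc).__name__}: {exc}")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
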
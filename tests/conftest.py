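import numpy as np
import pytest

from tokenmdp.mdp import build_transition_model, value_iteration
from tokenmdp.pipeline import reference_value_table
from tokenmdp.rw import RWParams, cue_observation_trajectories, extract_mean_curves
from tokenmdp.simulate import BehaviorGroundTruth, simulate_session
from tokenmdp.task import TaskConfig


@pytest.fixture(scope="session")
def config():
    return TaskConfig()


@pytest.fixture(scope="session")
def truth():
    return BehaviorGroundTruth(seed=3)


@pytest.fixture(scope="session")
def choices_only_truth(truth):
    """Generator variant with all value couplings off (no table needed)."""
    from dataclasses import replace

    return replace(
        truth,
        rt_fix_coefs=(truth.rt_fix_coefs[0], 0.0),
        rt_choice_coefs=(truth.rt_choice_coefs[0], 0.0, 0.0),
        abort_coefs=(-20.0, 0.0),
    )


@pytest.fixture(scope="session")
def learned_curves(config, choices_only_truth):
    """Well-estimated mean cue-value curves from the default learning agent."""
    params = RWParams(
        alpha=choices_only_truth.alpha, beta=choices_only_truth.beta_rw
    )
    trajs = []
    for s in range(3):
        sess = simulate_session(
            config, choices_only_truth, None, n_blocks=30, seed=100 + s
        )
        trajs.append(cue_observation_trajectories(sess, params, config))
    return extract_mean_curves(np.concatenate(trajs), config)


@pytest.fixture(scope="session")
def ref_table(config, truth):
    """Latent state values used by the synthetic generator (default solver)."""
    return reference_value_table(config, truth, gamma=0.999, n_blocks=30, seed=42)


@pytest.fixture(scope="session")
def solved(learned_curves, config):
    """(table, policy) for the full task at the default 100-sweep cap."""
    tm = build_transition_model(learned_curves, k=1.0, config=config)
    return value_iteration(tm, gamma=0.999)


@pytest.fixture(scope="session")
def coupled_session(config, truth, ref_table):
    """One 9-block session with RT and abort couplings on."""
    return simulate_session(config, truth, ref_table, n_blocks=9, seed=777)
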
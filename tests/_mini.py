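"""Miniaturized tokens task shared by solver-oracle tests: four cues,
two conditions, cash-out over {2, 3} trials, two learning stages."""

import numpy as np

from tokenmdp.rw import CueValueCurves
from tokenmdp.task import TaskConfig

MINI = TaskConfig(
    block_length=4,
    n_conditions=2,
    presentations_per_condition=2,
    cue_deltas=(2, 1, -1, -2),
    cashout_support=(2, 3),
    max_tokens=6,
    nobs_max=2,
    epoch_labels=("fixation", "cond1", "cond2", "outcome", "cashout", "iti"),
)


def mini_curves() -> CueValueCurves:
    return CueValueCurves(
        raw=np.zeros((4, 4)),
        collapsed=np.array([[0, 0.6], [0, 0.3], [0, -0.2], [0, -0.3]]),
        sigma=np.array([0.2, 0.2]),
        config=MINI,
    )


def mini_dense_mdp(tm):
    """Explicit dense transition matrices for the miniature task, built by
    independent enumeration (the oracle route)."""
    K, S, E, N = 7, 3, 6, 2
    pairs = MINI.condition_pairs()
    deltas = tm.deltas

    def sid(k, s, e, n):
        return ((k * S + s) * E + e) * N + n

    nS = K * S * E * N
    P = np.zeros((2, nS, nS))
    r = np.zeros(nS)
    for k in range(K):
        for s in range(S):
            for n in range(N):
                for a in range(2):
                    for c in range(2):
                        P[a, sid(k, s, 0, n), sid(k, s, 1 + c, n)] += 0.5
                for c in range(2):
                    for a, cue in enumerate(pairs[c + 1]):
                        for di, d in enumerate(deltas):
                            k2 = min(max(k + d, 0), K - 1)
                            P[a, sid(k, s, 1 + c, n), sid(k2, s, 3, n)] += (
                                tm.outcome_dist[cue, n, di]
                            )
                h = tm.hazard(s + 1)
                for a in range(2):
                    if h > 0:
                        P[a, sid(k, s, 3, n), sid(k, s, 4, n)] += h
                    if h < 1:
                        P[a, sid(k, s, 3, n), sid(k, min(s + 1, S - 1), 5, n)] += 1 - h
                    P[a, sid(k, s, 4, n), sid(0, 0, 5, n)] = 1.0
                    n2 = min(n + 1, N - 1)
                    if n2 != n:
                        P[a, sid(k, s, 5, n), sid(k, s, 0, n)] += 0.5
                        P[a, sid(k, s, 5, n), sid(k, s, 0, n2)] += 0.5
                    else:
                        P[a, sid(k, s, 5, n), sid(k, s, 0, n)] += 1.0
                r[sid(k, s, 4, n)] = k
    return P, r


def mini_rollout(tm, policy, start, gamma, horizon, rng):
    """One Monte-Carlo discounted return under the greedy policy."""
    pairs = MINI.condition_pairs()
    deltas = np.array(tm.deltas)
    K, S, N = 7, 3, 2
    k, s, e, n = start
    G, disc = 0.0, 1.0
    for _ in range(horizon):
        if e == 4:
            G += disc * k
        disc *= gamma
        if e == 0:
            e = 1 + int(rng.integers(2))
        elif e in (1, 2):
            c0 = e - 1  # 0-based condition index
            a = int(policy.greedy[c0, k, s, n])
            cue = pairs[c0 + 1][a]
            d = int(rng.choice(deltas, p=tm.outcome_dist[cue, n]))
            k = min(max(k + d, 0), K - 1)
            e = 3
        elif e == 3:
            if rng.random() < tm.hazard(s + 1):
                e = 4
            else:
                s = min(s + 1, S - 1)
                e = 5
        elif e == 4:
            k, s, e = 0, 0, 5
        else:  # iti
            if rng.random() < 0.5:
                n = min(n + 1, N - 1)
            e = 0
    return G
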
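# Methods

This note records the modelling choices behind `tokenmdp`: what each stage
assumes, the parameters that matter, and where genuinely open design
decisions were resolved.

## Task model

A block is 108 completed trials over four novel cue images worth
(+2, +1, −1, −2) tokens, presented as six unordered pairs. The scheduler
treats each block as nine disjoint 12-trial windows; each window contains
every condition exactly twice with opposite left/right arrangements, which
automatically yields 18 presentations per condition and a 9/9 side split
per block. (The original task also discouraged some loss–loss
adjacencies; only the 12-trial balancing rule is implemented, as that is
the constraint stated precisely.)

Outcomes are delivered with probability 0.75, the token count is floored
at zero, and a cash-out converts tokens to juice one-for-one. The cash-out
interval is uniform on {4, 5, 6} trials, giving conditional hazards 0, 0,
0, 1/3, 1/2, 1 over TSCO (trials since cash-out). An aborted attempt is
repeated immediately under the same condition and side assignment and
advances nothing (schedule, tokens, TSCO, observation counts).

## Rescorla–Wagner learning and mean cue-value curves

Cue values update by the delta rule with one learning rate per cue; the
prediction target R is the *realized* token change, so the 25% undelivered
outcomes pull values toward zero. Values reset at each block start (novel
images). Choices are a two-option softmax with one inverse temperature
shared across conditions. Sessions are fit by maximum likelihood over all
completed trials with bounded L-BFGS-B from five fixed-seed starts
(α ∈ [0, 1], β ∈ [0, 50]); the likelihood of the fitted model always
weakly dominates the random-choice model, which is asserted in tests.

Mean cue-value curves index each cue's average fitted value by how many
times it has been *seen* (54 times per block: three conditions × 18).
These are collapsed to the 18 cue-pair observation counts by averaging
consecutive triples. The dispersion σ at each collapsed index is the
standard deviation across blocks of the collapsed value, averaged over the
four cues — one σ per learning stage, shared across cues, so the outcome
posterior's likelihood width varies over learning but not between cues.

## The MDP

States are (NTk 0–12, TSCO 1–6, TE 1–10, NObs 1–18): 14,040 states. Epochs
are fixation, the six cue conditions, token outcome, cash-out, ITI; the
model runs in epoch time, not seconds. Immediate reward is NTk in the
cash-out epoch and zero elsewhere; a cash-out with zero tokens is still a
cash-out (it resets TSCO with zero juice). Inside the table, ITI states
carry the *upcoming* trial's TSCO; fixation/cue/outcome states carry the
current trial's, which is what the hazard and the regressions consume.

**Outcome transitions.** The cue→outcome step is the monkey's inferred
mapping of images to token changes: p(0) = 0.25 exactly, and the four
non-zero outcomes share the 0.75 delivery mass in proportion to a Bayesian
posterior with uniform priors and Gaussian likelihoods centred on the
(k-scaled) collapsed cue means with the stage's σ. The 0.75 rescaling is
load-bearing: the maximum entry of a four-way posterior is at least 0.25,
so the published early-learning transition probability of 0.24 is only
attainable after rescaling — both published worked examples (0.24 and
0.52) reproduce to two decimals under this convention, with σ recovered by
1-D root-finding (0.175 and 0.23). At NObs = 1 the transition is the
uninformed prior outright: before any outcome has been observed all
mappings are equally likely, which also makes the two action values of
every condition exactly equal on a pair's first presentation.

**NObs bookkeeping.** The state carries a single block-level learning
counter. Since each pair recurs every six trials on average under the
balanced schedule, the solver advances NObs stochastically with
probability 1/6 per trial at the ITI→fixation transition. By default
NObs 18 is absorbing: modelling the block transition (NObs reset to 1 with
tokens and TSCO persisting) is supported (`nobs_wrap=True`), but pulls the
late-block fixation values down — the model then "sees" the coming reset —
which contradicts the reported phenomenology that fixation value rises
with learning progress; the absorbing plateau reproduces it.

**Solver.** Synchronous value iteration from zero initialization. The
default cap is 100 sweeps, which reproduces the reported utility scale
(values ≈ 15–30 juice drops; with γ = 0.999 absolute convergence would
put the baseline near 200). All downstream quantities — greedy policy,
softmax choice probabilities, regression statistics — depend only on value
*differences*, so the solver also offers a difference-stability stop
(`span_tol`): once the per-sweep increment is uniform across states, all
differences are at their fixed point even though the absolute level still
drifts. The phenomenology checks use that mode; the regressions are
asserted invariant (in sign, and exactly in 1/a-rescaling) under affine
maps u → a·u + b.

**Phenomenology.** At difference-convergence, utility is nondecreasing in
the token count everywhere, the fixation value is nondecreasing in NObs,
and utility rises with cash-out proximity for NTk ≥ 2. At NTk = 1 there is
a reproducible ~0.003% dip near certain cash-out (about −0.007 on values
of ~214): with a single token, an imminent cash-out buys almost no juice
while briefly interrupting accumulation. The dip is robust to the curve
scale and the stopping rule and is far below the resolution of any plot;
the corresponding strict assertion in the acceptance suite is left
failing rather than tolerated away, and this is the one known deviation
from the idealized monotonicity suite.

## Calibration

The two free parameters are k (scale of the cue means relative to the
fixed σ — effectively the model's learning signal-to-noise) and β (softmax
inverse temperature on the two action values). They are fit jointly by
minimizing RMSE over the 6 × 18 choice-probability matrix (equal weight,
missing cells skipped) against empirical better-option fractions, using
bounded Nelder–Mead from four fixed restarts; value iteration is re-run
per candidate k (the transitions depend on k but not on u, so one re-solve
after fitting reconverges the policy; the alternation loop exits as soon
as the policy is stable). Model choice probabilities average the softmax
over the feasible (NTk, TSCO) cells uniformly. Self-consistency recovery
of (k, β) is exact to optimizer tolerance and is asserted at ±10%.

The discount factor is not fit freely: candidates
(0.8, 0.85, 0.9, 0.95, 0.99, 0.999) are swept, each scored by the mean
residual variance of the three behavioral regressions, and 0.999 is the
package default; behavior generated from 0.999-discount values selects
0.999 in the sweep.

## Synthetic behavior

The generator plays the exact task with an RW agent and couples motivated
behaviors to a latent value table (solved from the generator's own
learning parameters at the default solver settings):

| parameter | default | meaning |
|---|---|---|
| α | (0.35, 0.30, 0.10, 0.10) | per-cue learning rates; gain cues learn faster |
| β_RW | 2.5 | choice consistency |
| (b0, b1) | (−1.2, −0.05) | log fixation RT = b0 + b1·V_fix (≈0.30 s baseline) |
| (c0, c1, c2) | (−1.5, −0.04, −0.04) | log choice RT on V_cue and ΔV (≈0.22 s baseline) |
| (a0, a1) | (0.5, −0.15) | logistic abort hazard, on V_fix before cue onset and V_cue after |
| σ_RT | 0.25 | log-scale RT noise |

RT noise is log-normal because the regressions are specified on log RT;
with zero noise the regressions are exactly identified, which is asserted.
The abort intercept offsets the positive value scale so that the default
abort rate lands near 5–15% (as in monkey behavior) with a coupling strong
enough that each slope's recovery is adequately powered at the study scale
(~9 blocks/session) — the generator exists to make the regression
structure recoverable, and its defaults are chosen once by that power
criterion, not per-experiment. What the generator does *not* emulate:
satiety or drift within sessions, inter-animal variability beyond seeds,
side biases, autocorrelated RTs, or any structured abort policy (aborts
are conditionally independent given the state value). Passing recovery
tests therefore demonstrates pipeline correctness, not that real monkeys
satisfy these couplings.

## Regressions and group statistics

RTs are Tukey-filtered per session and per RT type (both fences) before
log-transform and OLS; aborted attempts contribute no RTs. The abort
logistic regression uses all attempts (completed and aborted) with
unpenalized ML and a small-ridge (λ = 1e−6) Newton fallback under
separation. Marginalization replaces u with its mean over one feature's
feasible range (NTk ≤ 2·TSCO bounds the token range; marginalizing the
cue condition averages the six cue epochs). Feature-level multivariate
regressions use condition 1 (+2 vs +1) as the reference level and split
aborts into fixation-stage and choice-stage subsets, since before cue
onset the condition is unknown to the animal. Group inference is a
one-sample t test across sessions per animal, then an exact one-sided
Wilcoxon signed-rank test on per-animal means (one-sided because the
smallest attainable n = 5 two-sided p would be 1/16, and the hypotheses
are directional).

## Problem sizes

Defaults used by the test suite and examples: mean cue-value curves from
90 simulated blocks; regressions on 9-block sessions; sign-recovery over
20 seeds; group statistics over 5 synthetic animals × 2 sessions;
(k, β) recovery over five parameter settings; the solver-oracle checks run
on a miniature task (four cues, two conditions, cash-out over {2, 3},
two learning stages, 252 states) where exhaustive enumeration and
Monte-Carlo rollouts are cheap.

## Known limitations

- The MDP has no abort action; aborts are treated purely as a readout.
- A single shared NObs counter approximates six per-pair counters; the
  approximation is good only because the schedule is balanced.
- The collapsed curve index conflates the three conditions a cue appears
  in; cues are assumed to learn at one rate per image, not per pairing.
- Absolute utilities are meaningful only up to the affine scale set by the
  stopping rule; only differences should ever be interpreted.
- The NTk = 1 cash-out-proximity dip described above.
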
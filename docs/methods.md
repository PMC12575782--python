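# Methods

## The task

The environment models a rodent plus-maze protocol in which each trial is
effectively a T-maze: the animal starts at the end of the north or south
arm, walks a corridor to a central junction, and must turn into the east
or west arm, one end of which is rewarded.  Two rule families define where
the reward is:

- **allocentric**: the reward sits at a fixed world side (east by
  default) regardless of the start arm, so the correct turn depends on
  where the agent started;
- **egocentric**: the reward is always on the agent's right at the
  junction, so the correct motor sequence is start-independent.

The maze is a `(2L+1) x 9` grid of scalar cell codes (empty 0, wall 1,
cues 2–5, distractor 6, masked −1), with start corridors of length `L`
(default 4) and terminal arms of fixed length 2, giving the canonical
7-state optimal path.  Four cues flank the start corridors — key/square
near the north start, lava/ball near the south — so the initial view
identifies the start arm.  Each trial the opposite start arm is walled
off.  The agent has three actions (forward, rotate left, rotate right),
a 128-step episode cap, reward 1 at the rewarded terminal and 0
elsewhere, and three post-terminal free steps that model behaviour right
after reward consumption (extended to twenty steps in the
activation-recording mode so the +4 s analysis window is covered;
learning always stops at the terminal transition).

Observability is the experimental variable: the default observation is a
forward-facing 3×3 egocentric window (the agent at the bottom centre;
nothing behind it; out-of-grid cells padded with wall code), masked down
to the agent's own cell inside the terminal arms.  Junction approaches
from the two starts produce *identical* 3×3 views, so under the
allocentric rule the observation stream is aliased exactly where the
decision must be made — the structural reason a memoryless policy cannot
solve both allocentric subtasks.  A full 9×9 top-down view (with the
agent's cell marked by an orientation-specific code) removes the
aliasing for the full-observability comparisons.

## Agents

All agents are three-layer value networks mirroring the hippocampal
trisynaptic loop: flattened observation (entorhinal/dentate input) → CA3
(50 units) → CA1 (50 rectified units) → per-task linear Q readouts of the
three actions.  The recurrent variant (hcDRQN) implements CA3 as a bank
of gated recurrent units; the feedforward variant (hcDQN) uses a
rectified dense layer; a third variant freezes the CA3 recurrent weight
matrices at their initial values.  Two output heads (allocentric /
egocentric) are switched by the active rule; a single-head variant
instead appends a task-ID bit to the input.

Learning is online one-step Q-learning with a frozen target network and
no experience replay (buffer size 1, batch size 1): the target is
`r + γ max_a' Q(s', a'; θ⁻)` (or `r` at trial end), the loss its squared
error, γ = 0.9, Adam with learning rate 10⁻³.  For the recurrent agents
the gradient is backpropagated through time to the trial start; updates
fire every second environment step and at the terminal transition,
covering the transitions since the previous update, and the BPTT window
is capped at 128 steps (the episode cap, so the cap never truncates in
practice).  Hidden state resets at every trial start; no gradient or
state crosses trials.  ε-greedy exploration decays linearly from 0.3 to
0.05 over the first half of the schedule, then stays constant.

The gate equations, the hand-derived backward pass, and Adam live in
`hcnav.nn` (numba-accelerated); all gradients are validated against
central finite differences, and the TD targets against a hand-coded
tabular Q-learning oracle, in the test suite.

**Target-network refresh.** The refresh interval is a named but unprinted
hyperparameter.  The package default is 25 parameter updates.  At the
package's scaled trial counts (2,000–4,000 trials) slower refresh (100)
leaves the allocentric subtasks unconverged, while 25 converges all four
subtasks reliably; at 6,000+ trials both settings converge.  The value is
configurable.

**Continual-learning baselines.** Elastic weight consolidation (default
importance 800, diagonal Fisher accumulated from squared TD-loss
gradients at task boundaries) and synaptic intelligence (default
importance 30, online path-integral importances normalized by squared
displacement) attach to the feedforward trunk as quadratic anchor
penalties `λ Σ_w Ω_w (θ_w − θ*_w)²`.

## Curriculum

Training alternates 25-trial blocks (10 in the scaled presets) of a
single (rule, start-arm) combination: allocentric north/south alternated
four times, then egocentric blocks, the 16-block super-cycle repeating to
10,000 trials at full scale.  Egocentric blocks alternate north/south by
default; a literal mode holds one start for the whole egocentric phase
(the protocol description admits both readings).  Per-trial success,
steps and block labels are logged; drop and recovery around a switch are
the first-block mean minus the minimum of the remaining blocks, and the
mean of the last two blocks minus that minimum.

**Scales.** Three problem sizes are used, preserving the block pattern:
the full protocol (25-trial blocks, 10,000 trials), a scaled preset for
fast property suites (10-trial blocks, 2,000 trials), and a desk scale
for reproducing printed quantities (10-trial blocks, 4,000 trials, 3–5
seeds), at which the recurrent agent converges on all four subtasks
across seeds.

**Intermediate checkpoint.** Analyses of partially-trained agents use the
first parameter snapshot whose trailing-100-trial success rate enters
[0.70, 0.85] after at least one full super-cycle — a success regime
comparable to the animals' — falling back to the final snapshot if the
band is never hit.

## Population-activity demixing

CA1 activations are recorded during greedy-with-small-ε (ε = 0.05)
rollouts of the intermediate checkpoint, 200 trials per subtask (800
total, the order of a behavioural session), with learning off.  Trials
are aligned to the terminal crossing, converted to seconds at 200 ms per
step, and averaged into a neurons × strategy(4) × decision(2) × time(30)
tensor spanning −2 s to +4 s (trials shorter than the window are
edge-padded; condition cells with no trials — typically
egocentric-incorrect once the egocentric tasks are mastered — are
flagged and filled by masked averaging over the observed decisions,
never zero-filled).

The centered tensor is decomposed into four orthogonal marginalizations
(time; strategy + strategy×time; decision + decision×time; the remaining
strategy×decision terms).  Because the decomposition is orthogonal, the
squared norms partition the variance exactly; the reported
per-marginalization "explained variance" percentages are that partition.
Demixed components per marginalization come from ridge-regularized
reduced-rank regression of the marginal data onto the full data
(`B = X_m X' (X X' + λ‖X‖²_F I)⁻¹`, rank-reduced through the SVD of
`B X`), with λ selectable by held-out-unit grid search over
10⁻⁷…10⁻² (default 10⁻⁶; the grid-search optimum for the reference
recordings, 2.919×10⁻⁵, is accepted directly).  Model-to-reference
component agreement uses the min–max-normalized mean squared error; a
constant series normalizes to all-0.5 with a warning.

## Spatial coding

Per-unit rate maps accumulate per-step occupancy (rotations in place
count as dwell) and CA1 activation magnitude over episodes, divide
activity by occupancy, and evaluate, over visited bins only: spatial
information `SI = Σ p_i (r_i/r̄) log₂(r_i/r̄)` (bits, with 0·log 0 := 0),
sparsity `(Σ p_i r_i)² / (Σ p_i r_i² + ε)` with ε = 10⁻⁸, and coherence,
the Pearson correlation of each bin's rate with its ≤8-neighbour local
mean (neighbourhoods clipped at map edges; Spearman available).  Spatial
bins are the maze grid cells.

## Behaviour profiles

Dwell-time maps count steps per cell; the 7-state profile extracts the
optimal-path cells and normalizes each state's dwell by the final
(terminal) state's dwell.  Post-terminal steps count toward terminal
dwell by default (they model post-reward behaviour; a toggle excludes
them).  Episodes that never reach the terminal enter the map but not the
ratio profile.  The behaviour error between two profiles is the MSE over
the seven state-to-end ratios.  Action certainty along the path is the
relative Q-value variance: population variance (n-denominator) of the
three action values divided by their mean, undefined (flagged) where the
mean is not positive.

## Generalization battery

All evaluations are greedy with learning off.  Corridor lengths rise to
32 (episode cap scaled as 4× the corridor length when longer than 128);
cue removal enumerates all 2⁴ subsets for the whole trial; the distractor
adds a single novel-code cell just below the north cue pair (the
manipulation text is singular "another cue"; placing one per pair
perturbs every subtask's start view and collapses performance far below
the reported level, so the single-cue reading is used); Gaussian noise
N(0, σ²), σ² ∈ 1…15, is drawn fresh per step on cue codes in the emitted
observation only; probabilistic cues hide each cue independently per
step with probability 1−p (invisible cues render as empty).  Default
evaluation is 100 trials per subtask with binomial standard errors.

## Synthetic CA1 generator

The generator emulates the statistical shape of the CA1 tetrode dataset
the demixing pipeline targets: 612 neurons, 0.2 s bins, −2/+4 s windows,
strategy × decision labels.  Condition means are a baseline rate (2 Hz)
plus low-rank components confined to each marginalization — exponential
time decays, logistic decision steps diverging before the terminal and
persisting after it, and strategy offsets — scaled so the noiseless
marginal variance fractions equal the planted targets exactly (defaults:
strategy 0.37, interaction 0.17, decision 0.06, time 0.40, mirroring the
animal-side split).  Trials add Gaussian rate noise (σ = 1, i.e.
per-trial SNR of 1; 40 trials per condition) or Poisson counts, floored
at 0.  The functional forms are fixtures: recovery tests show the
pipeline recovers planted fractions within ±5 points at default noise,
which validates the analysis code, not any biological claim.  The
generator does not emulate spiking biophysics, theta rhythm, replay, or
position-coupled fields.

## What the synthetic conditions do and do not show

Passing tests on this stack demonstrates that the implementation of the
task, the learners and the analyses is internally correct and reproduces
the study's qualitative and (at desk scale) quantitative patterns under
the stated conditions.  Real recordings differ in trial counts per
condition, non-stationarity across sessions, and neuron identity across
animals; the optional tensor reader accepts external trials × neurons ×
time arrays with a label sidecar so real data can be slotted into the
same pipeline.

## Numerical and reproducibility choices

Everything is float64.  Each run seed spawns three independent streams
(environment, agent initialization, exploration), so stochasticity
sources can be ablated separately; identical seeds reproduce logs and
parameters bit-for-bit.  Greedy action selection breaks ties toward the
lowest action index.  Episode truncation at the step cap counts as an
incorrect trial with reward 0.  Rank-deficient demixing fits reduce the
component count with a warning; all-zero rate maps report SI 0 and
sparsity 0; constant maps report coherence as missing with a reason.

## Known limitations

- Desk-scale cohorts (4,000 trials, 3–5 seeds) are smaller than the full
  protocol (10,000 trials, 5 seeds); stochastic quantities carry
  correspondingly wider seed-to-seed spread, and the corridor-length and
  distractor outcomes are the most scale-sensitive.
- The interaction share of the demixed variance partition runs above the
  reference value at this scale (the strategy×decision structure induced
  by masked filling of empty egocentric-incorrect cells and by
  incorrect-trial trajectories is a real feature of the recordings the
  pipeline makes, not an artifact of the fit).
- The continual-learning baselines are implemented and unit-tested but
  not part of the headline cohort comparisons.
- The relative Q-value variance along the optimal path is not monotone:
  it spikes at the first masked terminal-arm state (where the
  observation collapses to the agent's own cell) before dropping at the
  terminal.  Start-to-terminal certainty still increases, and that is
  the form the tests assert.
- Allo-vs-ego separability of the strategy-component scores varies
  substantially across seeds (recurrent ~0.7–0.97, feedforward
  ~0.5–0.86 at desk scale); the recurrent advantage is consistent and is
  what the tests check.
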
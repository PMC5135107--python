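# Methods

## The model

Each partner's wrist is a discrete-time linear plant with state
x = [θ, θ̇, τ, f]ᵀ — angle (deg), angular velocity (deg/s), applied
torque (Nm), and the auxiliary first stage f of a two-stage muscle
filter.  The dynamics are

    x_{k+1} = A x_k + B u_k + C (xᵖ_k − x_k)

with time step Δt = 0.01 s.  A integrates angle and velocity,
accelerates the wrist by τ/I, and low-pass filters the motor command u
through two first-order stages sharing the pole 1 − Δt/τ_u
(τ_u = 40 ms; both stages deliberately share the same time constant, as
the transition matrix implies).  The coupling matrix C injects the
partner's relative angle and velocity into the acceleration row — a
virtual spring-damper with stiffness K = 0.4 Nm/deg (the experimental
coupling) and damping D = 0.05 Nm·s/deg — and is zero when the partners
are disconnected.

Angles are kept in degrees everywhere.  The effective inertia is the
numerical constant I = 0.1 in the deg-based unit system; only its
numerical value matters for the closed loop, since K is specified per
degree.

Each agent plans *independently*: its feedback gain L solves the
infinite-horizon discrete LQR with state cost Q = diag(q_pos, q_vel, 0, 0)
and control cost R = 0.5, computed on the **uncoupled** A, B.  The
partner enters only through C at execution time (co-activity — there is
no joint plan).  The motor command is u = −L (x − t) with target
t = [θ_t, 0, 0, 0]ᵀ during reaching, or t = [θ_0, 0, ±τ_0, 0]ᵀ while a
pre-movement torque is held.  We read the superscript on (R + BᵀSB) in
the Riccati recursion as the inverse (the scalar reciprocal); the
literal transpose is dimensionally meaningless and the recursion is
otherwise the standard one.

Numerical choices: the Riccati fixed point is iterated from S = Q,
symmetrising each iterate, until the maximum element change falls below
1e-10 (bound 10⁶ iterations; in practice a few hundred suffice —
convergence is geometric at the squared spectral radius of the closed
loop).  Gains are memoised on (q_pos, q_vel, R, plant), which is what
makes the 64-candidate tree search affordable.  The gain is invariant to
a common positive scaling of (q_pos, q_vel, R); unit tests pin this and
the agreement with an independent finite-horizon dynamic-programming
oracle and with `scipy.linalg.solve_discrete_are`.

### Hold rule

A pure LQR never ends a movement exerting sustained torque against its
partner.  The simulation therefore supports an endgame rule: at the
first sample where the *average* angle reaches the task target, each
agent's target is replaced by its own current angle, freezing both
postures and sustaining whatever coupling torque exists at that moment.
The trigger compares the average against the displayed task target (30°
by default), not against the agents' private plan targets, which the
identification stage treats as free parameters.  If the average never
reaches the target within the simulated window, no switch occurs.

### Pre-movement opposing torque

In push-pull blocks partners hold ±0.7 Nm against each other before
moving.  Two initial-condition constructors are provided:

- `init_pushpull_state` settles the coupled closed loop under the
  pre-movement target [θ_0, 0, ±τ_0, 0]ᵀ for 3 s (settling verified by a
  0.1 deg/s terminal-velocity check, and validated against the exact
  linear fixed point in tests).  Because Q places no weight on the
  torque state, the controller tracks the torque component of its target
  only weakly: with the default plan the settled torque is ≈ 0.06 Nm,
  not 0.7 Nm, and the routine warns accordingly.  This is a property of
  the model class, not a bug: Q(3,3) ≡ 0 by construction.
- `constrained_pushpull_state` returns the exact mechanical equilibrium
  with the torque constraint *enforced* — wrists at rest, muscle torques
  at ±τ_0, angles split by τ_0/K about θ_0 so the spring transmits
  exactly the held torque.  This is the state an experimenter's visual
  torque feedback drives participants to, and it is what the synthetic
  generator uses for the pre-onset segment.

## Signal preprocessing

Raw 100 Hz trials are processed in a fixed order: onset detection →
truncation → resampling → filtering.  Onset is the first raw sample
where the central-difference speed of the *average cursor* exceeds
5 deg/s (the average cursor is what participants see and what all
downstream analysis uses).  The 1.2 s window after onset is linearly
interpolated onto 256 samples (linear resampling is exact for the
sub-6 Hz content that survives filtering, and endpoint-preserving), then
each curve is filtered with a zero-phase order-6 Butterworth low-pass at
6 Hz designed at the analysis-grid rate 255/1.2 = 212.5 Hz and applied
forward-backward (squared magnitude response) with reflective padding of
3× the filter order.  Filtering is deliberately last, and onset is
detected on unfiltered data.  A 30-trial block becomes 6 chronological
bins of 5 trials; block statistics are per-sample means and unbiased
(n−1) variances.

## Plan identification

The six free parameters (q_pos, q_vel, θ_t per partner) minimise the
normalised squared distance between simulation and block means:

    M = (1/2L) Σᵢ [ (θ̄ᵢ−θᵢ)²/σ²_θᵢ + (τ̄ᵢ−τᵢ)²/σ²_τᵢ ],   L = 256,

where the sum runs over all 256 samples.  Simulated curves are the
average-cursor angle and the interaction torque in the recording sign
convention (positive = partner 1 pushing the cursor toward the target).
Variance curves are floored at 1% of their block-wide mean before use;
a variance curve that is identically zero is rejected as degenerate.
R is fixed at 0.5 and never searched; K, D, I, τ_u are likewise fixed.

The search is a greedy walk on the lattice with steps δq_pos = 1,
δq_vel = 0.05, δθ = 1°, starting from Q = diag(2, 0.1), θ = 30° for both
partners.  Each iteration evaluates all 2⁶ = 64 sign permutations of one
step in every coordinate (each evaluation = two cached LQR solves plus
one coupled simulation, batched), negative weights clipping to zero, and
moves to the best candidate; the reported answer is the best point
visited anywhere along the 200-iteration path.

Two deterministic policies harden the walk, and both are needed:

- **No revisiting.** Because *every* coordinate must move each
  iteration, the raw argmin walk locks into a period-2 cycle between two
  corners within a handful of iterations, wasting the rest of the
  budget.  The walk therefore never re-expands an already-visited point.
- **Restart on stall.** After 10 consecutive non-improving moves the
  walk returns to the incumbent best point and continues (the visited
  set forces a different route out).

The plain walk is available via
`PlanSearchConfig(allow_revisit=True, restart_patience=0)`.

A structural property of the move scheme worth knowing: after n
iterations every coordinate's displacement from the start is n steps
minus twice the number of down-moves, so all six displacements share the
parity of n.  The walk can therefore only ever *visit* lattice points
whose displacement parity from the initialisation is uniform across
coordinates; any other lattice point can at best be bracketed to within
one step.  Parameter-recovery studies accordingly draw ground truths on
this walkable lattice, and report recovery to within one step per
coordinate.  Self-consistency studies use noiseless mean curves with
constant variance weights of 1 deg² (angle) and 0.01 Nm² (torque) —
an idealised noise-free block has zero across-trial variance, for which
M is undefined, so weights at the channels' natural scales (1 deg,
0.1 Nm) stand in.  Under these conditions the search recovers ~90% of
random walkable-lattice truths within one step in 200 iterations; the
remaining misses end in decoy basins of this deep-and-narrow objective.
Identifiability is genuinely marginal at the one-step scale: a
one-step q_vel change alters the torque curve by well under 0.1 Nm rms.

Between-block comparisons use the position-priority ratio
q_pos/(q_pos + q_vel), which is invariant to common weight scaling.

## Wavelet-domain functional ANOVA

Each 256-sample curve is decomposed on third-order coiflets to level 4
with periodized boundaries, giving exactly 256 coefficients ordered
[cA4, cD4, cD3, cD2, cD1] (periodization is the only boundary mode that
preserves the sample count; the transform is orthogonal, so energy is
preserved and reconstruction is exact).  For each coefficient position a
balanced one-way fixed-effects ANOVA across the 6 bins (df 5, 24) flags
positions with p < 0.05.  Coefficient positions that are constant across
all 30 trials get F = 0, p = 1 — no evidence of change rather than 0/0.

Post hoc, every flagged position's 15 bin-pair contrasts are tested by
Scheffé's criterion — (mean difference)² / (MSE·(2/5)) against
(k−1)·F_crit at level 0.05/m, where m is the number of significant
omnibus tests (Bonferroni over positions) and k = 6.  With m = 0 the
post hoc mask is empty, which is a result, not an error.

For each bin pair, the raw mean-difference curve is the inverse
transform of the difference of bin-mean spectra (by linearity, identical
to the difference of bin-mean curves), and the significant-difference
curve inverts only the post-hoc-masked coefficients; it is forced to
exact zeros when the pair's mask is empty, and its maximal runs with
|Δ| > 1e-9 are reported as significant time windows in seconds on
[0, 1.2].  A per-sample time-domain ANOVA (unadjusted, with the same
omnibus + Scheffé scheme for pairs) serves as corroboration only.

## Synthetic data

The generator exists because the deterministic model produces identical
trials while the analysis needs across-trial variance.  It emulates one
block of the reaching experiment per call: a stationary pre-onset
segment (rest for coupled blocks; the constrained ±0.7 Nm equilibrium
for push-pull blocks), then a coupled reach from −10° toward 30° under
the hold rule, recorded at 100 Hz for ≥ 2 s.  Four noise sources, all
derived from (seed, trial index) so blocks are bit-reproducible:

- motor-command noise, white, SD 0.02 Nm — the trial-to-trial execution
  variability that gives the variance curves their shape;
- plan jitter, multiplicative SD 5% on q_pos and q_vel per trial —
  slow variation in movement vigour;
- onset jitter, SD 0.05 s — imperfect countdown synchronisation;
- angle measurement noise, SD 0.1 deg, low-pass filtered at 3 Hz.
  The smoothing matters: white 0.1 deg noise at 100 Hz implies
  ~7 deg/s of spurious central-difference velocity, which would trip
  the 5 deg/s onset detector while the wrist is still; encoder plus
  soft-tissue noise in real kinematics is smooth at this scale.

Per-bin plan overrides inject mid-block motion-plan changes for power
studies.  What the generator does **not** emulate: signal-dependent
motor noise, reaction-time asymmetries between partners beyond the
shared onset jitter, within-trial plan adaptation, and the feedback
control real participants use to satisfy the 0.7 Nm pre-movement
constraint (the constraint is imposed as an exact initial condition
instead).  Green tests on synthetic blocks therefore certify the
pipeline's statistical machinery, not the realism of any particular
human dyad's torque waveform.

## Study sizes used by the shipped checks

The test suite and `scripts/acceptance.py` use: 20 random cost matrices
for the Riccati/dynamic-programming comparison (horizon 10⁵);
10 random walkable-lattice dyads for parameter recovery (200 iterations
each); 2000 null replicates for the type-I calibration of the
per-coefficient ANOVA (expected rate 0.05, asserted within
[0.04, 0.06]); 15 replicate blocks for the injected-plan-change power
check (q_pos 2 → 6 in bins 4–6, power asserted ≥ 0.8); and two full
pipeline runs for byte-identity.  These sizes keep a full run in the
low minutes on one CPU while leaving Monte-Carlo error well inside the
asserted margins.

## Known limitations

- The model is linear and noise-free inside the controller; there is no
  state estimation, signal-dependent noise, or nonlinear musculoskeletal
  dynamics, and stability of aggressive plans is bounded by the muscle
  filter (solo overshoot saturates near +2.5° regardless of q_pos).
- The free-running LQR cannot hold the pre-movement torque constraint;
  see the two initial-condition constructors above.
- The lattice search inherits the parity restriction and decoy basins
  described above; its estimates are best interpreted through the
  position-priority ratio rather than raw weights.
- Each dyad and block is analysed separately; no pooled or mixed-effects
  inference, and no multiplicity control beyond the Bonferroni-adjusted
  Scheffé step.
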
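# dyadreach

Simulation and trial-by-trial analysis of **dyadic wrist reaching**:
two people, rigidly coupled wrist-to-wrist through a stiff virtual
spring, jointly steer an averaged cursor from −10° to a 30° target.
Who pushes, who brakes, and does anyone change their plan from trial to
trial?  This package provides the computational apparatus to answer
that from kinematic and torque recordings:

- **`dyadreach.model`** — a discrete-time state-space model of one or
  two coupled wrists.  Each agent's state is x = [θ, θ̇, τ, f]ᵀ with a
  second-order muscle filter (τ_u = 40 ms) and an infinite-horizon LQR
  controller minimising Σ xᵀQx + u R u with Q = diag(q_pos, q_vel, 0, 0),
  R = 0.5.  Partners plan independently and interact only through the
  coupling torque K Δθ + D Δθ̇ (K = 0.4 Nm/deg, D = 0.05 Nm·s/deg) —
  *co-activity*, no joint plan.  A position-hold endgame rule lets
  agents freeze once the averaged cursor reaches the target, which is
  the only way optimal agents end a reach with sustained opposing
  torque.
- **`dyadreach.identify`** — recovers both partners' *motion plans*
  (q_pos, q_vel, θ_target each) from a block's mean angle/torque curves
  by greedy lattice search over the 64 one-step sign permutations,
  minimising the variance-normalised squared distance
  M = (1/2L) Σ [(θ̄−θ)²/σ²_θ + (τ̄−τ)²/σ²_τ].
- **`dyadreach.preprocess`** — raw 100 Hz recordings → onset-aligned,
  1.2 s, 256-sample, zero-phase 6 Hz low-pass filtered curves, binned
  6 × 5 per 30-trial block.
- **`dyadreach.wavelet_anova`** — wavelet-domain functional ANOVA:
  coiflet-3 level-4 periodized transform (exactly 256 coefficients),
  per-coefficient one-way ANOVA across bins, Scheffé post hoc with
  Bonferroni adjustment, and reconstruction of significant time-domain
  difference curves with their time windows.
- **`dyadreach.synthetic`** — a seeded generator of realistic raw
  blocks (motor noise, plan jitter, onset jitter, smooth sensor noise,
  optional mid-block plan changes and ±0.7 Nm push-pull pre-loads), so
  the whole pipeline is testable without human recordings.

The analysis-facing pieces are scikit-learn-style estimators
(`TrialPreprocessor`, `MotionPlanIdentifier`, `WaveletBinAnova`) and
compose with sklearn tooling; every operation is also exposed as a
plain function.  A `dyadreach` CLI (`generate`, `prep`, `analyze`,
`identify`, `run`) drives the same library code on delimited-text
files.

## Worked example

```python
import dyadreach as dr

plant = dr.PlantParams()                       # K=0.4, D=0.05, dt=0.01, tau_u=0.04
pusher = dr.MotionPlan(q_pos=25.0, q_vel=0.01) # position-priority agent
puller = dr.MotionPlan(q_pos=2.5,  q_vel=0.05) # velocity-priority agent
x0 = (dr.WristState(-10, 0, 0, 0), dr.WristState(-10, 0, 0, 0))

trace = dr.simulate_dyad(pusher, puller, plant, x0, 3.0,
                         hold_rule=True, hold_target=30.0)
print(f"hold fired at t = {trace.hold_switch_index * plant.dt:.2f} s")
print(f"final angles: {trace.angle(0)[-1]:.2f} deg / {trace.angle(1)[-1]:.2f} deg")
print(f"terminal interaction torque: {trace.data_torque[-1]:.2f} Nm")
```

```
hold fired at t = 0.74 s
final angles: 30.55 deg / 29.72 deg
terminal interaction torque: 0.33 Nm
```

The position-priority agent drives the pair across the target and ends
*overshooting* it (30.55°), the velocity-priority agent ends
*undershooting* (29.72°), and because both freeze at the hold the spring
keeps transmitting a constant 0.33 Nm — the characteristic signature of
a driver/braker dyad.  Without `hold_rule` the same pair's torque peaks
and then decays to zero.

Plan identification inverts this: given a block's mean curves, the
lattice search recovers the plans that produced them.

```python
truth1 = dr.MotionPlan(4.0, 0.2, theta_target=28.0)
truth2 = dr.MotionPlan(4.0, 0.2, theta_target=32.0)
stats = dr.noiseless_block_statistics(truth1, truth2)
ident = dr.MotionPlanIdentifier(n_iterations=200).fit(stats)
print("identified parameters:", ident.result_.params)
print(f"fit metric M = {ident.fit_metric_:.3g}")
```

```
identified parameters: [ 4.   0.2 28.   4.   0.2 32. ]
fit metric M = 3.31e-29
```

Both agents' cost weights and private targets are recovered exactly
(the metric is numerically zero).  `compare_plans` then summarises
between-block changes as shifts in the scale-invariant
position-priority ratio q_pos/(q_pos+q_vel).

The same flow from the shell:

```sh
dyadreach run --seed 1 --out run1/
# run1/: raw trials + manifest, block_statistics.csv, anova_{torque,angle}.csv,
#        difference_curves/, identified_plan.csv, run_log.txt
```

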
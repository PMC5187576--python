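# Methods

This note documents the model equations, the numerical and design choices
behind the shipped defaults, what the simulated plants do and do not
emulate, and the known limitations.

## Circuit and dynamics

Populations: mossy fibers (MF; 5 channels for the motor plant, 7 for the
robot), 755 granule cells (GC) whose axons are the parallel fibers (PF),
5 Golgi cells (GO), 15 basket/stellate cells (BA), 1 Purkinje cell (PC).
Per control sample (t_s = 10 ms), in order:

1. granule drive `x_GC = y_MF (M∘W)_MF-GC + y_GO(t−1) (M∘W)_GO-GC`,
2. `y_PF = σ(x_GC)` with `σ(x) = 1/(1+e^{−8(x−1/2)})`,
3. Golgi drive from current `y_MF` and `y_PF`, then `y_GO = σ(x_GO)`,
4. basket drive from `y_PF`, then `y_BA = σ(x_BA)`,
5. Purkinje drive `x_PC = y_PF W_PF-PC + y_BA W_BA-PC`,
   `y_PC = σ(x_PC) − 1/2`.

`M` are binary masks with exact convergence counts (MF→GC 4, GO→GC 3,
PF→GO 150, PF→BA 50; MF→GO, PF→PC and BA→PC are fully connected — the
published divergence figures are mutually inconsistent with the population
sizes, so convergence is what the implementation enforces).  The GC↔GO
recurrence is closed with a one-sample delay on the GO→GC arm; this is
the standard discrete-time resolution and is also load-bearing for the
robot preset (below).

Plasticity acts only on the PF→PC vector:
`ΔW = −γ (y_PF − 1/2) CF(t)`, `γ = 0.008` per sample, with the updated
weights clipped to `[10⁻⁶, 1]` to keep the synapse excitatory.

## Mossy-fiber encoding

Each channel's physical signal (rad, rad/s or A) is multiplied by its
fixed gain and passed through the same sigmoid, **centred on the
activation midpoint**: a zero signal encodes to the mid rate 0.5 and
signed excursions encode above/below it.  The zero-centred factor
`(y_PF − 1/2)` in the learning rule presupposes rates that straddle 0.5 —
with rates centred near the sigmoid's foot instead, every weight moves in
lockstep with the CF sign, the update rail-locks against the clip bounds
within a cycle or two, and depression/potentiation counts become
degenerate.  Channel gains: motor — desired position 0.1 rad⁻¹, desired
velocity 0.19 s/rad, position error 0.5 rad⁻¹, velocity error 0.07 s/rad,
efference copy 1 A⁻¹; robot — desired wheel position 0.03 rad⁻¹, desired
wheel velocity 0.04 s/rad, tilt error 1 rad⁻¹, tilt-rate error 0.5 s/rad,
wheel position error 0.1 rad⁻¹, wheel velocity error 0.2 s/rad, efference
copy 0.5 A⁻¹.  The efference channel carries the previous sample's total
plant command.

## Weight initialization and operating point

Weights are drawn by rejection sampling from Normal(0.5, 1) truncated to
(0, 1] (excitatory) and Normal(−0.5, 1) truncated to [−1, 0)
(inhibitory); rejection avoids the point masses at the bounds that
clipping would create.  Raw draws summed over hundreds of inputs would
saturate every sigmoid (the PC alone sums 755 PF inputs), so each
projection is then rescaled by one deterministic scalar
`min(1, T / (0.5 c))` toward a target column sum `T` (`c` = convergence
count).  The targets are per-plant presets:

| projection | motor preset T | robot preset T |
|---|---|---|
| MF→GC | 1.5 | 1.3 |
| GO→GC | −0.5 | −1.0 |
| MF→GO | 0.5 | 0.1 |
| PF→GO | 0.5 | 0.9 |
| PF→BA | 1.0 | 3.0 |
| PF→PC | 16 | 31 |
| BA→PC | −15 | −15 |

Two considerations set these numbers.  First, *depression headroom*: the
learned correction requires per-synapse weight excursions comparable to
the mean weight, so the plastic pool's column sum must be large (16–31)
with basket inhibition balancing it; otherwise depression saturates at
the lower clip bound, which rectifies oscillating updates upward and
locks the PC at its rail.  Second, *plasticity-loop gain*: with 755
synapses updated at 100 Hz, γ = 0.008 slews the Purkinje drive across its
whole sensitive range within a cycle unless the granule code is kept
temperate.  The motor preset does this with moderate drive targets.  The
robot preset instead drives the delayed GC↔GO loop (PF→GO 0.9, GO→GC −1)
past its oscillation threshold: the granular layer settles into an
alternating (period-2, 50 Hz) regime in which `(y_PF − 1/2)` flips sign
every sample while the CF varies slowly, so consecutive updates cancel to
first order and only the slower covariance between granule modulation and
the CF accumulates — an effective learning-rate reduction of roughly two
orders of magnitude that prevents rail-locking on the much slower, harder
robot task.  Granular-layer oscillations are a documented feature of the
real circuit; here their discrete-time analogue doubles as the gain
control that makes the published γ usable on this plant.

After drawing, a *Purkinje-saturation guard* rescales `W_BA-PC` by a
single logged scalar so the nominal mid-rate Purkinje drive
`0.5 (ΣW_PF-PC + ΣW_BA-PC)` equals the midpoint exactly, preventing
over-inhibition of the single output cell.  The guard scalar (≈1.9 motor,
≈3.8 robot) stretches basket weights beyond the unit interval of the raw
draw; the drawn values are recoverable by dividing by the logged scalar.
Even so, the realized closed-loop network starts with a strongly biased
Purkinje output; the first few cycles of learning re-centre it, visible
as an initial-cycle overshoot that disappears by roughly cycle 5.

## Teaching signals and command path

Errors are desired − actual.  PD command: motor `0.8 φ_e + 0.01 φ̇_e`;
robot `(5 θ_e + 0.5 θ̇_e) + (0.2 φ_e + 0.05 φ̇_e)` (desired tilt ≡ 0).
Teaching signals:

* SE (kinematic): `0.5 φ_e + 0.02 φ̇_e`, plus `5 θ_e + 0.5 θ̇_e` for the
  robot;
* ME (motor-command): `c1 ·` PD output with `|c1| = 0.4 A⁻¹`;
* SE+ME: their sum; NONE: CF ≡ 0 (learning off).

The plant current is `PD − gain · y_PC` (the Purkinje projection is
inhibitory).  Because both teaching signals respond to a Purkinje
perturbation through the same plant pathway — `∂SE/∂y_PC ∝ a1·E` and
`∂ME/∂y_PC ∝ c1·k_p·E` with a shared loop factor `E` — `c1` must carry
the same sign as `a1` for both modes to close negative-feedback
plasticity loops; with opposite signs exactly one of the two is driven by
runaway positive feedback regardless of the network's operating point.
The package therefore ships `c1 = +0.4 A⁻¹`.  The CF is passed to the
learning rule unclipped (an optional symmetric clip exists in config).

The Purkinje-to-command gain defaults to 0.3 A (motor) and 0.15 A
(robot) per unit rate: large enough that the bounded `y_PC ∈ (−1/2, 1/2)`
can supply the feedforward current each task needs, small enough that the
plasticity loop stays below its oscillation threshold.

## Plants

Both plants are linear ODE systems integrated by fixed-step RK4 at
`dt_inner = 1 ms` under zero-order-hold current over each 10-ms control
period.  For a linear time-invariant system this integrator is exactly an
affine map per period, so the implementation precomputes the RK4
transition matrices once and applies one matrix-vector product per step —
bit-equivalent to looping RK4, ~40× faster.

*Motor*: `J φ̈ = K_t i − B φ̇` with `J = 10⁻⁵ kg·m²`, `B = 2·10⁻⁴ N·m·s`,
`K_t = 0.01 N·m/A` — a small hobby-class motor whose PD position loop has
≈4.5 Hz natural frequency, tracking the 0.5-Hz stimulus competently
(PD-only RSE ≈ 0.18 rad) while leaving a visible error to learn away.

*Robot*: the standard linearized wheeled-inverted-pendulum pair (wheel
angle φ, tilt θ, masses 0.8/0.05 kg, wheel radius 2.5 cm, COM height
10 cm), with the wheel-motor polarity `τ = −K_t i`: on a balancing robot
the effective current-to-wheel-position gain under a stabilized tilt is
inverted, and of the two possible polarities only this one is stabilized
by the standard positive PD gains (verified by eigenvalue computation:
open loop max Re λ ≈ +15.3 s⁻¹, PD-closed loop ≈ −1.6 s⁻¹).  Tilt beyond
π/4 marks the trial failed.  Sensors are noiseless and delay-free; there
is no actuator saturation by default.

## Protocol and metric

`φ_des = π sin(2πft)`, f = 0.5 Hz (motor) or 0.2 Hz (robot), 100 cycles,
five replicate weight initializations (seeds 1–5), plus a PD-only
baseline run with the identical loop and the cerebellar output
disconnected (deterministic, seed-independent).  RSE is computed per
stimulus cycle (cycle k = samples with `⌊t·f⌋ = k`), and "late" summaries
average cycles 91–100.  The robot trials store the full granule-rate
history in float32 when the correlation analyses are requested
(755 × 50 000 ≈ 150 MB).

## Analyses

Weight-change census uses strict inequalities with a 10⁻¹² tie tolerance.
Granule cells are sorted by final-minus-initial plastic weight (most
depressed first); Pearson correlations of each cell's rate series against
a reference signal (CF, wheel error, desired position) are computed over
the whole record and smoothed with a centred 13-point moving average whose
window truncates symmetrically at the edges.  The rotated trajectory view
maps (desired, yielded) to `x' = (φ_des + φ)/√2, y' = (φ − φ_des)/√2`, so
perfect tracking is the line y' = 0; which rotation sense maps overshoot
above the line is a convention, documented rather than asserted.

## What the experiments show — and what they do not

With the shipped defaults, all three CF contents beat the PD-only
baseline for every default seed on both plants (motor ≈ 66–73%
improvement; robot ≈ 3–6%, no tip-overs), and on the motor the classic
adaptive-filter signature emerges: cells whose PF→PC synapses potentiated
are anticorrelated with the CF, depressed cells positively correlated,
with 76–78% of synapses depressed.  On the robot the depressed cells are
CF-correlated and the depressed fraction is higher under ME than SE, but
the potentiated tail's correlation stays positive: the CF retains a small
slowly-decaying mean on this plant, and its accumulated product with the
per-cell mean rates dominates the covariance term, also pushing the
depressed fraction above 90%.  About one robot initialization in eight
(outside the default seed set) still rail-locks under SE — the
over-inhibition failure mode is genuinely nearby in this model class.

The plants are noiseless linear stand-ins: no sensor noise or delay, no
friction nonlinearity, no motor electrical pole, no large-angle pendulum
terms.  Passing results therefore demonstrate the learning architecture's
behaviour in a clean closed loop, not robustness to real-world sensing;
quantities tied to hardware specifics (absolute RSE values, exact
depressed fractions, ME-vs-SE phase lags at higher frequencies) should be
read qualitatively.

## Numerical notes

Rates live in mathematically open intervals but can round onto the bounds
at double precision when drives saturate (|x| ≳ 5).  Seeds expand through
`numpy.random.SeedSequence` spawning, one independent stream per
projection, so masks and each weight matrix are reproducible
independently.  Trials are bit-reproducible for a given seed and config.
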
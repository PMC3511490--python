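# Methods

## Plant model

One agent's arm is reduced to the force it exerts on a shared point mass
along one axis.  The neural control signal u passes through a Winter-type
activation filter — a second-order low-pass written as two cascaded
first-order stages with an auxiliary state g:

    τ₁ ġ = u − g ,   τ₂ Ḟ = g − F .

Both stages are normalized to unit DC gain.  The gain of the activation
filter is a free modelling choice; unity makes u directly interpretable as
the desired steady-state force and keeps the LQR effort weight r in force
units, so we fix it.  Defaults τ₁ = 0.03 s, τ₂ = 0.04 s give an activation
bandwidth in the range usually quoted for human muscle twitch dynamics
(~70 ms rise); both are configurable per agent.  The cascade is linear and
therefore commutative in (τ₁, τ₂).

Kinematics are Newton's law for the object mass (default M = 1 kg) driven
by the SUM of both agents' forces — the rigid coupling is the entire
interaction channel.  Everything is discretized by forward Euler at
dt = 0.01 s.  An exact zero-order-hold discretization is available
(`PlantConfig(discretization="zoh")`) but Euler is the default: the whole
control design lives in discrete time, and the simple Euler matrices are
the reference definition of the plant.  Consequences of that choice are
quantified below under *Numerical accuracy*.

The per-agent state is [e, v, F, g] with e = p − p\* the error to the
agent's own target; the dyad stacks both agents' states into the redundant
8-vector [e₁, v₁, F₁, g₁, e₂, v₂, F₂, g₂].  The redundancy is deliberate:
per-agent diagonal cost matrices can then address "own" and "partner"
blocks verbatim, and a target offset is purely a shift of agent 2's error
read-out (e₂ = e₁ + δ), leaving the synthesis problem untouched.

## Behavior presets

Each behavior class is a zero/sign/symmetry pattern on the pair of cost
weights (see the table in `presets.yaml`).  The *numeric* preset values are
a calibration, frozen once: they were chosen so that the golden scenarios
reproduce the reference effort/time ratios that characterize each role
(assistance slave/master effort ratio ≈ 2.7; education teacher/student
effort 0.75 with a hardworking and 3.59 with a lazy student; lazy/hardworking
reach-time ratio toward 1.11; co-activity duration penalty > 20 %, peak
force ≤ 7 N and ~0.5 N terminal standoff) while keeping the qualitative
orderings that define the roles — the master's metabolic weight far above
the slave's, the lazy student's error weight low and metabolic weight high,
the stronger co-activity agent distinguished **only** by a lower metabolic
weight.  With the teacher's cost held fixed across both education runs (as
the scenario demands), the three education targets are not independent:
matching both effort ratios pins the reach-time ratio near 1.17, which is
where the package leaves it.

Velocity weights are kept at 1 % of the corresponding error weight
throughout — enough damping to prevent terminal oscillation without
affecting the effort ratios.

One modelling subtlety: the weight on the partner's muscle-force state
(`w_force_partner`, the partner-energy proxy of the slave and of mutual
assistance) is *policy-inert*.  The partner's muscle block is not
controllable from the agent's own input, so a diagonal weight there shifts
the value function but leaves the optimal gain unchanged.  It is kept
because it is structurally meaningful — it is what separates the slave
(minimizes the master's error *and* energy) from the teacher (minimizes the
student's error but its *own* energy), and mutual assistance from
collaboration — and the classifier keys on exactly this pattern.

## Gain synthesis on a rigidly coupled state

Each agent's gain is synthesized independently on the full dyad
(A, Bᵢ, Qᵢ, rᵢ), treating the partner's input as zero; both loops are then
closed simultaneously.  This "iterated best response with a silent partner"
is the standard engineering route; a coupled feedback-Nash synthesis is out
of scope.

The rigid coupling makes the stationary Riccati problem singular in an
instructive way: both kinematic copies are driven by the same total force,
so the difference coordinates v₁ − v₂ and e₁ − e₂ are constants of the
motion — uncontrollable modes on the unit circle.  Whenever a cost weights
any e or v entry these modes are cost-observable and the value matrix P
grows without bound along them.  The *gain*, however, converges: the
backward Riccati recursion is therefore stopped on gain stationarity
(relative change < 1e-10) rather than value stationarity, after a warm-up
of a few state dimensions (the weight needs several steps to propagate
through the e ← v ← F ← g chain, during which the gain sits exactly at
zero).  On the rigid-coupling manifold the converged gain coincides, to
~1e-8, with the stabilizing DARE solution of the reduced 6-state problem
(shared e, v plus both muscle pairs); the test suite checks this against
`scipy.linalg.solve_discrete_are` as an independent oracle.

Indefinite Q (competition-type costs with negative partner weights) need
not admit a stationary solution at all; `solve_dare` then switches to a
plain finite-horizon backward pass (default 2000 steps, zero terminal
weight) and warns.  R must always be positive definite; strictly unstable
uncontrollable modes are rejected by a PBH test.

## Scenarios and metrics

All golden scenarios use M = 1 kg, 2 m initial error, dt = 0.01 s and a
10 s horizon (1000 steps — seconds of CPU for the whole set).  Simulations
never stop early on reach, so terminal metrics are well defined; a state
norm above 1e6 aborts with a diagnostic.  Metrics:

- **effort** ∑F²·dt per agent (N²·s) — the metabolic-cost proxy;
- **reach time** — first t with |e₁| ≤ (1 − f)·|e₁(0)|, reach fraction
  f = 0.9 by default.  The fraction is configurable and deliberately kept
  out of the sharp quantitative checks (reach-time *ratios* are insensitive
  to it, absolute reach times are not);
- **peak force** max|Fᵢ|;
- **terminal force** — mean |Fᵢ| over the final 10 % of the run, a
  robust estimator of the asymptotic standoff force that tolerates residual
  oscillation.

The antagonistic co-activity scenario separates the two targets by 0.5 m
and lowers agent 1's metabolic weight (r = 1.5 vs 5).  The object settles
between the targets, nearer the stronger agent's, with equal and opposite
residual forces — the standoff ("co-contraction") of about 0.5 N per agent.
Because neither agent models the other, this equilibrium is imposed by the
dominant agent rather than negotiated.

## Adaptation (assist as needed)

Control is feedforward plus fixed feedback, u = θᵀφ(p, v) − K z, with the
gradient learning law

    θ ← θ + dt · ( α φ · (−ε) − γ θ ) ,   ε = e + 0.2 v ,

where α is the learning rate (1/s) and γ the forgetting (effort-decay)
rate.  The regressor is pluggable; shipped are a constant regressor and a
constant-plus-RBF regressor over the movement range.  The training task is
to *hold* the object on target against a constant disturbance force: unlike
the reaching transient, the disturbance admits an exact feedforward
compensation, so the error can genuinely be annihilated and θ has a well
defined fixed point (θ → −d with a constant regressor, forgetting 0 and a
pure error/velocity feedback; with an LQR feedback the force-state feedback
terms shift the fixed point by a computable offset, which is why the
parameter-recovery test uses a PD gain).  A trainer with γ > 0 gives up
whatever force the learner takes over — across trials its effort fades
toward zero when the learner adapts, and stays high when the learner cannot
(rate 0).  Updates are per-step, so the law applies to arbitrary movements,
not only repeated trials.

## Numerical accuracy

- Halving dt changes effort *ratios* and reach times of the golden
  scenarios by < 1 %.  Absolute efforts and the peak force carry the
  first-order global error of the Euler muscle filter, about 2 % at
  dt = 0.01 with τ of 30–40 ms; the test suite asserts < 3 % for these.
  All quantitative checks on the golden ratios use ±10 % and are re-run at
  dt/2.
- Riccati tolerances: 1e-10 relative, 1e5 iterations maximum; symmetry is
  enforced each step.  Weight-pattern symmetry comparisons in the
  classifier use a relative 1e-9.
- Everything is deterministic; the `seed` field in configs is reserved and
  unused by the dynamics.

## Limitations

- Linear point-mass plant, single axis, no signal-dependent noise, no
  perception noise of own or partner state, full-state feedback for both
  agents.  Role *switching* during a task is not modelled: each run has
  frozen cost functions.
- The per-agent LQR route treats the partner as silent during synthesis;
  for strongly adversarial weight pairs this is not a Nash equilibrium and
  the closed loop can even diverge (the simulator guards and reports this).
- Preset weight values are a calibrated realization of the taxonomy's
  qualitative patterns, not measurements; only the patterns themselves and
  the reproduced ratio targets carry meaning.
- The compliant-coupling case (springy grasp, contact breaking) and dyads
  of more than two agents are out of scope.
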
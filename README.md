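# dyadsim

Simulation of **dyadic motor interaction**: two agents (human–human,
human–robot or robot–robot) rigidly coupled through a single object, each
minimizing its own quadratic error/effort cost function.  The package
implements a cost-function **taxonomy of interactive behaviors** —
co-activity, competition, collaboration, assistance (master–slave),
education (teacher–student) and mutual assistance — and generates the
corresponding motor behavior with per-agent linear-quadratic regulators
(LQR), plus an error/effort-driven feedforward adaptation law that produces
assist-as-needed training.

It is aimed at researchers in computational motor control, physical
human–robot interaction and rehabilitation robotics who want a small,
deterministic sandbox for role distribution in joint motor tasks.

## Model

Each agent *i* drives a shared point mass *M* through a muscle modelled as a
second-order low-pass filter (two cascaded first-order stages with unit DC
gain and time constants τ₁, τ₂):

    τ₁ ġᵢ = uᵢ − gᵢ ,   τ₂ Ḟᵢ = gᵢ − Fᵢ ,   M p̈ = F₁ + F₂ ,

discretized with forward Euler at dt.  With the error eᵢ = p − p*ᵢ to agent
*i*'s target, the per-agent state is xᵢ = [eᵢ, vᵢ, Fᵢ, gᵢ] and the dyad
stacks both: z = [e₁, v₁, F₁, g₁, e₂, v₂, F₂, g₂], coupled through the sum
of forces in both velocity rows.

Agent *i* minimizes

    Jᵢ = Σₖ zₖᵀ Qᵢ zₖ + rᵢ uᵢ,ₖ² ,

where the diagonal of Qᵢ places weights on the agent's own error/velocity,
on the partner's error/velocity (negative for competition) and optionally on
the partner's muscle force (a partner-energy proxy).  The zero/sign/symmetry
pattern of (Q₁, Q₂) *is* the behavior: e.g. an assistance slave has zero
self-error weight, high partner-error weight and a partner-force weight,
while an education teacher weights the student's error but preserves its own
energy.  Gains Kᵢ solve the discrete-time algebraic Riccati equation for
(A, Bᵢ, Qᵢ, rᵢ) independently per agent; both loops are then closed
simultaneously, uᵢ = −Kᵢ z.

## Worked example

```bash
$ dyadsim reference
scenario                       eff1     eff2   ratio   reach   peak
assistance                    2.721    1.005   2.708    2.05   3.50
collaboration                 1.977    1.977   1.000    1.93   3.04
education-hardworking         2.172    2.878   0.755    1.79   3.80
education-lazy                2.930    0.805   3.642    2.10   3.55
coactivity-antagonistic       5.685    3.979   1.429    3.11   4.08

assistance slave/master effort ratio : 2.708
education teacher/student effort     : hardworking 0.755, lazy 3.642
education lazy/hardworking speed     : 1.173
co-activity duration increase        : 58.1% over the mean of the others
co-activity terminal standoff forces : 0.496 / 0.496 N
```

Reading the table: `eff` is each agent's effort ∑F²·dt (N²·s), `reach` the
time (s) to cover 90 % of the 2 m initial distance, `peak` the largest
force (N).  The slave supplies ~2.7× the master's effort; with a hardworking
student the teacher contributes only 0.75 of the student's effort but a lazy
student forces the teacher to 3.64×, and the movement is ~1.17× slower; the
antagonistic co-activity run (targets 0.5 m apart, one agent stronger via a
lower metabolic weight) is over 20 % slower than the cooperative schemes and
ends in a force standoff of ~0.5 N per agent even though the object has
stopped.

The same is available from Python:

```python
from dyadsim import scenario_from_preset, run_scenario, compute_metrics

m = compute_metrics(run_scenario(scenario_from_preset("assistance")))
print(m.effort_ratio)        # 2.708...
```

Other entry points: `dyadsim run --scenario assistance --out out/` (CSV time
series + JSON metrics + manifest), `dyadsim classify --config cfg.yaml`
(taxonomy label with decision trace), `dyadsim train` (trainer/learner
adaptation loop with fading assistance).

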
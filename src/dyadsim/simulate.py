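"""Closed-loop scenario execution and the interaction metrics.

A scenario is a behavior preset plus plant parameters.  Both agents' LQR
loops are closed simultaneously on the shared object,

    u_i(k) = -K_i z(k),

each agent reading the state in its OWN error coordinates (a target offset
shifts agent 2's position feedback).  From the resulting time series the
package computes the quantities used to characterize the interaction: each
agent's effort (integral of squared force), the effort ratio, the time to
cover a configured fraction of the initial distance, and peak / terminal
force magnitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .arm_plant import AgentParams, PlantConfig
from .behaviors import Behavior, BehaviorLabel, CostWeights, available_presets, preset
from .dyad import DyadSystem, build_dyad
from .lqr import agent_gain

DIVERGENCE_LIMIT = 1e6

#: Names of the golden scenarios shipped with the package.
GOLDEN_SCENARIOS = ("assistance", "collaboration", "education-hardworking",
                    "education-lazy", "coactivity-antagonistic")


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete description of one closed-loop run.

    ``seed`` is reserved for forward compatibility: the dynamics are
    deterministic and no randomness is consumed.
    """

    label: BehaviorLabel = field(
        default_factory=lambda: BehaviorLabel(Behavior.COLLABORATION))
    weights: tuple[CostWeights, CostWeights] | None = None
    agent1: AgentParams = field(default_factory=lambda: AgentParams(label="agent1"))
    agent2: AgentParams = field(default_factory=lambda: AgentParams(label="agent2"))
    plant: PlantConfig = field(default_factory=PlantConfig)
    initial_error: float = 2.0
    duration: float = 10.0
    reach_fraction: float = 0.9
    seed: int = 0
    name: str = "scenario"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0 < self.reach_fraction < 1:
            raise ValueError("reach_fraction must be in (0, 1)")

    def resolve_weights(self) -> tuple[CostWeights, CostWeights]:
        return self.weights if self.weights is not None else preset(self.label)


@dataclass(frozen=True)
class SimulationResult:
    """Time series of one run; ``F1/F2/u1/u2`` have one entry per step."""

    t: np.ndarray
    e: np.ndarray
    v: np.ndarray
    F1: np.ndarray
    F2: np.ndarray
    u1: np.ndarray
    u2: np.ndarray
    config: ScenarioConfig
    gains: tuple[np.ndarray, np.ndarray]

    @property
    def dt(self) -> float:
        return self.config.plant.dt


@dataclass(frozen=True)
class Metrics:
    """Derived interaction metrics; ``reach_time`` is ``inf`` when the
    configured fraction of the distance is never covered."""

    effort_1: float
    effort_2: float
    effort_ratio: float
    reach_time: float
    reached: bool
    peak_force_1: float
    peak_force_2: float
    terminal_force_1: float
    terminal_force_2: float

    def to_dict(self) -> dict:
        return {
            "effort_1": self.effort_1,
            "effort_2": self.effort_2,
            "effort_ratio": self.effort_ratio,
            "reach_time": self.reach_time if self.reached else None,
            "reached": self.reached,
            "peak_force_1": self.peak_force_1,
            "peak_force_2": self.peak_force_2,
            "terminal_force_1": self.terminal_force_1,
            "terminal_force_2": self.terminal_force_2,
        }


def scenario_from_preset(name: str, **overrides) -> ScenarioConfig:
    """Build one of the golden scenarios (see ``GOLDEN_SCENARIOS``)."""
    table = available_presets()["scenarios"]
    try:
        entry = table[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(table)}") from None
    label = BehaviorLabel(Behavior(entry["behavior"]), tuple(entry["roles"]))
    w1, w2 = preset(label)
    for agent_key, w in (("agent1", w1), ("agent2", w2)):
        for fld, val in entry.get("overrides", {}).get(agent_key, {}).items():
            w = type(w)(**{**w.__dict__, fld: val})
        if agent_key == "agent1":
            w1 = w
        else:
            w2 = w
    offset = float(entry.get("target_offset", 0.0))
    a1 = AgentParams(label=entry["roles"][0], target=0.0)
    a2 = AgentParams(label=entry["roles"][1], target=offset)
    return ScenarioConfig(label=label, weights=(w1, w2), agent1=a1, agent2=a2,
                          name=name, **overrides)


def run_scenario(cfg: ScenarioConfig) -> SimulationResult:
    """Close both agents' loops simultaneously and step the dyad.

    Raises ``FloatingPointError`` with a diagnostic if the joint state leaves
    the ``DIVERGENCE_LIMIT`` ball (possible for adversarial weight choices).
    """
    sys = build_dyad(cfg.agent1, cfg.agent2, cfg.plant)
    w1, w2 = cfg.resolve_weights()
    K1 = agent_gain(sys, w1, 1)
    K2 = agent_gain(sys, w2, 2)
    dt = cfg.plant.dt
    n = int(round(cfg.duration / dt))
    z = sys.initial_state(cfg.initial_error)
    e = np.empty(n + 1); v = np.empty(n + 1)
    F1 = np.empty(n); F2 = np.empty(n)
    u1 = np.empty(n); u2 = np.empty(n)
    e[0], v[0] = z[0], z[1]
    A, B1, B2 = sys.A, sys.B1[:, 0], sys.B2[:, 0]
    K1v, K2v = K1.ravel(), K2.ravel()
    for k in range(n):
        u1[k] = -float(K1v @ z)
        u2[k] = -float(K2v @ z)
        z = A @ z + B1 * u1[k] + B2 * u2[k]
        if np.max(np.abs(z)) > DIVERGENCE_LIMIT:
            raise FloatingPointError(
                f"state diverged at t={k * dt:.3f} s (|z|={np.max(np.abs(z)):.2e}); "
                "check the cost weights")
        e[k + 1], v[k + 1] = z[0], z[1]
        F1[k], F2[k] = z[2], z[6]
    t = np.arange(n + 1) * dt
    return SimulationResult(t=t, e=e, v=v, F1=F1, F2=F2, u1=u1, u2=u2,
                            config=cfg, gains=(K1, K2))


def compute_metrics(res: SimulationResult, reach_fraction: float | None = None) -> Metrics:
    """Interaction metrics of a completed run.

    Effort is the rectangle-rule integral of squared force; the terminal
    force is the mean absolute force over the final 10 % of the run (robust
    to residual oscillation); reach time is the first time the object error
    falls to ``(1 - reach_fraction)`` of its initial magnitude.
    """
    frac = res.config.reach_fraction if reach_fraction is None else reach_fraction
    dt = res.dt
    eff1 = float(np.sum(res.F1 ** 2) * dt)
    eff2 = float(np.sum(res.F2 ** 2) * dt)
    thr = (1.0 - frac) * abs(res.e[0])
    hit = np.nonzero(np.abs(res.e) <= thr)[0]
    reached = hit.size > 0
    reach_time = float(hit[0] * dt) if reached else math.inf
    ntail = max(1, res.F1.size // 10)
    return Metrics(
        effort_1=eff1,
        effort_2=eff2,
        effort_ratio=eff1 / eff2 if eff2 > 0 else math.inf,
        reach_time=reach_time,
        reached=reached,
        peak_force_1=float(np.max(np.abs(res.F1))),
        peak_force_2=float(np.max(np.abs(res.F2))),
        terminal_force_1=float(np.mean(np.abs(res.F1[-ntail:]))),
        terminal_force_2=float(np.mean(np.abs(res.F2[-ntail:]))),
    )


def compare_scenarios(
    a: Metrics | list[Metrics], b: Metrics | list[Metrics]
) -> dict:
    """Relative report of run ``b`` against baseline ``a``.

    Either side may be a list, in which case its mean metrics are used
    (one-vs-mean-of-many comparisons).  Speed ratio is
    ``b.reach_time / a.reach_time``; the duration change is the same
    quantity as a percentage.  Raises ``ValueError`` when a reach time is
    undefined.
    """
    base = a if isinstance(a, list) else [a]
    others = b if isinstance(b, list) else [b]
    if any(not m.reached for m in base + others):
        raise ValueError("cannot compare runs that never reached the target")
    rt_a = float(np.mean([m.reach_time for m in base]))
    rt_b = float(np.mean([m.reach_time for m in others]))
    speed_ratio = rt_b / rt_a
    mean = lambda ms, f: float(np.mean([getattr(m, f) for m in ms]))  # noqa: E731
    return {
        "speed_ratio": speed_ratio,
        "duration_change_pct": 100.0 * (speed_ratio - 1.0),
        "effort_1_delta": mean(others, "effort_1") - mean(base, "effort_1"),
        "effort_2_delta": mean(others, "effort_2") - mean(base, "effort_2"),
    }


def run_golden_table(plant: PlantConfig | None = None) -> dict[str, Metrics]:
    """Run all golden scenarios and return their metrics, keyed by name."""
    out: dict[str, Metrics] = {}
    for name in GOLDEN_SCENARIOS:
        kwargs = {} if plant is None else {"plant": plant}
        cfg = scenario_from_preset(name, **kwargs)
        out[name] = compute_metrics(run_scenario(cfg))
    return out
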
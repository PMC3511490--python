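"""Error/effort-driven feedforward adaptation ("assist as needed").

Each adaptive agent issues ``u = u_ff + u_fb``: a fixed LQR feedback plus a
learned feedforward ``u_ff = theta' phi(p, v)``.  The parameters follow a
gradient law on the error-plus-effort objective,

    theta <- theta + rate * phi * eps - forgetting * theta,

where ``eps`` is a tracking-error signal (here ``-(e + kappa_v v)``, so that
a positive standing error grows a compensating negative force) and the decay
term implements effort minimization: parameters that are not needed to keep
the error small are given up.  A trainer with nonzero forgetting therefore
cedes work to a learner who keeps improving — the education behavior, in
which assistance fades as competence grows.

The regressor ``phi`` is pluggable; the default is a constant term plus
radial basis functions over the movement range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .arm_plant import AgentParams, MuscleState, PlantConfig, muscle_step

Regressor = Callable[[float, float], np.ndarray]

#: velocity weighting inside the tracking-error signal (s)
KAPPA_V = 0.2


def constant_regressor() -> Regressor:
    """phi = [1]; sufficient to learn a constant disturbance."""
    return lambda p, v: np.ones(1)


def rbf_regressor(
    centers: Sequence[float] = (0.0, 0.5, 1.0, 1.5, 2.0), width: float = 0.5
) -> Regressor:
    """Constant term plus Gaussian bumps over the movement range (m)."""
    c = np.asarray(centers, float)

    def phi(p: float, v: float) -> np.ndarray:
        return np.concatenate(([1.0], np.exp(-0.5 * ((p - c) / width) ** 2)))

    return phi


@dataclass
class LearnerState:
    """Feedforward parameters and learning gains of one adaptive agent."""

    theta: np.ndarray
    regressor: Regressor
    rate: float = 1.0
    forgetting: float = 0.0

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, float)
        if self.rate < 0:
            raise ValueError("rate must be non-negative")
        if self.forgetting < 0:
            raise ValueError("forgetting must be non-negative")


@dataclass(frozen=True)
class TrialRecord:
    """Per-trial summary of a training run."""

    trial: int
    tracking_error: float     # integrated |e| (m s)
    learner_effort: float     # N^2 s
    trainer_effort: float     # N^2 s


def feedforward(state: LearnerState, position: float, velocity: float) -> float:
    """u_ff = theta' phi(position, velocity)."""
    phi = state.regressor(position, velocity)
    if phi.shape != state.theta.shape:
        raise ValueError(
            f"regressor dimension {phi.shape} does not match theta {state.theta.shape}")
    return float(state.theta @ phi)


def update(
    state: LearnerState, error: float, position: float, velocity: float,
    dt: float = 0.01,
) -> LearnerState:
    """One gradient step of the learning law (see module docstring).

    ``error`` is the raw position error ``e``; the tracking signal
    ``e + KAPPA_V * v`` is formed internally.  ``rate`` and ``forgetting``
    are continuous-time gains (per second); the step is scaled by ``dt``.
    """
    phi = state.regressor(position, velocity)
    eps = error + KAPPA_V * velocity
    theta = state.theta + dt * (
        state.rate * phi * (-eps) - state.forgetting * state.theta)
    if not np.all(np.isfinite(theta)):
        raise FloatingPointError("feedforward parameters diverged")
    return replace(state, theta=theta)


@dataclass
class AdaptiveAgent:
    """A fixed feedback gain plus an adapting feedforward."""

    learner: LearnerState
    feedback_gain: np.ndarray  # (8,) gain on the dyad state
    params: AgentParams = field(default_factory=AgentParams)

    def command(self, z: np.ndarray, p: float, v: float) -> float:
        return float(-self.feedback_gain @ z) + feedforward(self.learner, p, v)


def run_training(
    trainer: AdaptiveAgent,
    learner: AdaptiveAgent,
    n_trials: int,
    disturbance: float = 0.0,
    plant: PlantConfig | None = None,
    initial_error: float = 0.0,
    duration: float = 3.0,
) -> list[TrialRecord]:
    """Trainer-vs-learner trial loop on the shared object.

    The task is to keep the object on target while ``disturbance`` — a
    constant force (N) — pushes it away: the compensation is learnable, so
    the tracking error can actually be annihilated by the feedforward.
    Each trial restarts the object ``initial_error`` metres from the target
    (default on target) with silent muscles; parameters persist across
    trials and adapt at every step.  Raises ``FloatingPointError`` (with the
    trial index) on divergence.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    plant = plant or PlantConfig()
    dt, M = plant.dt, plant.M
    n = int(round(duration / dt))
    records: list[TrialRecord] = []
    for trial in range(n_trials):
        e, v = initial_error, 0.0
        m1, m2 = MuscleState(), MuscleState()
        z = np.zeros(8)
        err_int = 0.0
        eff_tr = 0.0
        eff_le = 0.0
        try:
            for _ in range(n):
                z[:] = (e, v, m1.F, m1.g, e, v, m2.F, m2.g)
                p = e  # target at the error origin
                u1 = trainer.command(z, p, v)
                u2 = learner.command(z, p, v)
                trainer.learner = update(trainer.learner, e, p, v)
                learner.learner = update(learner.learner, e, p, v)
                a = (m1.F + m2.F + disturbance) / M
                m1 = muscle_step(m1, u1, trainer.params, dt)
                m2 = muscle_step(m2, u2, learner.params, dt)
                e += dt * v
                v += dt * a
                err_int += abs(e) * dt
                eff_tr += m1.F ** 2 * dt
                eff_le += m2.F ** 2 * dt
                if abs(e) > 1e6:
                    raise FloatingPointError
        except FloatingPointError as exc:
            raise FloatingPointError(f"training diverged in trial {trial}") from exc
        records.append(TrialRecord(trial=trial, tracking_error=err_int,
                                   learner_effort=eff_le, trainer_effort=eff_tr))
    return records
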
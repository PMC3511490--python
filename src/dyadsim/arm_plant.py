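"""Single-agent arm dynamics: muscle activation filter and point-mass motion.

The arm of one agent is modelled as a point mass driven by a lumped muscle
force.  The muscle maps a neural control signal ``u`` to force ``F`` through a
second-order low-pass filter (Winter-type activation dynamics), written as two
cascaded first-order filters with an auxiliary state ``g``::

    tau1 * dg/dt = u - g
    tau2 * dF/dt = g - F

Both filters have unit DC gain, so a held control signal converges to an equal
steady-state force and ``u`` is interpretable as desired force.  The
kinematics follow Newton's law for the shared object mass ``M``::

    de/dt = v          (e is the position error to the agent's target)
    dv/dt = F / M

Everything is discretized with a forward-Euler step ``dt`` (exact zero-order
hold is available as an option), yielding the per-agent state ``[e, v, F, g]``
used throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

#: Package-wide per-agent state ordering.
STATE_LAYOUT = ("e", "v", "F", "g")


@dataclass(frozen=True)
class AgentParams:
    """Muscle time constants and task target of one agent.

    Parameters
    ----------
    tau1, tau2 : float
        Time constants (s) of the two cascaded first-order activation
        filters.  The cascade is commutative, so swapping them leaves the
        force trajectory unchanged.
    label : str
        Identifier used in reports and column names.
    target : float
        Target position (m); the error coordinate is ``e = p - target``.
    """

    tau1: float = 0.03
    tau2: float = 0.04
    label: str = "agent"
    target: float = 0.0

    def __post_init__(self) -> None:
        if not (self.tau1 > 0 and self.tau2 > 0):
            raise ValueError("muscle time constants must be positive")


@dataclass
class MuscleState:
    """Muscle force output ``F`` and auxiliary filter state ``g`` (N)."""

    F: float = 0.0
    g: float = 0.0


@dataclass(frozen=True)
class PlantConfig:
    """Shared object mass (kg) and discretization step (s)."""

    M: float = 1.0
    dt: float = 0.01
    discretization: str = field(default="euler")  # "euler" | "zoh"

    def __post_init__(self) -> None:
        if self.M <= 0:
            raise ValueError("mass must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.discretization not in ("euler", "zoh"):
            raise ValueError("discretization must be 'euler' or 'zoh'")


def _check_dt(dt: float, params: AgentParams) -> None:
    if dt > 0.5 * min(params.tau1, params.tau2):
        warnings.warn(
            f"dt={dt} is not small against muscle time constants "
            f"({params.tau1}, {params.tau2}); the Euler filter is poorly resolved",
            stacklevel=3,
        )


def muscle_step(state: MuscleState, u: float, params: AgentParams, dt: float) -> MuscleState:
    """Advance the activation filter one forward-Euler step.

    The cascade runs ``u -> g -> F``; both stages have unit DC gain, so a
    constant ``u`` held much longer than ``tau1 + tau2`` drives ``F -> u``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not np.isfinite(u):
        raise FloatingPointError("non-finite control signal")
    g = state.g + dt * (u - state.g) / params.tau1
    F = state.F + dt * (state.g - state.F) / params.tau2
    return MuscleState(F=F, g=g)


def single_agent_system(
    params: AgentParams, plant: PlantConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Discrete-time state matrices ``(A, B)`` for one agent, state [e, v, F, g].

    The kinematic rows implement ``e' = e + dt*v`` and ``v' = v + dt*F/M``;
    the muscle rows reproduce :func:`muscle_step`.  ``B`` feeds only the
    auxiliary muscle state ``g``.  With ``discretization="zoh"`` the exact
    matrix exponential of the continuous dynamics is used instead of the
    forward-Euler default.
    """
    dt, M = plant.dt, plant.M
    _check_dt(dt, params)
    if plant.discretization == "zoh":
        Ac = np.zeros((4, 4))
        Ac[0, 1] = 1.0
        Ac[1, 2] = 1.0 / M
        Ac[2, 2] = -1.0 / params.tau2
        Ac[2, 3] = 1.0 / params.tau2
        Ac[3, 3] = -1.0 / params.tau1
        Bc = np.zeros((4, 1))
        Bc[3, 0] = 1.0 / params.tau1
        # exact ZOH via the augmented-exponential trick
        blk = np.zeros((5, 5))
        blk[:4, :4] = Ac
        blk[:4, 4:] = Bc
        E = expm(blk * dt)
        return E[:4, :4], E[:4, 4:]
    A = np.eye(4)
    A[0, 1] = dt
    A[1, 2] = dt / M
    A[2, 2] = 1.0 - dt / params.tau2
    A[2, 3] = dt / params.tau2
    A[3, 3] = 1.0 - dt / params.tau1
    B = np.zeros((4, 1))
    B[3, 0] = dt / params.tau1
    return A, B
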
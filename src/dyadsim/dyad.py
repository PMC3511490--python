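"""Coupled two-agent state space: both agents push on one rigid object.

The dyad stacks both agents' four-dimensional states into
``[e1, v1, F1, g1, e2, v2, F2, g2]``.  Because the agents hold one rigid
object, each kinematic block is driven by the SUM of both muscle forces; the
velocity rows of the two blocks are identical, so ``v1 = v2`` and
``e1 - e2 = delta`` (the target offset) hold for all inputs once the initial
state is consistent.  The redundant 8-state layout is kept deliberately: the
per-agent diagonal cost matrices weight "own" and "partner" error/velocity
blocks verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .arm_plant import AgentParams, PlantConfig, single_agent_system

#: Stacked dyad state ordering.
DYAD_LAYOUT = ("e1", "v1", "F1", "g1", "e2", "v2", "F2", "g2")


@dataclass(frozen=True)
class DyadSystem:
    """Assembled discrete-time dyad.

    Attributes
    ----------
    A : (8, 8) ndarray
        Joint transition matrix; the coupling is the partner-force entry in
        each velocity row.
    B1, B2 : (8, 1) ndarray
        Per-agent input columns, each touching only its own muscle block.
    agents : tuple of AgentParams
    plant : PlantConfig
    delta : float
        Target offset ``target1 - target2`` (m); agent 2's error channel
        reads ``e2 = e1 + delta``.
    """

    A: np.ndarray
    B1: np.ndarray
    B2: np.ndarray
    agents: tuple[AgentParams, AgentParams]
    plant: PlantConfig
    delta: float = 0.0

    @property
    def M(self) -> float:
        return self.plant.M

    def initial_state(self, initial_error: float) -> np.ndarray:
        """Consistent initial dyad state for an object ``initial_error``
        metres from agent 1's target, at rest with silent muscles."""
        z = np.zeros(8)
        z[0] = initial_error
        z[4] = initial_error + self.delta
        return z

    def to_dict(self) -> dict:
        """JSON-serializable dump of the assembled matrices."""
        return {
            "layout": list(DYAD_LAYOUT),
            "A": self.A.tolist(),
            "B1": self.B1.ravel().tolist(),
            "B2": self.B2.ravel().tolist(),
            "delta": self.delta,
            "mass": self.plant.M,
            "dt": self.plant.dt,
        }


def build_dyad(a1: AgentParams, a2: AgentParams, plant: PlantConfig) -> DyadSystem:
    """Assemble the 8-state dyad from two single-agent systems.

    Each agent's block is its own single-agent system with the velocity row
    additionally driven by the partner's muscle force (rigid coupling).
    ``delta`` is computed from the two targets.
    """
    A = np.zeros((8, 8))
    Bs = []
    for off, params in ((0, a1), (4, a2)):
        Ai, Bi = single_agent_system(params, plant)
        A[off : off + 4, off : off + 4] = Ai
        Bfull = np.zeros((8, 1))
        Bfull[off : off + 4] = Bi
        Bs.append(Bfull)
    # rigid coupling: the partner's force enters the own velocity row with
    # the same influence the own force has
    A[1, 6] = A[1, 2]  # dF column of agent 2 -> v1
    A[5, 2] = A[5, 6]  # dF column of agent 1 -> v2
    delta = a1.target - a2.target
    return DyadSystem(A=A, B1=Bs[0], B2=Bs[1], agents=(a1, a2), plant=plant, delta=delta)


def apply_target_offset(sys: DyadSystem, offset: float) -> DyadSystem:
    """Shift agent 2's position feedback by ``offset`` metres.

    The offset is realized in agent 2's error coordinate (``e2`` reads
    ``e1 + offset``), not by augmenting the state, so the gain-synthesis
    problem is unchanged.  ``offset = 0`` returns an equivalent system.
    """
    if not np.isfinite(offset):
        raise ValueError("offset must be finite")
    a1, a2 = sys.agents
    new_a2 = replace(a2, target=a1.target - offset)
    return replace(sys, agents=(a1, new_a2), delta=offset)
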
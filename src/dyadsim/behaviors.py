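"""Cost-function taxonomy of dyadic motor behaviors.

Each agent's role in an interaction is encoded as a quadratic cost over the
stacked dyad state plus an effort term: a diagonal weight matrix Q placing
weights on the agent's own error/velocity block, on the partner's block
(negative weights model competition), optionally on the partner's muscle
force (a proxy for partner energy expenditure), together with a scalar
effort weight R on the agent's own control signal.

Six behavior classes arise from the zero / sign / symmetry pattern of the
two agents' weights:

========================  ============================================
co-activity               each agent weights only its own error/effort
competition               symmetric, negative partner-error weight
collaboration             symmetric, positive partner-error weight
assistance (master-slave) asymmetric; the slave minimizes the master's
                          error AND energy (positive partner-force weight)
education                 asymmetric; the teacher minimizes the student's
                          error but preserves its OWN energy
mutual assistance         symmetric, positive partner-error AND
                          partner-force weights
========================  ============================================

``classify`` answers the taxonomy decision tree: first the task type
(divisible tasks induce co-activity), then symmetry, partner-weight sign and
the energy-preservation pattern of the cost pair.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import yaml

_SYMMETRY_RTOL = 1e-9


class Behavior(str, enum.Enum):
    CO_ACTIVITY = "co_activity"
    COMPETITION = "competition"
    COLLABORATION = "collaboration"
    ASSISTANCE = "assistance"
    EDUCATION = "education"
    MUTUAL_ASSISTANCE = "mutual_assistance"


#: Behaviors whose two cost functions are identical under agent permutation.
SYMMETRIC_BEHAVIORS = frozenset(
    {Behavior.CO_ACTIVITY, Behavior.COMPETITION, Behavior.COLLABORATION,
     Behavior.MUTUAL_ASSISTANCE}
)


@dataclass(frozen=True)
class CostWeights:
    """Diagonal quadratic weights of one agent, see module docstring."""

    w_err_self: float = 0.0
    w_vel_self: float = 0.0
    w_err_partner: float = 0.0
    w_vel_partner: float = 0.0
    w_force_partner: float = 0.0
    r_effort: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.w_err_self, self.w_vel_self, self.w_err_partner,
                self.w_vel_partner, self.w_force_partner, self.r_effort)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("cost weights must be finite")
        if self.r_effort <= 0:
            raise ValueError("r_effort must be positive (Riccati solvability)")

    @property
    def is_indefinite(self) -> bool:
        """True if any state weight is negative (competition-type cost)."""
        return min(self.w_err_self, self.w_vel_self, self.w_err_partner,
                   self.w_vel_partner, self.w_force_partner) < 0


@dataclass(frozen=True)
class TaskSpec:
    """Task structure: divisibility, polarity and per-agent targets."""

    divisibility: str = "interactive"  # "divisible" | "interactive"
    polarity: str = "agonistic"        # "agonistic" | "antagonistic"
    targets: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.divisibility not in ("divisible", "interactive"):
            raise ValueError("divisibility must be 'divisible' or 'interactive'")
        if self.polarity not in ("agonistic", "antagonistic"):
            raise ValueError("polarity must be 'agonistic' or 'antagonistic'")
        if (self.divisibility == "divisible" and self.polarity == "antagonistic"
                and self.targets[0] == self.targets[1]):
            raise ValueError("antagonistic divisible tasks need distinct targets")


@dataclass(frozen=True)
class BehaviorLabel:
    """A behavior class plus the per-agent roles realizing it."""

    behavior: Behavior
    roles: tuple[str, str] = ("peer", "peer")

    def __post_init__(self) -> None:
        sym = self.behavior in SYMMETRIC_BEHAVIORS
        if sym and self.roles[0] != self.roles[1]:
            raise ValueError(f"{self.behavior.value} is symmetric; roles must match")
        if not sym and self.roles[0] == self.roles[1]:
            raise ValueError(f"{self.behavior.value} is asymmetric; roles must differ")


def _load_presets() -> dict:
    text = resources.files("dyadsim").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


_PRESETS = _load_presets()


def available_presets() -> dict:
    """The shipped preset table (behaviors and golden scenarios)."""
    return _PRESETS


def preset(label: BehaviorLabel) -> tuple[CostWeights, CostWeights]:
    """Golden cost-weight pair for a behavior label.

    Raises ``KeyError`` for an unknown behavior or role.
    """
    entry = _PRESETS["behaviors"][label.behavior.value]
    out = []
    for role in label.roles:
        try:
            w = entry["weights"][role]
        except KeyError:
            raise KeyError(
                f"unknown role {role!r} for behavior {label.behavior.value!r}"
            ) from None
        out.append(CostWeights(**w))
    return out[0], out[1]


def build_Q(w: CostWeights, agent: int) -> tuple[np.ndarray, np.ndarray]:
    """Diagonal 8x8 state-weight matrix and 1x1 effort weight for one agent.

    ``agent`` is 1 or 2 and selects which half of the dyad layout
    ``[e1, v1, F1, g1, e2, v2, F2, g2]`` is "own".  Negative diagonal entries
    (competition) make Q indefinite; the gain solver then falls back to a
    finite-horizon recursion.
    """
    if agent not in (1, 2):
        raise ValueError("agent must be 1 or 2")
    own = 0 if agent == 1 else 4
    partner = 4 - own
    d = np.zeros(8)
    d[own] = w.w_err_self
    d[own + 1] = w.w_vel_self
    d[partner] = w.w_err_partner
    d[partner + 1] = w.w_vel_partner
    d[partner + 2] = w.w_force_partner
    return np.diag(d), np.array([[w.r_effort]])


def _close(a: float, b: float) -> bool:
    return abs(a - b) <= _SYMMETRY_RTOL * max(1.0, abs(a), abs(b))


def _weights_symmetric(w1: CostWeights, w2: CostWeights) -> bool:
    return all(
        _close(getattr(w1, f), getattr(w2, f))
        for f in ("w_err_self", "w_vel_self", "w_err_partner",
                  "w_vel_partner", "w_force_partner", "r_effort")
    )


def _cares_about_partner(w: CostWeights) -> bool:
    return any(abs(x) > 0 for x in (w.w_err_partner, w.w_vel_partner,
                                    w.w_force_partner))


@dataclass(frozen=True)
class Classification:
    label: BehaviorLabel
    trace: tuple[str, ...]


def classify(task: TaskSpec, w1: CostWeights, w2: CostWeights) -> Classification:
    """Taxonomy decision tree: task type first, then the cost-pair pattern.

    Returns the behavior label together with the sequence of answered
    questions; ambiguous cases are flagged in the trace rather than raised.
    """
    trace: list[str] = []
    if task.divisibility == "divisible":
        trace.append("task divisible -> agents act independently: co-activity")
        return Classification(
            BehaviorLabel(Behavior.CO_ACTIVITY, ("peer", "peer")), tuple(trace))
    trace.append("task interactive -> inspect cost-function pair")

    if not (_cares_about_partner(w1) or _cares_about_partner(w2)):
        trace.append("neither agent weights the partner -> behaves as co-activity "
                     "(flagged: interactive task without interaction terms)")
        return Classification(
            BehaviorLabel(Behavior.CO_ACTIVITY, ("peer", "peer")), tuple(trace))

    if _weights_symmetric(w1, w2):
        trace.append("cost functions symmetric under agent permutation")
        if w1.w_err_partner < 0:
            trace.append("partner-error weight negative -> competition")
            return Classification(
                BehaviorLabel(Behavior.COMPETITION, ("peer", "peer")), tuple(trace))
        if w1.w_force_partner > 0:
            trace.append("partner error AND partner effort weighted -> mutual assistance")
            return Classification(
                BehaviorLabel(Behavior.MUTUAL_ASSISTANCE, ("peer", "peer")),
                tuple(trace))
        trace.append("positive partner-error weight, own effort kept -> collaboration")
        return Classification(
            BehaviorLabel(Behavior.COLLABORATION, ("peer", "peer")), tuple(trace))

    trace.append("cost functions asymmetric -> cooperation with distinct roles")
    # the helper is the agent weighting the partner's error
    helper_is_1 = abs(w1.w_err_partner) >= abs(w2.w_err_partner)
    helper = w1 if helper_is_1 else w2
    if helper.w_err_partner < 0:
        trace.append("helper weight negative -> one-sided competition (flagged "
                     "ambiguous, labelled competition)")
        return Classification(
            BehaviorLabel(Behavior.COMPETITION, ("peer", "peer")), tuple(trace))
    if helper.w_force_partner > 0:
        trace.append("helper also minimizes the partner's energy, disregarding "
                     "its own -> assistance (master-slave)")
        roles = ("slave", "master") if helper_is_1 else ("master", "slave")
        return Classification(
            BehaviorLabel(Behavior.ASSISTANCE, roles), tuple(trace))
    trace.append("helper preserves its own energy -> education (teacher-student)")
    roles = ("teacher", "student") if helper_is_1 else ("student", "teacher")
    return Classification(BehaviorLabel(Behavior.EDUCATION, roles), tuple(trace))


def flip_partner_sign(w: CostWeights) -> CostWeights:
    """Negate the partner error/velocity weights (collaboration <-> competition)."""
    return replace(w, w_err_partner=-w.w_err_partner,
                   w_vel_partner=-w.w_vel_partner)
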
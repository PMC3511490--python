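"""Behavior taxonomy: presets, weight matrices and the classifier."""

import numpy as np
import pytest

from dyadsim import (
    Behavior,
    BehaviorLabel,
    CostWeights,
    TaskSpec,
    build_Q,
    classify,
    flip_partner_sign,
    preset,
)
from dyadsim.behaviors import SYMMETRIC_BEHAVIORS

ALL_LABELS = [
    BehaviorLabel(Behavior.CO_ACTIVITY),
    BehaviorLabel(Behavior.COMPETITION),
    BehaviorLabel(Behavior.COLLABORATION),
    BehaviorLabel(Behavior.MUTUAL_ASSISTANCE),
    BehaviorLabel(Behavior.ASSISTANCE, ("slave", "master")),
    BehaviorLabel(Behavior.EDUCATION, ("teacher", "student")),
]

INTERACTIVE = TaskSpec(divisibility="interactive")
DIVISIBLE = TaskSpec(divisibility="divisible", polarity="antagonistic",
                     targets=(0.0, 0.5))


class TestPresets:
    @pytest.mark.parametrize("label", ALL_LABELS, ids=lambda l: l.behavior.value)
    def test_preset_structure_matches_template(self, label):
        """Zero/sign/symmetry pattern of each preset follows its class."""
        w1, w2 = preset(label)
        b = label.behavior
        if b in SYMMETRIC_BEHAVIORS:
            assert w1 == w2
        if b == Behavior.CO_ACTIVITY:
            assert w1.w_err_partner == 0 and w1.w_force_partner == 0
            assert w1.w_err_self > 0
        elif b == Behavior.COMPETITION:
            assert w1.w_err_partner < 0
        elif b == Behavior.COLLABORATION:
            assert w1.w_err_partner > 0 and w1.w_force_partner == 0
        elif b == Behavior.MUTUAL_ASSISTANCE:
            assert w1.w_err_partner > 0 and w1.w_force_partner > 0
        elif b == Behavior.ASSISTANCE:
            slave, master = w1, w2
            assert slave.w_err_self == 0 and slave.w_err_partner > 0
            assert slave.w_force_partner > 0
            assert master.w_err_partner == 0 and master.w_err_self > 0
            assert master.r_effort > slave.r_effort  # metabolic cost asymmetry
        elif b == Behavior.EDUCATION:
            teacher, student = w1, w2
            assert teacher.w_err_self == 0 and teacher.w_err_partner > 0
            assert teacher.w_force_partner == 0  # preserves own energy instead
            assert student.w_err_partner == 0 and student.w_err_self > 0

    def test_lazy_student_is_lazier_than_hardworking(self):
        _, hard = preset(BehaviorLabel(Behavior.EDUCATION, ("teacher", "student")))
        _, lazy = preset(BehaviorLabel(Behavior.EDUCATION, ("teacher", "lazy_student")))
        assert lazy.w_err_self < hard.w_err_self
        assert lazy.r_effort > hard.r_effort

    def test_unknown_role_raises(self):
        with pytest.raises((KeyError, ValueError)):
            preset(BehaviorLabel(Behavior.ASSISTANCE, ("slave", "emperor")))

    def test_invalid_weights(self):
        with pytest.raises(ValueError):
            CostWeights(r_effort=0.0)
        with pytest.raises(ValueError):
            CostWeights(w_err_self=float("nan"))


class TestBuildQ:
    def test_weight_placement_on_layout(self):
        w = CostWeights(w_err_self=3, w_vel_self=0.3, w_err_partner=5,
                        w_vel_partner=0.5, w_force_partner=0.7, r_effort=2)
        Q, R = build_Q(w, agent=1)
        np.testing.assert_allclose(np.diag(Q), [3, 0.3, 0, 0, 5, 0.5, 0.7, 0])
        assert R[0, 0] == 2
        Q2, _ = build_Q(w, agent=2)
        np.testing.assert_allclose(np.diag(Q2), [5, 0.5, 0.7, 0, 3, 0.3, 0, 0])

    def test_collaboration_Q_invariant_under_block_permutation(self):
        w1, w2 = preset(BehaviorLabel(Behavior.COLLABORATION))
        Q1, _ = build_Q(w1, 1)
        Q2, _ = build_Q(w2, 2)
        perm = np.r_[4:8, 0:4]
        np.testing.assert_allclose(Q1[np.ix_(perm, perm)], Q2)

    def test_competition_Q_indefinite(self):
        w1, _ = preset(BehaviorLabel(Behavior.COMPETITION))
        Q, _ = build_Q(w1, 1)
        assert np.min(np.diag(Q)) < 0
        assert w1.is_indefinite

    def test_psd_when_all_weights_nonnegative(self):
        w1, _ = preset(BehaviorLabel(Behavior.COLLABORATION))
        Q, _ = build_Q(w1, 1)
        assert np.min(np.linalg.eigvalsh(Q)) >= 0


class TestClassifier:
    @pytest.mark.parametrize("label", ALL_LABELS, ids=lambda l: l.behavior.value)
    def test_round_trip(self, label):
        """classify(preset(X)) returns X for every behavior class."""
        w1, w2 = preset(label)
        task = DIVISIBLE if label.behavior == Behavior.CO_ACTIVITY else INTERACTIVE
        out = classify(task, w1, w2)
        assert out.label.behavior == label.behavior
        assert len(out.trace) >= 1

    def test_divisible_task_always_co_activity(self):
        w1, w2 = preset(BehaviorLabel(Behavior.COLLABORATION))
        out = classify(DIVISIBLE, w1, w2)
        assert out.label.behavior == Behavior.CO_ACTIVITY

    def test_sign_flip_maps_collaboration_to_competition_and_back(self):
        w1, w2 = preset(BehaviorLabel(Behavior.COLLABORATION))
        f1, f2 = flip_partner_sign(w1), flip_partner_sign(w2)
        assert classify(INTERACTIVE, f1, f2).label.behavior == Behavior.COMPETITION
        assert classify(INTERACTIVE, flip_partner_sign(f1),
                        flip_partner_sign(f2)).label.behavior == Behavior.COLLABORATION

    def test_energy_preservation_separates_assistance_from_education(self):
        # the same helper/helped pair, with only the partner-energy term
        # switched, moves between the two cooperation schemes
        helper = CostWeights(w_err_partner=6.0, w_vel_partner=0.06,
                             w_force_partner=0.5, r_effort=1.0)
        helped = CostWeights(w_err_self=10.0, w_vel_self=0.1, r_effort=5.0)
        assert classify(INTERACTIVE, helper, helped).label.behavior == Behavior.ASSISTANCE
        teacher = CostWeights(w_err_partner=6.0, w_vel_partner=0.06,
                              w_force_partner=0.0, r_effort=1.0)
        out = classify(INTERACTIVE, teacher, helped)
        assert out.label.behavior == Behavior.EDUCATION
        assert out.label.roles == ("teacher", "student")

    def test_roles_follow_agent_order(self):
        w1, w2 = preset(BehaviorLabel(Behavior.ASSISTANCE, ("slave", "master")))
        out = classify(INTERACTIVE, w2, w1)  # master listed first
        assert out.label.roles == ("master", "slave")

    def test_no_partner_terms_flagged_as_co_activity(self):
        w = CostWeights(w_err_self=1.0, r_effort=1.0)
        out = classify(INTERACTIVE, w, w)
        assert out.label.behavior == Behavior.CO_ACTIVITY
        assert any("flagged" in s for s in out.trace)


class TestTaskSpec:
    def test_antagonistic_divisible_needs_distinct_targets(self):
        with pytest.raises(ValueError):
            TaskSpec(divisibility="divisible", polarity="antagonistic",
                     targets=(0.0, 0.0))

    def test_symmetric_label_requires_equal_roles(self):
        with pytest.raises(ValueError):
            BehaviorLabel(Behavior.COLLABORATION, ("peer", "master"))
        with pytest.raises(ValueError):
            BehaviorLabel(Behavior.ASSISTANCE, ("slave", "slave"))
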
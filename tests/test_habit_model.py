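import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alerthabit.habit_model import (
    HabitParams,
    attach_habit,
    closed_form_constant_action,
    habit_trajectory,
    update_habit,
)

from conftest import make_events


def brute_force_trajectory(actions, alpha, h0=0.0):
    """Independent oracle: literal iteration of the update rule."""
    pre, post = [], []
    h = h0
    for a in actions:
        pre.append(h)
        h = h + alpha * (a - h)
        post.append(h)
    return np.array(pre), np.array(post)


class TestUpdate:
    @pytest.mark.parametrize("h,action,alpha,expected", [
        (0.0, 1, 0.1, 0.1),
        (0.5, 0, 0.05, 0.475),
        (1.0, 1, 0.3, 1.0),   # fixed point under continued dismissal
    ])
    def test_single_update(self, h, action, alpha, expected):
        assert update_habit(h, action, HabitParams(alpha)) == pytest.approx(expected)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            update_habit(1.5, 1, HabitParams(0.1))
        with pytest.raises(ValueError):
            update_habit(0.5, 2, HabitParams(0.1))
        with pytest.raises(ValueError):
            HabitParams(alpha=1.0)
        with pytest.raises(ValueError):
            HabitParams(alpha=0.1, h0=-0.2)


class TestTrajectory:
    def test_constant_dismissal_matches_closed_form(self):
        params = HabitParams(0.05)
        traj = habit_trajectory(np.ones(60), params)
        assert traj.post_action_h[59] == pytest.approx(1 - 0.95**60, abs=1e-12)
        assert traj.post_action_h[59] == pytest.approx(0.95393, abs=5e-6)

    def test_all_zero_actions_stay_at_zero(self):
        traj = habit_trajectory(np.zeros(50), HabitParams(0.1))
        assert (traj.pre_action_h == 0).all() and (traj.post_action_h == 0).all()

    def test_alternating_actions_brute_force(self):
        actions = [1, 0, 1, 0, 1, 0]
        traj = habit_trajectory(actions, HabitParams(0.5))
        np.testing.assert_allclose(
            traj.post_action_h[:4], [0.5, 0.25, 0.625, 0.3125], atol=1e-15)
        pre, post = brute_force_trajectory(actions, 0.5)
        np.testing.assert_allclose(traj.post_action_h, post, atol=1e-15)

    def test_matches_brute_force_on_random_streams(self):
        rng = np.random.default_rng(42)
        for alpha in (0.01, 0.05, 0.1, 0.73):
            actions = rng.integers(0, 2, 200)
            traj = habit_trajectory(actions, HabitParams(alpha, h0=0.3))
            pre, post = brute_force_trajectory(actions, alpha, h0=0.3)
            np.testing.assert_allclose(traj.pre_action_h, pre, atol=1e-12)
            np.testing.assert_allclose(traj.post_action_h, post, atol=1e-12)

    def test_rejects_non_binary_and_empty(self):
        with pytest.raises(ValueError):
            habit_trajectory([0, 2, 1], HabitParams(0.1))
        with pytest.raises(ValueError):
            habit_trajectory([], HabitParams(0.1))


class TestClosedForm:
    @pytest.mark.parametrize("t,alpha,expected", [
        (0, 0.05, 0.0),
        (1, 0.05, 0.05),
        (100, 0.01, 1 - 0.99**100),
    ])
    def test_values(self, t, alpha, expected):
        assert closed_form_constant_action(t, HabitParams(alpha)) == pytest.approx(
            expected, abs=1e-12)

    def test_negative_exposure_rejected(self):
        with pytest.raises(ValueError):
            closed_form_constant_action(-1, HabitParams(0.05))

    def test_agrees_with_iteration_up_to_1000(self):
        for alpha in (0.01, 0.05, 0.1):
            params = HabitParams(alpha)
            traj = habit_trajectory(np.ones(1000), params)
            analytic = np.array([closed_form_constant_action(t, params)
                                 for t in range(1, 1001)])
            np.testing.assert_allclose(traj.post_action_h, analytic, atol=1e-12)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    alpha=st.floats(0.001, 0.999),
    h0=st.floats(0.0, 1.0),
    actions=st.lists(st.integers(0, 1), min_size=1, max_size=100),
)
def test_boundedness_property(alpha, h0, actions):
    """Every habit value stays in [0,1] for any binary stream."""
    traj = habit_trajectory(actions, HabitParams(alpha, h0))
    assert (traj.pre_action_h >= 0).all() and (traj.pre_action_h <= 1).all()
    assert (traj.post_action_h >= 0).all() and (traj.post_action_h <= 1).all()


def test_geometric_contraction_under_constant_action():
    """|H_{t+1} - a| shrinks by exactly (1-alpha) each step."""
    for a in (0, 1):
        traj = habit_trajectory(np.full(30, a), HabitParams(0.07, h0=0.4))
        gaps = np.abs(np.concatenate([[0.4], traj.post_action_h]) - a)
        ratios = gaps[1:][gaps[:-1] > 0] / gaps[:-1][gaps[:-1] > 0]
        np.testing.assert_allclose(ratios, 0.93, atol=1e-12)


class TestAttachHabit:
    def test_hand_iterated_example(self):
        log = make_events([
            ("a1", "P1", "PT1", "2017-03-06 09:00:00", "dismiss", 1.0),
            ("a2", "P1", "PT1", "2017-03-06 10:00:00", "dismiss", 1.0),
            ("a3", "P1", "PT2", "2017-03-06 11:00:00", "acknowledge", 1.0),
        ])
        out = attach_habit(log, alphas=[0.1])
        np.testing.assert_allclose(out.events["H_0.1"], [0.0, 0.1, 0.19], atol=1e-15)

    def test_first_event_of_every_physician_is_zero(self, small_sim):
        _, log, _ = small_sim
        out = attach_habit(log, alphas=[0.05]).events
        firsts = out.groupby("physician_id").head(1)
        assert (firsts["H_0.05"] == 0.0).all()

    def test_single_event_attaches_h0_regardless_of_action(self):
        for action in ("dismiss", "acknowledge"):
            log = make_events([("a1", "P1", "PT1", "2017-03-06 09:00:00", action, 1.0)])
            out = attach_habit(log, alphas=[0.05], h0=0.25)
            assert out.events.loc[0, "H_0.05"] == 0.25

    def test_stream_is_per_physician_across_patients(self):
        """The habit carries over between patients of the same physician."""
        log = make_events([
            ("a1", "P1", "PT1", "2017-03-06 09:00:00", "dismiss", 1.0),
            ("a2", "P1", "PT2", "2017-03-06 10:00:00", "dismiss", 1.0),
        ])
        out = attach_habit(log, alphas=[0.1])
        assert out.events.loc[1, "H_0.1"] == pytest.approx(0.1)

    def test_remove_order_codes_zero_like_acknowledge(self):
        log = make_events([
            ("a1", "P1", "PT1", "2017-03-06 09:00:00", "remove_order", 1.0),
            ("a2", "P1", "PT1", "2017-03-06 10:00:00", "dismiss", 1.0),
        ])
        out = attach_habit(log, alphas=[0.1])
        assert out.events["H_0.1"].tolist() == [0.0, 0.0]
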
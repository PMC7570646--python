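"""Stability-limited modulation, consistency rule, habits prediction, steps."""

import numpy as np
import pytest

import adaptfuse as af
from adaptfuse.core import ValidationError

ACT = af.ACTIVITIES


def _pl(sensor, scores):
    return af.ProbabilityList.from_scores(sensor, scores)


def _mix(W1, W2, t):
    return {k: (1 - t) * W1[k] + t * W2[k] for k in W1}


def grid_stability_oracle(outputs, W_start, W_target, n=1000):
    """Independent check: walk a dense grid along the segment and return the
    last fraction before the fused decision first changes."""
    base = af.fuse(outputs, W_start).activity
    last_ok = 0.0
    for t in np.linspace(0.0, 1.0, n + 1):
        if af.fuse(outputs, _mix(W_start, W_target, float(t))).activity == base:
            last_ok = float(t)
        else:
            break
    return last_ok


def random_stability_instance(rng, n_sensors):
    sensors = list("BCDE")[:n_sensors]
    acts = list(rng.choice(ACT, size=4, replace=False))
    outputs = [
        _pl(s, {a: float(rng.random()) + 0.01 for a in acts}) for s in sensors
    ]
    w1 = af.normalize({s: float(rng.random()) + 0.01 for s in sensors})
    w2 = af.normalize({s: float(rng.random()) + 0.01 for s in sensors})
    return outputs, w1, w2


class TestStabilityLimit:
    def test_same_decision_at_both_ends_reaches_target(self):
        outputs = [_pl("B", {"1a": 0.9, "2a": 0.1}), _pl("C", {"1a": 0.8, "2a": 0.2})]
        res = af.stability_limit(outputs, {"B": 1.0, "C": 0.0}, {"B": 0.0, "C": 1.0})
        assert res.reached_target
        assert res.W_limit == {"B": 0.0, "C": 1.0}

    def test_flip_at_midpoint_is_located(self):
        s1 = _pl("B", {"1a": 0.6, "2a": 0.4})
        s2 = _pl("C", {"2a": 0.6, "1a": 0.4})
        res = af.stability_limit(
            [s1, s2], {"B": 1.0, "C": 0.0}, {"B": 0.0, "C": 1.0}, tol=1e-3
        )
        assert not res.reached_target
        assert res.t == pytest.approx(0.5, abs=2e-3)

    def test_immediate_flip_stays_at_start(self):
        # sensor C flatly contradicts B and dominates for any t > 0 mix toward it
        s1 = _pl("B", {"1a": 0.51, "2a": 0.49})
        s2 = _pl("C", {"2a": 1.0})
        start = {"B": 1.0, "C": 0.0}
        res = af.stability_limit([s1, s2], start, {"B": 0.0, "C": 1.0}, tol=1e-3)
        assert not res.reached_target
        assert res.t <= 0.05
        assert af.fuse([s1, s2], res.W_limit).activity == "1a"

    def test_non_normalized_rejected(self):
        out = [_pl("B", {"1a": 1.0})]
        with pytest.raises(ValidationError):
            af.stability_limit(out, {"B": 0.5}, {"B": 1.0})

    def test_mismatched_sensors_rejected(self):
        out = [_pl("B", {"1a": 1.0})]
        with pytest.raises(ValidationError):
            af.stability_limit(out, {"B": 1.0}, {"C": 1.0})

    @pytest.mark.parametrize("n_sensors", [2, 4])
    def test_agrees_with_grid_search_oracle(self, n_sensors):
        rng = np.random.default_rng(42 + n_sensors)
        for _ in range(50):
            outputs, w1, w2 = random_stability_instance(rng, n_sensors)
            res = af.stability_limit(outputs, w1, w2, tol=1e-3)
            t_grid = grid_stability_oracle(outputs, w1, w2, n=1000)
            assert abs(res.t - t_grid) <= 2.5e-3
            base = af.fuse(outputs, w1).activity
            assert af.fuse(outputs, res.W_limit).activity == base


class TestConsistencySelect:
    def test_previous_kept_within_top_group(self, table3):
        h = af.build_hierarchy(table3, "5b")
        assert set(h.top_group) == {"BD", "BDE"}
        # straightening up after bending detected with BE: 5b's top group
        # excludes BE, but with BE unavailable-free candidates containing it
        h_be = af.build_hierarchy(table3, "5b", pool={"BE", "DE"})
        assert af.consistency_select(h_be, "BE") == "BE"

    def test_overlap_breaks_tie(self):
        import pandas as pd

        df = pd.DataFrame({"1a": [99.0, 99.0, 99.0]}, index=["BC", "DE", "CD"])
        h = af.build_hierarchy(af.ReliabilityTable(values=df, mode="activity"),
                               "1a", pool=["BC", "DE", "CD"])
        assert len(h.groups) == 1
        # previous in the group: kept
        assert af.consistency_select(h, "CD") == "CD"
        # BDE shares two sensors with DE, one with the others
        assert af.consistency_select(h, "BDE") == "DE"
        # BD shares one sensor with each member: canonical order decides
        assert af.consistency_select(h, "BD") == "BC"

    def test_single_set_hierarchy(self, table3):
        h = af.build_hierarchy(table3, "5a", pool={"BD"})
        assert af.consistency_select(h, "CE") == "BD"


class TestHabits:
    def test_counts_adjacent_pairs(self):
        db = af.habits_update(af.HabitsDB(), ["4a", "4b", "3a"])
        assert db.transition_counts == {("4a", "4b"): 1, ("4b", "3a"): 1}
        assert db.marginal_counts == {"4a": 1, "4b": 1}

    def test_repeated_pose_cycle_counts(self):
        poses = ["4a", "4b", "3a", "3b", "5a", "5b", "1a", "1b"]
        db = af.habits_update(af.HabitsDB(), poses * 10)
        assert db.transition_counts[("4a", "4b")] == 10
        assert db.transition_counts[("1b", "4a")] == 9  # cycle wrap

    def test_update_additivity(self):
        seq = ["1a", "1b", "2a", "2b", "1a"]
        db1 = af.habits_update(af.HabitsDB(), seq)
        db2 = af.habits_update(
            af.habits_update(af.HabitsDB(), seq[:3]), seq[2:]
        )
        assert db1.transition_counts == db2.transition_counts

    def test_predicts_learned_successor(self):
        poses = ["4a", "4b", "3a", "3b", "5a", "5b", "1a", "1b"]
        db = af.habits_update(af.HabitsDB(), poses * 10)
        assert af.habits_predict(db, "4a") == "4b"
        assert af.habits_predict(db, "3a") == "3b"

    def test_empty_db_falls_back_to_current(self):
        assert af.habits_predict(af.HabitsDB(), "2b") == "2b"

    def test_tie_broken_canonically(self):
        db = af.habits_update(af.HabitsDB(), ["1a", "2a"])
        db = af.habits_update(db, ["1a", "3a"])
        assert af.habits_predict(db, "1a") == "2a"

    def test_json_round_trip(self):
        db = af.habits_update(af.HabitsDB(), ["4a", "4b", "3a", "4a", "4b"])
        again = af.HabitsDB.from_dict(db.to_dict())
        assert again.transition_counts == {
            k: v for k, v in db.transition_counts.items() if v > 0
        }

    def test_unknown_code_rejected(self):
        with pytest.raises(ValidationError):
            af.habits_update(af.HabitsDB(), ["1a", "zz"])


def _agreeing_outputs(activity, sensors="BCDE", mass=0.8):
    rest = (1 - mass) / (len(ACT) - 1)
    return [
        af.ProbabilityList(
            sensor=s,
            entries=tuple([(activity, mass)] + [(a, rest) for a in ACT if a != activity]),
        )
        for s in sensors
    ]


class TestConservativeStep:
    def test_fixed_point_when_weights_already_optimal(self, table3):
        target = af.target_weights(af.CostProfile.uniform(), table3, "5a")
        state = af.AdaptationState(
            current_weights=dict(target), current_set="BDE"
        )
        outputs = _agreeing_outputs("5a")
        new = af.conservative_step(state, outputs, table3)
        assert new.current_decision.activity == "5a"
        assert new.current_set == "BDE"
        for s in "BCDE":
            assert new.current_weights[s] == pytest.approx(target[s])

    def test_weights_move_toward_detected_optimum(self, table3):
        state = af.AdaptationState.initial()
        outputs = _agreeing_outputs("5a")
        new = af.conservative_step(state, outputs, table3)
        target = af.target_weights(af.CostProfile.uniform(), table3, "5a")
        assert new.current_decision.activity == "5a"
        # unanimous outputs: decision invariant to weights, target reachable
        assert new.last_stability.reached_target
        for s in "BCDE":
            assert new.current_weights[s] == pytest.approx(target[s])

    def test_unavailable_sensor_zero_weight_and_set_reselected(self, table3):
        state = af.AdaptationState.initial().with_availability({"E": False})
        assert state.current_weights["E"] == 0.0
        assert sum(state.current_weights.values()) == pytest.approx(1.0)
        outputs = _agreeing_outputs("6a", sensors="BCD")
        new = af.conservative_step(state, outputs, table3)
        assert new.current_weights["E"] == 0.0
        assert "E" not in new.current_set
        # best E-free set for walking right (6a) is BCD
        assert new.current_set == "BCD"

    def test_no_available_sensors_is_fatal(self, table3):
        with pytest.raises(af.ConfigurationError):
            af.AdaptationState.initial().with_availability(
                {s: False for s in "BCDE"}
            )


class TestPredictiveStep:
    def test_targets_predicted_next_activity(self, table3):
        poses = ["2b", "3a", "3b", "5a", "5b"]
        habits = af.habits_update(af.HabitsDB(), poses * 5)
        state = af.AdaptationState.initial(mode="predictive")
        outputs = _agreeing_outputs("3a")
        new = af.predictive_step(state, outputs, table3, habits=habits)
        assert new.current_decision.activity == "3a"
        assert new.predicted_next == "3b"
        target_3b = af.target_weights(af.CostProfile.uniform(), table3, "3b")
        assert new.last_stability.reached_target
        for s in "BCDE":
            assert new.current_weights[s] == pytest.approx(target_3b[s])

    def test_empty_habits_reduces_to_conservative(self, table3):
        state = af.AdaptationState.initial(mode="predictive")
        outputs = _agreeing_outputs("5a")
        pred = af.predictive_step(state, outputs, table3, habits=af.HabitsDB())
        cons = af.conservative_step(
            af.AdaptationState.initial(), outputs, table3
        )
        assert pred.current_decision.activity == cons.current_decision.activity
        for s in "BCDE":
            assert pred.current_weights[s] == pytest.approx(cons.current_weights[s])


class TestStabilityInvariantProperty:
    def test_returned_weights_preserve_decision(self):
        """The fused activity at the stability limit always equals the
        pre-modulation activity (randomized instances)."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            outputs, w1, w2 = random_stability_instance(rng, 4)
            base = af.fuse(outputs, w1).activity
            res = af.stability_limit(outputs, w1, w2, tol=1e-3)
            assert af.fuse(outputs, res.W_limit).activity == base
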
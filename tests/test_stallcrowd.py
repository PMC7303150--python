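"""Crowd engine: sensitivity updates, weighting, stopping, serving, triage."""

import numpy as np
import pytest

from stallflow import stallcrowd as sc
from stallflow.synthgen import generate_players


def answers(*pairs):
    return [
        sc.AnswerRecord(f"p{i}", "t0", ans, w, i) for i, (w, ans) in enumerate(pairs)
    ]


class TestSensitivity:
    def test_new_player_prior_is_half(self):
        assert sc.PlayerProfile("p").sensitivity == 0.5

    def test_smoothed_update_formula(self):
        """9 of 10 correct on stalled calibration items -> 10/12."""
        prof = sc.PlayerProfile("p")
        for i in range(10):
            ans = "flowing" if i == 0 else "stalled"
            sc.update_sensitivity(prof, ans, "stalled")
        assert prof.sensitivity == pytest.approx(10 / 12)

    def test_always_correct_tends_to_one_monotonically(self):
        prof = sc.PlayerProfile("p")
        prev = prof.sensitivity
        for _ in range(50):
            sc.update_sensitivity(prof, "stalled", "stalled")
            assert prof.sensitivity >= prev
            prev = prof.sensitivity
        assert prof.sensitivity > 0.96

    def test_flowing_items_update_specificity_not_sensitivity(self):
        prof = sc.PlayerProfile("p")
        sc.update_sensitivity(prof, "flowing", "flowing")
        assert prof.sensitivity == 0.5
        assert prof.specificity == pytest.approx(2 / 3)

    def test_missing_truth_rejected(self):
        with pytest.raises(ValueError, match="truth"):
            sc.update_sensitivity(sc.PlayerProfile("p"), "stalled", None)


class TestConfidence:
    def test_unanimous_stalled_is_one(self):
        assert sc.crowd_confidence(answers((0.7, "stalled"), (0.9, "stalled"))).value == 1.0

    def test_weighted_average(self):
        """weights (0.8, 0.5), answers (stalled, flowing) -> 0.8/1.3."""
        c = sc.crowd_confidence(answers((0.8, "stalled"), (0.5, "flowing")))
        assert c.value == pytest.approx(0.8 / 1.3)

    def test_single_flowing_answer_is_zero(self):
        assert sc.crowd_confidence(answers((0.6, "flowing"))).value == 0.0

    def test_zero_weights_flagged_insufficient(self):
        c = sc.crowd_confidence(answers((0.0, "stalled")))
        assert c.status == "insufficient signal"
        assert np.isnan(c.value)

    def test_no_answers_rejected(self):
        with pytest.raises(ValueError):
            sc.crowd_confidence([])


class TestStopping:
    def test_sum_reaches_threshold(self):
        a = answers(*[(w, "stalled") for w in (0.9, 0.9, 0.8, 0.7, 0.8)])
        assert sc.stopping_rule(a, 4.0) == "closed"  # sum = 4.1

    def test_below_threshold_stays_open(self):
        assert sc.stopping_rule(answers((0.9, "stalled")), 4.0) == "open"

    def test_zero_threshold_warns_and_closes(self):
        with pytest.warns(RuntimeWarning):
            assert sc.stopping_rule(answers((0.5, "flowing")), 0.0) == "closed"


class TestServing:
    def test_ratio_schedule_nondecreasing(self):
        grid = np.linspace(0, 1, 101)
        ratios = [sc.serving_ratio(s) for s in grid]
        assert ratios == sorted(ratios)
        assert sc.serving_ratio(0.5) == 1.0
        assert sc.serving_ratio(0.99) == 9.0

    def test_mixing_equation(self):
        f, feasible = sc.calibration_stalled_fraction(0.25, 1.0, 0.01)
        assert f == pytest.approx(0.49)
        assert feasible

    def test_infeasible_mix_clamped(self):
        """9:1 serving at 1% research rate cannot reach a 25% shown rate."""
        f, feasible = sc.calibration_stalled_fraction(0.25, 9.0, 0.01)
        assert not feasible
        assert f == 1.0  # required 2.41, clamped

    def test_no_calibration_needed_when_q_equals_base_rate(self):
        f, feasible = sc.calibration_stalled_fraction(0.01, 9.0, 0.01)
        assert feasible
        assert f == pytest.approx(0.01)

    def test_serve_next_respects_queues(self):
        rng = np.random.default_rng(0)
        queues = sc.ServingQueues(
            research=["r1", "r2"],
            calibration_stalled=["cs"],
            calibration_flowing=["cf"],
            research_base_rate=0.01,
        )
        served = {
            sc.serve_next(sc.PlayerProfile("p"), queues, 0.25, rng) for _ in range(100)
        }
        assert served == {"r1", "r2", "cs", "cf"}

    def test_base_rate_control_within_tolerance(self, beta_pool):
        """Realized shown-stall fraction tracks the target when feasible."""
        truths = np.random.default_rng(3).random(1500) < 0.01
        res = sc.simulate_crowd(
            truths,
            beta_pool,
            3.0,
            target_shown_stall_rate=0.10,
            min_answers=8,
            seed=4,
        )
        assert res.n_served >= 10000
        assert res.shown_stall_fraction == pytest.approx(0.10, abs=0.03)


class TestTriageAndCalibration:
    def _perfect_run(self, n=300, rate=0.05, seed=5):
        pool = generate_players(
            20, (8, 2), seed=1, fixed_sensitivity=1.0, fixed_specificity=1.0
        )
        truths = np.random.default_rng(seed).random(n) < rate
        res = sc.simulate_crowd(truths, pool, 3.0, min_answers=3, seed=seed)
        return res

    def test_perfect_players_give_perfect_precision(self):
        res = self._perfect_run()
        calls, report = sc.expert_triage(res.calls, sc.ground_truth_oracle(res.calls))
        for b in report["bins"]:
            if b["n_reviewed"]:
                assert b["precision"] == 1.0
        confirmed = calls.confirmed_stalls()
        assert len(confirmed) == int((res.calls.table["truth"] == "stalled").sum())

    def test_no_high_confidence_items_means_no_review(self):
        pool = generate_players(
            5, (8, 2), seed=1, fixed_sensitivity=1.0, fixed_specificity=1.0
        )
        truths = np.zeros(50, bool)
        res = sc.simulate_crowd(truths, pool, 2.0, min_answers=2, seed=6)
        calls, report = sc.expert_triage(res.calls, sc.ground_truth_oracle(res.calls))
        assert len(calls.confirmed_stalls()) == 0
        assert (calls.table["expert_verdict"] == "unreviewed").all()

    def test_weight_freezing(self):
        """Confidence recomputed after later sensitivity updates is unchanged."""
        recs = answers((0.6, "stalled"), (0.7, "flowing"))
        before = sc.crowd_confidence(recs).value
        # the players get much better afterwards; records keep old weights
        prof = sc.PlayerProfile("p0")
        for _ in range(30):
            sc.update_sensitivity(prof, "stalled", "stalled")
        after = sc.crowd_confidence(recs).value
        assert after == before

    def test_calibrate_threshold_deterministic(self, beta_pool):
        truths = np.zeros(300, bool)
        truths[:15] = True
        a = sc.calibrate_threshold(truths, beta_pool, seed=9)
        b = sc.calibrate_threshold(truths, beta_pool, seed=9)
        assert a.threshold == b.threshold
        assert a.satisfied

    def test_coin_flip_crowd_fails_calibration(self):
        """ŝ=0.5 coin-flippers never separate stalls; diagnostic path."""
        pool = generate_players(
            30, (8, 2), seed=2, fixed_sensitivity=0.5, fixed_specificity=0.5
        )
        truths = np.zeros(200, bool)
        truths[:10] = True
        res = sc.calibrate_threshold(truths, pool, grid=(2.0, 4.0), seed=3)
        assert not res.satisfied
        assert res.threshold == 4.0  # largest candidate, with diagnostics
        assert res.per_threshold[4.0]["ok"] is False

    def test_requires_known_stalls(self, beta_pool):
        with pytest.raises(ValueError, match="stall"):
            sc.calibrate_threshold(np.zeros(10, bool), beta_pool)

    def test_confidence_calibration_monotone(self, beta_pool):
        """P(truly stalled | confidence bin) is nondecreasing across bins."""
        truths = np.random.default_rng(11).random(3000) < 0.25
        res = sc.simulate_crowd(truths, beta_pool, 4.0, min_answers=6, seed=12)
        df = res.calls.table
        edges = [0.0, 0.2, 0.4, 0.6, 0.8, 1.0001]
        rates = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            sel = df[(df["confidence"] >= lo) & (df["confidence"] < hi)]
            if len(sel) >= 20:
                rates.append((sel["truth"] == "stalled").mean())
        assert len(rates) >= 3
        assert all(b >= a - 1e-9 for a, b in zip(rates, rates[1:]))

    def test_reported_fraction_is_confirmed_over_total(self):
        """Per-stack stall fraction = confirmed stalls / segments, exactly."""
        from stallflow.stallmetrics import stall_fraction

        res = self._perfect_run(n=400, rate=0.04, seed=13)
        calls, _ = sc.expert_triage(res.calls, sc.ground_truth_oracle(res.calls))
        per_stack, _ = stall_fraction(calls, {0: 400})
        n_conf = len(calls.confirmed_stalls())
        assert per_stack["stall_fraction"].iloc[0] == n_conf / 400
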
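"""Behavioral scores and the normality-gated group-comparison logic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stallflow import cohortstats as cs
from stallflow.synthgen import BehaviorParams, generate_behavior


def brute_force_alternation(entries):
    """Independent enumeration of distinct-arm windows of length 3."""
    wins = [entries[i : i + 3] for i in range(len(entries) - 2)]
    triads = sum(1 for w in wins if w[0] != w[1] and w[1] != w[2] and w[0] != w[2])
    return 100.0 * triads / (len(entries) - 2)


class TestAlternation:
    @pytest.mark.parametrize(
        "entries,expected",
        [
            (list("ABCABC"), 100.0),
            (list("ABABA"), 0.0),
            (list("ABCCAB"), 50.0),  # ABC ok, BCC no, CCA no, CAB ok -> 2/4
        ],
    )
    def test_worked_examples(self, entries, expected):
        assert cs.alternation_score(entries) == pytest.approx(expected)

    def test_too_few_entries_flagged(self):
        with pytest.raises(cs.UndefinedScoreError):
            cs.alternation_score(["A", "B"])

    @settings(deadline=None, max_examples=200)
    @given(st.lists(st.sampled_from("ABC"), min_size=3, max_size=40))
    def test_matches_brute_force(self, entries):
        assert cs.alternation_score(entries) == pytest.approx(
            brute_force_alternation(entries)
        )


class TestORPreference:
    def test_chance_level(self):
        assert cs.or_preference({"moved": 30.0, "unmoved": 30.0}) == 50.0

    def test_sixty_percent(self):
        assert cs.or_preference({"moved": 36.0, "unmoved": 24.0}) == pytest.approx(60.0)

    def test_exclusive_exploration(self):
        assert cs.or_preference({"moved": 5.0, "unmoved": 0.0}) == 100.0

    def test_zero_total_flagged(self):
        with pytest.raises(cs.UndefinedScoreError):
            cs.or_preference({"moved": 0.0, "unmoved": 0.0})


class TestSociability:
    def _log(self, chamber):
        class L:
            sociability = {
                "session1": {
                    "duration_s": 600,
                    "chamber_s": chamber,
                    "contact_s": {"stranger": 60.0, "empty": 0.0},
                },
                "session2": {
                    "duration_s": 600,
                    "chamber_s": {"novel": 200.0, "center": 200.0, "familiar": 200.0},
                    "contact_s": {"novel": 30.0, "familiar": 30.0},
                },
            }

        return L()

    def test_all_time_with_stranger(self):
        log = self._log({"stranger": 600.0, "center": 0.0, "empty": 0.0})
        assert cs.sociability_scores(log)["session1"]["chamber_fraction"] == 1.0

    def test_equal_time_is_one_third(self):
        log = self._log({"stranger": 200.0, "center": 200.0, "empty": 200.0})
        s = cs.sociability_scores(log)
        assert s["session1"]["chamber_fraction"] == pytest.approx(1 / 3)
        assert s["session2"]["chamber_fraction"] == pytest.approx(1 / 3)

    def test_missing_chamber_record_rejected(self):
        class L:
            sociability = {"session1": {}}

        with pytest.raises(cs.UndefinedScoreError):
            cs.sociability_scores(L())

    def test_generator_roundtrip_at_configured_preference(self):
        logs = generate_behavior(
            {"g": BehaviorParams(sociability_preference=0.6)}, 1000, seed=31
        )
        fracs = [
            cs.sociability_scores(log)["session1"]["contact_fraction"] for log in logs
        ]
        assert np.mean(fracs) == pytest.approx(0.6, abs=0.02)


class TestBeam:
    def test_first_trial_excluded(self):
        """Trials (60, ·), (10, 1), (12, 3) -> time 11, slips 2."""
        t, s = cs.beam_metrics([(60.0, 0), (10.0, 1), (12.0, 3)])
        assert t == 11.0
        assert s == 2.0

    def test_identical_trials(self):
        t, s = cs.beam_metrics([(9.0, 1), (9.0, 1), (9.0, 1)])
        assert (t, s) == (9.0, 1.0)

    def test_cap_retained_in_mean(self):
        t, _ = cs.beam_metrics([(30.0, 0), (60.0, 2), (10.0, 0)])
        assert t == 35.0  # the capped 60 s trial counts as 60

    def test_fewer_trials_warns(self):
        with pytest.warns(RuntimeWarning):
            t, s = cs.beam_metrics([(8.0, 1), (12.0, 3)])
        assert t == 10.0 and s == 2.0


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(10, 2, 12)
        res = cs.compare_groups({"a": vals, "b": vals.copy()})
        assert len(res.significant_pairs()) == 0

    def test_large_separation_uses_anova_and_detects(self):
        rng = np.random.default_rng(0)
        res = cs.compare_groups(
            {
                "a": rng.normal(0, 1, 10),
                "b": rng.normal(3, 1, 10),
                "c": rng.normal(0, 1, 10),
            }
        )
        assert res.test_used == "anova_holm_sidak"
        sig = res.significant_pairs()
        assert {"a", "b"} in [set(p) for p in zip(sig["group_a"], sig["group_b"])]

    def test_heavy_tailed_group_takes_nonparametric_branch(self):
        """A Cauchy group (n = 50) routes to Kruskal-Wallis + Dunn in
        >= 80% of simulations."""
        rng = np.random.default_rng(2)
        taken = 0
        n_sim = 40
        for _ in range(n_sim):
            groups = {
                "a": rng.normal(0, 1, 50),
                "b": rng.standard_cauchy(50),
            }
            res = cs.compare_groups(groups)
            taken += res.test_used == "kruskal_dunn"
        assert taken / n_sim >= 0.8

    def test_small_groups_cannot_certify_normality(self):
        rng = np.random.default_rng(3)
        res = cs.compare_groups({"a": rng.normal(0, 1, 5), "b": rng.normal(0, 1, 5)})
        assert res.test_used == "kruskal_dunn"

    def test_tiny_group_excluded_with_warning(self):
        rng = np.random.default_rng(4)
        with pytest.warns(RuntimeWarning, match="excluded"):
            res = cs.compare_groups(
                {
                    "a": rng.normal(0, 1, 10),
                    "b": rng.normal(0, 1, 10),
                    "c": [1.0, 2.0],
                }
            )
        assert res.excluded == ["c"]

    def test_adjusted_p_not_below_raw(self):
        rng = np.random.default_rng(5)
        res = cs.compare_groups(
            {g: rng.normal(0, 1, 10) for g in "abcd"}
        )
        assert (res.pairwise["p_adj"] >= res.pairwise["p_raw"] - 1e-12).all()

    def test_trend_band_reported(self):
        assert cs._categorize(0.07) == "trend"
        assert cs._categorize(0.04) == "significant"
        assert cs._categorize(0.2) == "ns"

    def test_familywise_error_under_null(self):
        """FWER of the full gated pipeline <= 0.06 at nominal 0.05."""
        rng = np.random.default_rng(6)
        n_sim = 2000
        false_pos = 0
        for _ in range(n_sim):
            groups = {g: rng.normal(50, 5, 10) for g in "abc"}
            res = cs.compare_groups(groups)
            false_pos += len(res.significant_pairs()) > 0
        assert false_pos / n_sim <= 0.06


class TestMarkers:
    def test_single_factor_markers(self):
        a = {"genotype": "APP/PS1", "diet": "NC"}
        b = {"genotype": "WT", "diet": "NC"}
        assert cs.assign_marker(a, b) == "*"
        c = {"genotype": "APP/PS1", "diet": "Hfd"}
        assert cs.assign_marker(a, c) == "†"
        assert cs.assign_marker({"treatment": "aLy6G"}, {"treatment": "IsoCtr"}) == "#"
        assert cs.assign_marker({"age": 11}, {"age": 21}) == "λ"

    def test_multi_factor_concatenation_and_purity(self):
        a = {"genotype": "APP/PS1", "diet": "NC"}
        b = {"genotype": "WT", "diet": "Hfd"}
        assert cs.assign_marker(a, b) == "*†"
        assert cs.assign_marker(a, b) == cs.assign_marker(a, b)
        assert cs.assign_marker(a, dict(a)) == ""


class TestInteraction:
    def test_synergistic_effect_detected(self):
        rng = np.random.default_rng(7)
        fa, fb, y = [], [], []
        for ga in ("wt", "tg"):
            for gb in ("nc", "hfd"):
                effect = 5.0 if (ga, gb) == ("tg", "hfd") else 0.0
                for _ in range(10):
                    fa.append(ga)
                    fb.append(gb)
                    y.append(rng.normal(effect, 1.0))
        res = cs.interaction_test(y, fa, fb)
        assert res["interaction_p"] < 0.01

    def test_no_interaction_when_effects_additive(self):
        rng = np.random.default_rng(8)
        fa, fb, y = [], [], []
        for ga in ("wt", "tg"):
            for gb in ("nc", "hfd"):
                mean = 2.0 * (ga == "tg") + 3.0 * (gb == "hfd")
                for _ in range(15):
                    fa.append(ga)
                    fb.append(gb)
                    y.append(rng.normal(mean, 1.0))
        res = cs.interaction_test(y, fa, fb)
        assert res["interaction_p"] > 0.05


class TestScoreLogs:
    def test_scores_frame_complete(self):
        logs = generate_behavior({"a": BehaviorParams(), "b": BehaviorParams()}, 4, seed=9)
        df = cs.score_logs(logs)
        assert len(df) == 8
        assert set(df["group"]) == {"a", "b"}
        assert df["alternation_pct"].between(0, 100).all()
        assert df["or_preference_pct"].between(0, 100).all()
        assert (df["beam_time_s"] > 0).all()
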
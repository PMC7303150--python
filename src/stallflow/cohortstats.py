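"""Behavioral scoring and group-comparison statistics.

Scores
    * Y-maze spontaneous alternation: 100 x (alternating triads) /
      (arm entries - 2), a triad being three consecutive entries into
      three different arms.
    * Object-replacement (OR) preference: 100 x time on the moved object
      / total object exploration time in trial 2.
    * Three-chamber sociability: fraction of time in the stranger's
      chamber, and fraction of direct-contact time with the stranger,
      per session.
    * Balance beam: mean crossing time and mean hindpaw slips over the
      last two of three trials (the first trial is habituation).

Comparisons
    :func:`compare_groups` follows a normality-gated decision rule:
    D'Agostino–Pearson on every group; if all groups look normal, one-way
    ANOVA with Holm–Šídák-corrected pairwise t-tests; otherwise
    Kruskal–Wallis with Holm-corrected Dunn pairwise tests.  p < 0.05 is
    significant and p in [0.05, 0.1) is reported as a trend.  Pairs of
    groups differing in exactly one design factor get that factor's
    significance marker (* genotype, # treatment, † diet, λ age).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

FACTOR_MARKERS = {"genotype": "*", "treatment": "#", "diet": "†", "age": "λ"}


class UndefinedScoreError(ValueError):
    """The event log cannot support the requested score."""


# --------------------------------------------------------------------------
# Scores


def alternation_score(entries) -> float:
    """Spontaneous alternation %: triads of 3 distinct arms / (n - 2) x 100."""
    entries = list(entries)
    if len(entries) < 3:
        raise UndefinedScoreError(
            f"need at least 3 arm entries for an alternation score; got {len(entries)}"
        )
    triads = sum(
        1
        for i in range(len(entries) - 2)
        if len(set(entries[i : i + 3])) == 3
    )
    return 100.0 * triads / (len(entries) - 2)


def or_preference(exploration: dict, novel_key: str = "moved") -> float:
    """OR preference %: novel-object share of total trial-2 exploration."""
    total = sum(exploration.values())
    if total <= 0:
        raise UndefinedScoreError("no object exploration recorded; score undefined")
    return 100.0 * exploration[novel_key] / total


def sociability_scores(log) -> dict:
    """Chamber-time and direct-contact fractions per session.

    For session 1 the preferred side is the stranger (vs empty); for
    session 2 the novel stranger (vs the familiar one).
    """
    out = {}
    for session, pref in (("session1", "stranger"), ("session2", "novel")):
        rec = log.sociability.get(session)
        if rec is None or "chamber_s" not in rec:
            raise UndefinedScoreError(f"missing chamber record for {session}")
        chamber = rec["chamber_s"]
        contact = rec.get("contact_s", {})
        out[session] = {
            "chamber_fraction": chamber[pref] / sum(chamber.values()),
            "contact_fraction": (
                contact[pref] / sum(contact.values()) if contact else float("nan")
            ),
        }
    return out


def beam_metrics(trials) -> tuple[float, float]:
    """Mean (crossing time, hindpaw slips) over the last two trials.

    The first trial is excluded as habituation; with fewer than 3 trials
    the available last <= 2 are used, with a warning.
    """
    trials = list(trials)
    if len(trials) < 3:
        warnings.warn(
            f"expected 3 beam trials, got {len(trials)}; using the last "
            f"{min(len(trials), 2)}",
            RuntimeWarning,
        )
    use = trials[-2:] if len(trials) >= 2 else trials
    times = [t for t, _ in use]
    slips = [s for _, s in use]
    return float(np.mean(times)), float(np.mean(slips))


def score_logs(logs) -> pd.DataFrame:
    """One row of behavioral scores per mouse."""
    rows = []
    for log in logs:
        soc = sociability_scores(log)
        t, s = beam_metrics(log.beam)
        rows.append(
            {
                "mouse_id": log.mouse_id,
                "group": log.group,
                "alternation_pct": alternation_score(log.arm_entries),
                "arm_entries": len(log.arm_entries),
                "or_preference_pct": or_preference(log.exploration),
                "total_exploration_s": sum(log.exploration.values()),
                "sociability_chamber_fraction": soc["session1"]["chamber_fraction"],
                "sociability_contact_fraction": soc["session1"]["contact_fraction"],
                "novelty_chamber_fraction": soc["session2"]["chamber_fraction"],
                "novelty_contact_fraction": soc["session2"]["contact_fraction"],
                "beam_time_s": t,
                "beam_slips": s,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Group comparison


@dataclass
class GroupComparison:
    measure: str
    groups: list
    normality_p: dict
    test_used: str  # 'anova_holm_sidak' | 'kruskal_dunn'
    omnibus_p: float
    pairwise: pd.DataFrame  # group_a, group_b, p_raw, p_adj, category, marker
    excluded: list = field(default_factory=list)

    def significant_pairs(self):
        return self.pairwise[self.pairwise["category"] == "significant"]


def _dunn_pairwise(groups_values: dict) -> list:
    """Two-sided Dunn z-tests on rank sums, with tie correction."""
    labels = list(groups_values)
    all_vals = np.concatenate([groups_values[g] for g in labels])
    n = all_vals.size
    ranks = stats.rankdata(all_vals)
    mean_ranks = {}
    pos = 0
    for g in labels:
        k = len(groups_values[g])
        mean_ranks[g] = ranks[pos : pos + k].mean()
        pos += k
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    out = []
    for a, b in itertools.combinations(labels, 2):
        na, nb = len(groups_values[a]), len(groups_values[b])
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        out.append((a, b, float(p)))
    return out


def _categorize(p: float) -> str:
    if p < 0.05:
        return "significant"
    if p < 0.1:
        return "trend"
    return "ns"


def assign_marker(labels_a: dict, labels_b: dict) -> str:
    """Marker for a pair from its design labels — pure function.

    Pairs differing in exactly one design factor get that factor's
    symbol (* genotype, # treatment, † diet, λ age); pairs differing in
    several factors get the concatenation, in factor order.
    """
    differing = [
        f
        for f in FACTOR_MARKERS
        if labels_a.get(f) is not None
        and labels_b.get(f) is not None
        and labels_a[f] != labels_b[f]
    ]
    return "".join(FACTOR_MARKERS[f] for f in differing)


def compare_groups(
    values_by_group: dict,
    design_labels: dict | None = None,
    *,
    measure: str = "measure",
    alpha: float = 0.05,
) -> GroupComparison:
    """Normality-gated omnibus + pairwise comparison across groups.

    ``values_by_group`` maps group label -> 1D values; groups with fewer
    than 3 values are excluded with a warning.  ``design_labels`` maps
    group label -> {factor: level} and drives significance markers.
    Groups too small for the D'Agostino-Pearson test (n < 8) cannot
    certify normality and send the comparison down the nonparametric
    branch.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    excluded = [g for g, v in groups.items() if v.size < 3]
    for g in excluded:
        warnings.warn(f"group {g!r} has fewer than 3 values; excluded", RuntimeWarning)
        del groups[g]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with >= 3 values each")

    normality_p = {}
    all_normal = True
    for g, v in groups.items():
        if v.size < 8:
            normality_p[g] = float("nan")
            all_normal = False
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(stats.normaltest(v).pvalue)
        normality_p[g] = p
        if p < alpha:
            all_normal = False

    labels = list(groups)
    pairs = list(itertools.combinations(labels, 2))
    if all_normal:
        test_used = "anova_holm_sidak"
        omnibus_p = float(stats.f_oneway(*groups.values()).pvalue)
        raw = [
            float(stats.ttest_ind(groups[a], groups[b]).pvalue) for a, b in pairs
        ]
        adj = multipletests(raw, method="holm-sidak")[1]
    else:
        test_used = "kruskal_dunn"
        omnibus_p = float(stats.kruskal(*groups.values()).pvalue)
        dunn = _dunn_pairwise(groups)
        raw = [p for _, _, p in dunn]
        adj = multipletests(raw, method="holm")[1]

    rows = []
    for (a, b), p_raw, p_adj in zip(pairs, raw, adj):
        marker = (
            assign_marker(design_labels.get(a, {}), design_labels.get(b, {}))
            if design_labels
            else ""
        )
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "p_raw": p_raw,
                "p_adj": float(max(p_adj, p_raw)),
                "category": _categorize(float(p_adj)),
                "marker": marker,
            }
        )
    return GroupComparison(
        measure=measure,
        groups=labels,
        normality_p=normality_p,
        test_used=test_used,
        omnibus_p=omnibus_p,
        pairwise=pd.DataFrame(rows),
        excluded=excluded,
    )


def interaction_test(
    values, factor_a, factor_b, *, measure: str = "measure"
) -> dict:
    """Optional two-factor interaction (synergy) test via OLS ANOVA.

    Tests whether the effect of one factor depends on the level of the
    other (e.g. genotype x diet synergy), returning the interaction-term
    p-value from a type-2 ANOVA on a linear model with both factors and
    their product.
    """
    import statsmodels.api as smapi
    from statsmodels.formula.api import ols

    df = pd.DataFrame(
        {"y": np.asarray(values, float), "fa": list(factor_a), "fb": list(factor_b)}
    )
    model = ols("y ~ C(fa) * C(fb)", data=df).fit()
    table = smapi.stats.anova_lm(model, typ=2)
    p_int = float(table.loc["C(fa):C(fb)", "PR(>F)"])
    return {
        "measure": measure,
        "interaction_p": p_int,
        "category": _categorize(p_int),
        "anova_table": table,
    }
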
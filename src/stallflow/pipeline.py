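"""End-to-end study scenarios on synthetic data.

Each function wires the synthetic generators to the measurement and
aggregation machinery and returns the recovered quantity next to its
generating ground truth.  Group-level defaults reflect the measured
study conditions these scenarios emulate: capillary stall prevalences
of 2% (amyloid-overexpressing mice, 11 months) down to 0.3–0.6%
(wild-type), a stall composition of 86% leukocyte / 5% platelet / 9%
RBC-only, a crowd of heterogeneous annotators, and behavioral
preference levels around 60%.
"""

from __future__ import annotations

import numpy as np

from . import hemodyn, stallcrowd, stallmetrics
from ._seeds import stream
from .synthgen import (
    BehaviorParams,
    generate_behavior,
    generate_network,
    generate_players,
    render_linescan,
    render_single_capillary,
)

#: Percent of capillaries stalled per group at 11 (21) months.
STALL_RATES = {
    "APP/PS1-NC": {11: 0.020, 21: 0.011},
    "APP/PS1-Hfd": {11: 0.017, 21: 0.013},
    "WT-NC": {11: 0.006, 21: 0.003},
    "WT-Hfd": {11: 0.005, 21: 0.005},
}

#: Stall cellular composition per group (leukocyte, platelet, rbc_only).
STALL_COMPOSITION = {
    "APP/PS1-NC": (0.86, 0.05, 0.09),
    "APP/PS1-Hfd": (0.80, 0.15, 0.05),
    "WT-NC": (0.0, 0.5, 0.5),
    "WT-Hfd": (0.6, 0.0, 0.4),
}


# --------------------------------------------------------------------------
# Crowd-pipeline stall-fraction recovery


def recover_stall_fraction(
    true_rate: float,
    *,
    n_stacks: int = 3,
    n_penetrating: int = 8,
    capillaries_per_pa: int = 500,
    composition=(0.86, 0.05, 0.09),
    n_players: int = 100,
    sensitivity_beta: tuple = (8.0, 2.0),
    min_answers: int = 8,
    seed: int = 0,
) -> dict:
    """Run the full crowd pipeline on synthetic stacks at a known rate.

    Generates ``n_stacks`` vascular networks (each
    ``n_penetrating x capillaries_per_pa`` capillary segments) with the
    given per-segment stall probability, simulates the annotator crowd
    with a threshold from :func:`~stallflow.stallcrowd.calibrate_threshold`,
    triages with a ground-truth expert, and reports the group-mean
    recovered stall fraction in percent.
    """
    pool = generate_players(n_players, sensitivity_beta, seed=seed + 1)

    # Threshold calibration on a labelled test set (5% known stalls).
    test_truths = np.zeros(400, dtype=bool)
    test_truths[:20] = True
    cal = stallcrowd.calibrate_threshold(
        test_truths, pool, seed=seed + 2, min_answers=min_answers
    )

    truths = []
    stack_ids = []
    for s in range(n_stacks):
        g = generate_network(
            n_penetrating,
            capillaries_per_pa,
            true_rate,
            composition,
            seed=seed * 17 + 3 + s,
        )
        edge_stalled = [
            g.graph.edges[e]["is_stalled"] for e in g.capillary_edges()
        ]
        truths.append(np.array(edge_stalled, dtype=bool))
        stack_ids.append(np.full(len(edge_stalled), s))
    truths = np.concatenate(truths)
    stack_ids = np.concatenate(stack_ids)

    res = stallcrowd.simulate_crowd(
        truths,
        pool,
        cal.threshold,
        stack_ids=stack_ids,
        min_answers=min_answers,
        seed=seed + 7,
    )
    calls, report = stallcrowd.expert_triage(
        res.calls, stallcrowd.ground_truth_oracle(res.calls)
    )
    per_stack, group = stallmetrics.stall_fraction(
        calls, {s: int((stack_ids == s).sum()) for s in range(n_stacks)}
    )
    return {
        "recovered_pct": float(group["mean"].iloc[0] * 100.0),
        "true_pct": float(truths.mean() * 100.0),
        "generating_pct": 100.0 * true_rate,
        "threshold": cal.threshold,
        "per_stack": per_stack,
        "precision_report": report,
        "n_segments": int(truths.size),
    }


def high_confidence_precision(
    *,
    n_segments: int = 20000,
    true_rate: float = 0.01,
    n_players: int = 120,
    competence_range: tuple = (0.75, 0.98),
    threshold: float = 6.5,
    min_answers: int = 8,
    seed: int = 0,
) -> dict:
    """Precision among items with crowd confidence > 0.9.

    Competent annotators (sensitivity and specificity uniform-Beta over
    ``competence_range``) score ``n_segments`` research segments with at
    least ``min_answers`` answers each; returns the percent of
    high-confidence items that are truly stalled.
    """
    pool = generate_players(
        n_players, (2.0, 2.0), seed=seed + 1, sensitivity_range=competence_range
    )
    truths = stream(seed, "stalls").random(n_segments) < true_rate
    res = stallcrowd.simulate_crowd(
        truths, pool, threshold, min_answers=min_answers, seed=seed + 3
    )
    df = res.calls.table
    hi = df[df["confidence"] > 0.9]
    precision = float((hi["truth"] == "stalled").mean() * 100.0)
    return {
        "precision_pct": precision,
        "n_high_confidence": int(len(hi)),
        "n_truly_stalled": int(truths.sum()),
        "mean_answers": float(df["n_answers"].mean()),
    }


# --------------------------------------------------------------------------
# Composition recovery through rendering + channel classification


def recover_composition(
    composition=(0.86, 0.05, 0.09),
    n_stalls: int = 500,
    seed: int = 0,
) -> dict:
    """Render stalled segments and recover the cause mix by channel logic."""
    causes = ("leukocyte", "platelet", "rbc_only")
    rng = stream(seed, "causes")
    drawn = rng.choice(3, size=n_stalls, p=np.asarray(composition, float))
    counts = {c: 0 for c in (*causes, "ambiguous")}
    correct = 0
    for i, ci in enumerate(drawn):
        stack, seg = render_single_capillary(causes[ci], seed=seed * 1000 + i)
        got = stallmetrics.classify_stall_cause(stack, seg)
        counts[got] = counts.get(got, 0) + 1
        correct += got == causes[ci]
    total = sum(counts.values())
    return {
        "fractions_pct": {c: 100.0 * counts[c] / total for c in counts},
        "drawn_pct": {
            c: 100.0 * float((drawn == k).mean()) for k, c in enumerate(causes)
        },
        "accuracy": correct / n_stalls,
        "n_stalls": n_stalls,
    }


# --------------------------------------------------------------------------
# Line-scan effect recovery


def recover_speed_effect(
    effect: float = 0.34,
    *,
    n_vessels: int = 20,
    median_um_s: float = 1000.0,
    cv: float = 0.2,
    paired_noise_cv: float = 0.0,
    seed: int = 0,
) -> dict:
    """Recover a percent change in median speed from rendered line scans.

    Vessel speeds are log-normal (median ``median_um_s``, coefficient of
    variation ``cv``); the same vessels are measured before and after
    (a repeated-measures design), with the true post speed
    ``(1 + effect)`` times the pre speed, so the post median equals the
    pre median scaled by the effect.  ``paired_noise_cv`` optionally
    adds a per-vessel physiological fluctuation between sessions.
    Speeds are estimated from rendered line scans by Radon velocimetry
    and the change in group medians is returned in percent.
    """
    rng = stream(seed, "speeds")
    sigma = float(np.sqrt(np.log(1.0 + cv**2)))
    pre = median_um_s * np.exp(sigma * rng.normal(size=n_vessels))
    wobble = np.exp(paired_noise_cv * rng.normal(size=n_vessels))
    post = pre * (1.0 + effect) * wobble

    def measure(speeds, tag):
        out = []
        for i, v in enumerate(speeds):
            ls = render_linescan(
                float(v), scan_rate=1000.0, duration=0.256, seed=seed + 31 * i + tag
            )
            est = hemodyn.estimate_speed(ls)
            if not est.low_confidence:
                out.append(est.speed_um_s)
        return out

    pre_est = measure(pre, 0)
    post_est = measure(post, 1)
    return {
        "recovered_pct": hemodyn.percent_change(pre_est, post_est),
        "true_pct": hemodyn.percent_change(pre.tolist(), post.tolist()),
        "generating_pct": 100.0 * effect,
        "n_pre": len(pre_est),
        "n_post": len(post_est),
    }


# --------------------------------------------------------------------------
# Behavioral recovery


def recover_or_preference(
    preference: float = 0.6, n_logs: int = 1000, seed: int = 0
) -> dict:
    """Mean OR preference score over synthetic exploration logs."""
    from .cohortstats import or_preference

    logs = generate_behavior(
        {"g": BehaviorParams(or_preference=preference)}, n_logs, seed=seed
    )
    scores = [or_preference(log.exploration) for log in logs]
    return {
        "mean_score_pct": float(np.mean(scores)),
        "generating_pct": 100.0 * preference,
        "n_logs": n_logs,
    }
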
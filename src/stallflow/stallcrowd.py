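"""Crowd-sourced stall scoring: calibration, weighting, stopping, triage.

The engine mirrors the mechanics of a citizen-science scoring platform
for flowing/stalled capillary judgments:

* every annotator's **sensitivity** — the probability they correctly
  label a truly stalled item — is estimated continuously from
  interleaved *calibration vessels* whose truth is known;
* research answers are **weighted by the annotator's sensitivity at the
  time of the answer** (weights are frozen into the answer record) and
  averaged into a per-segment *crowd confidence* in [0, 1], where values
  near 1 mean almost certainly stalled;
* an item stops collecting answers once the **sum of the sensitivities**
  of its answerers reaches a threshold, itself calibrated so that known
  stalls rank at the top of the confidence ordering;
* the mix of stalled vs flowing calibration items served is adjusted so
  the **overall fraction of stalled items shown stays constant** even as
  skilled players see mostly research items (whose stall base rate is
  well under 1%);
* finally, items with confidence >= 0.5 are **triaged by an expert** in
  descending confidence order, and only expert-confirmed stalls count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import stream

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Player profile and sensitivity updates


@dataclass
class PlayerProfile:
    """Running, Laplace-smoothed accuracy estimates for one annotator."""

    player_id: str
    stalled_seen: int = 0
    stalled_correct: int = 0
    flowing_seen: int = 0
    flowing_correct: int = 0
    alpha: float = 1.0  # symmetric smoothing; a new player sits at 0.5

    @property
    def sensitivity(self) -> float:
        return (self.stalled_correct + self.alpha) / (
            self.stalled_seen + 2 * self.alpha
        )

    @property
    def specificity(self) -> float:
        return (self.flowing_correct + self.alpha) / (
            self.flowing_seen + 2 * self.alpha
        )


def update_sensitivity(
    profile: PlayerProfile, answer: str, truth: str | None
) -> PlayerProfile:
    """Record a calibration answer and update the profile in place.

    ``truth`` must be known ('stalled' or 'flowing'): calibration items
    carry ground truth by definition.
    """
    if truth not in ("stalled", "flowing"):
        raise ValueError("calibration items must carry truth ('stalled'/'flowing')")
    if truth == "stalled":
        profile.stalled_seen += 1
        profile.stalled_correct += int(answer == truth)
    else:
        profile.flowing_seen += 1
        profile.flowing_correct += int(answer == truth)
    return profile


def serving_ratio(sensitivity: float) -> float:
    """Research:calibration serving ratio R (R research per 1 calibration).

    A nondecreasing step schedule: novices (ŝ <= 0.6) split 1:1; skilled
    players (ŝ >= 0.95) see 9 research items per calibration item.
    """
    if sensitivity <= 0.6:
        return 1.0
    if sensitivity <= 0.8:
        return 3.0
    if sensitivity < 0.95:
        return 5.0
    return 9.0


# --------------------------------------------------------------------------
# Answers, confidence, stopping


@dataclass
class AnswerRecord:
    player_id: str
    task_id: str
    answer: str  # 'flowing' | 'stalled'
    weight: float  # annotator sensitivity at answer time (frozen)
    order: int  # global timestamp index


@dataclass
class ConfidenceResult:
    value: float  # nan if undefined
    status: str = "ok"  # 'ok' | 'insufficient signal'

    def __float__(self) -> float:
        return self.value


def crowd_confidence(answers) -> ConfidenceResult:
    """Sensitivity-weighted fraction of 'stalled' votes."""
    if len(answers) == 0:
        raise ValueError("need at least one answer")
    w = np.array([a.weight for a in answers], dtype=float)
    stalled = np.array([a.answer == "stalled" for a in answers], dtype=float)
    tot = w.sum()
    if tot == 0:
        return ConfidenceResult(float("nan"), "insufficient signal")
    return ConfidenceResult(float((w * stalled).sum() / tot))


def stopping_rule(answers, threshold: float) -> str:
    """'closed' once the summed sensitivities of answerers reach the threshold."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if threshold == 0:
        warnings.warn(
            "threshold 0 closes every item immediately", RuntimeWarning
        )
    total = sum(a.weight for a in answers)
    return "closed" if total >= threshold else "open"


# --------------------------------------------------------------------------
# Serving with base-rate maintenance


_warned_infeasible: set = set()  # dedupe clamping warnings per configuration


def calibration_stalled_fraction(
    q: float, ratio: float, research_base_rate: float
) -> tuple[float, bool]:
    """Stalled share of calibration items that keeps the shown rate at q.

    With R research items per calibration item, the expected shown-stall
    fraction is ``(R * base + f) / (R + 1)``; solving for the calibration
    stalled fraction gives ``f = q * (R + 1) - base * R``.  Returns
    ``(f clamped to [0, 1], feasible)``.
    """
    f = q * (ratio + 1.0) - research_base_rate * ratio
    feasible = 0.0 <= f <= 1.0
    key = (round(q, 6), round(ratio, 6), round(research_base_rate, 6))
    if not feasible and key not in _warned_infeasible:
        _warned_infeasible.add(key)
        logger.warning(
            "target shown stall rate %.3f unachievable at ratio %.0f:1 "
            "(required calibration stalled fraction %.3f); clamping",
            q,
            ratio,
            f,
        )
    return float(np.clip(f, 0.0, 1.0)), feasible


@dataclass
class ServingQueues:
    """Item pools the server draws from."""

    research: list  # open research items
    calibration_stalled: list
    calibration_flowing: list
    research_base_rate: float = 0.01


def serve_next(
    profile: PlayerProfile,
    queues: ServingQueues,
    target_shown_stall_rate: float = 0.25,
    rng: np.random.Generator | None = None,
):
    """Pick the next item for this player.

    Research vs calibration follows the sensitivity-dependent serving
    ratio; within calibration, the stalled/flowing mix follows
    :func:`calibration_stalled_fraction` so the expected overall shown
    stall fraction equals the target whenever feasible.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if not (queues.research or queues.calibration_stalled or queues.calibration_flowing):
        raise ValueError("all serving queues are empty")
    ratio = serving_ratio(profile.sensitivity)
    p_research = ratio / (ratio + 1.0)
    if queues.research and (
        rng.random() < p_research
        or not (queues.calibration_stalled or queues.calibration_flowing)
    ):
        return queues.research[rng.integers(len(queues.research))]
    f, _ = calibration_stalled_fraction(
        target_shown_stall_rate, ratio, queues.research_base_rate
    )
    if queues.calibration_stalled and (
        rng.random() < f or not queues.calibration_flowing
    ):
        return queues.calibration_stalled[rng.integers(len(queues.calibration_stalled))]
    return queues.calibration_flowing[rng.integers(len(queues.calibration_flowing))]


# --------------------------------------------------------------------------
# Call table and expert triage

CONFIDENCE_BINS = [(0.5, 0.6), (0.6, 0.7), (0.7, 0.8), (0.8, 0.9), (0.9, 1.0)]


@dataclass
class StallCallTable:
    """Per-research-segment crowd outcome."""

    table: pd.DataFrame
    # columns: task_id, stack_id, confidence, sum_sensitivity, n_answers,
    #          status, expert_verdict, truth

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StallCallTable":
        return cls(pd.read_csv(path))

    def confirmed_stalls(self) -> pd.DataFrame:
        return self.table[self.table["expert_verdict"] == "stalled"]


def expert_triage(table: StallCallTable, expert_oracle) -> tuple[StallCallTable, dict]:
    """Review items with confidence >= 0.5 in descending-confidence order.

    ``expert_oracle(task_id) -> 'stalled' | 'flowing'`` stands in for the
    human reviewer (ground truth, in simulation).  Items at exactly 0.5
    are included.  Returns the finalized table and a precision report
    per confidence bin.
    """
    df = table.table
    if (df["status"] != "closed").any():
        raise ValueError("expert triage requires all items to be closed")
    df = df.copy()
    df["expert_verdict"] = "unreviewed"
    order = df[df["confidence"] >= 0.5].sort_values(
        "confidence", ascending=False, kind="mergesort"
    )
    for idx in order.index:
        df.loc[idx, "expert_verdict"] = expert_oracle(df.loc[idx, "task_id"])
    report = {"bins": []}
    for lo, hi in CONFIDENCE_BINS:
        sel = df[(df["confidence"] > lo) & (df["confidence"] <= hi)]
        n = int(len(sel))
        n_stalled = int((sel["expert_verdict"] == "stalled").sum())
        report["bins"].append(
            {
                "bin": (lo, hi),
                "n_reviewed": n,
                "n_stalled": n_stalled,
                "precision": n_stalled / n if n else float("nan"),
            }
        )
    return StallCallTable(df), report


# --------------------------------------------------------------------------
# End-to-end simulation


@dataclass
class SimulationResult:
    calls: StallCallTable
    answers: list  # AnswerRecord log
    profiles: dict  # player_id -> PlayerProfile
    shown_stall_fraction: float
    n_served: int


def simulate_crowd(
    truths,
    pool,
    threshold: float,
    *,
    stack_ids=None,
    target_shown_stall_rate: float = 0.25,
    min_answers: int = 1,
    research_base_rate: float | None = None,
    seed: int = 0,
    max_answers_per_item: int = 200,
    keep_answers: bool = False,
) -> SimulationResult:
    """Run the full serving/answering/aggregation loop on simulated players.

    ``truths`` is a boolean array (True = truly stalled) over research
    segments; ``pool`` a :class:`~stallflow.synthgen.PlayerPool`.  Players
    are drawn uniformly at random; each serves one item per step per the
    serving schedule, answers via their Bernoulli response model, and the
    loop runs until every research item is closed (summed sensitivities
    >= ``threshold`` and at least ``min_answers`` answers).
    """
    truths = np.asarray(truths, dtype=bool)
    n = truths.size

    def respond(player, truly_stalled: bool, r) -> str:
        # Bernoulli response drawn from the simulation's own stream so a
        # run is reproducible from its seed regardless of pool history.
        p_stalled = (
            player.true_sensitivity if truly_stalled else 1.0 - player.true_specificity
        )
        return "stalled" if r.random() < p_stalled else "flowing"

    if stack_ids is None:
        stack_ids = np.zeros(n, dtype=int)
    stack_ids = np.asarray(stack_ids)
    if research_base_rate is None:
        research_base_rate = max(float(truths.mean()), 1e-4)
    rng = stream(seed, "crowd")

    players = list(pool)
    profiles = {p.id: PlayerProfile(p.id) for p in players}

    w_total = np.zeros(n)
    w_stalled = np.zeros(n)
    n_ans = np.zeros(n, dtype=int)
    answered_by: list[list] = [[] for _ in range(n)]
    open_items = list(range(n))
    answers: list[AnswerRecord] = []

    served = 0
    served_stalled = 0
    order = 0
    while open_items:
        pi = int(rng.integers(len(players)))
        player = players[pi]
        prof = profiles[player.id]
        s_hat = prof.sensitivity
        ratio = serving_ratio(s_hat)
        if rng.random() < ratio / (ratio + 1.0):
            # --- research item
            for _ in range(4):
                k = int(rng.integers(len(open_items)))
                item = open_items[k]
                if pi not in answered_by[item]:
                    break
            else:
                continue
            truly_stalled = bool(truths[item])
            ans = respond(player, truly_stalled, rng)
            w_total[item] += s_hat
            w_stalled[item] += s_hat * (ans == "stalled")
            n_ans[item] += 1
            answered_by[item].append(pi)
            if keep_answers:
                answers.append(
                    AnswerRecord(player.id, f"r{item}", ans, s_hat, order)
                )
            served += 1
            served_stalled += int(truly_stalled)
            if (
                w_total[item] >= threshold and n_ans[item] >= min_answers
            ) or n_ans[item] >= max_answers_per_item:
                open_items[k] = open_items[-1]
                open_items.pop()
        else:
            # --- calibration item
            f, _ = calibration_stalled_fraction(
                target_shown_stall_rate, ratio, research_base_rate
            )
            truth = "stalled" if rng.random() < f else "flowing"
            ans = respond(player, truth == "stalled", rng)
            update_sensitivity(prof, ans, truth)
            served += 1
            served_stalled += int(truth == "stalled")
        order += 1

    conf = np.where(w_total > 0, w_stalled / np.maximum(w_total, 1e-300), np.nan)
    df = pd.DataFrame(
        {
            "task_id": [f"r{i}" for i in range(n)],
            "stack_id": stack_ids,
            "confidence": conf,
            "sum_sensitivity": w_total,
            "n_answers": n_ans,
            "status": "closed",
            "expert_verdict": "unreviewed",
            "truth": np.where(truths, "stalled", "flowing"),
        }
    )
    return SimulationResult(
        calls=StallCallTable(df),
        answers=answers,
        profiles=profiles,
        shown_stall_fraction=served_stalled / served if served else float("nan"),
        n_served=served,
    )


def ground_truth_oracle(calls: StallCallTable):
    """Expert oracle for simulations: answers with the stored ground truth."""
    lookup = dict(zip(calls.table["task_id"], calls.table["truth"]))

    def oracle(task_id: str) -> str:
        return lookup[task_id]

    return oracle


# --------------------------------------------------------------------------
# Threshold calibration


@dataclass
class CalibrationResult:
    threshold: float
    satisfied: bool
    per_threshold: dict = field(default_factory=dict)

    def __float__(self) -> float:
        return self.threshold


def calibrate_threshold(
    truths,
    pool,
    grid=(2.0, 3.0, 4.0, 5.0, 6.0, 8.0),
    *,
    seed: int = 0,
    min_answers: int = 1,
    target_shown_stall_rate: float = 0.25,
) -> CalibrationResult:
    """Smallest stopping threshold that ranks all known stalls on top.

    For each candidate threshold, the crowd is simulated on the test set
    and the criterion checked: every known stalled item's confidence
    must exceed the 95th percentile of the flowing items' confidences.
    If no candidate satisfies it, the largest is returned with
    ``satisfied=False`` (an uninformative crowd cannot be fixed by
    collecting more answers).
    """
    truths = np.asarray(truths, dtype=bool)
    if truths.sum() < 1:
        raise ValueError("test set must contain at least one known stall")
    per = {}
    for t in sorted(grid):
        res = simulate_crowd(
            truths,
            pool,
            t,
            seed=seed,
            min_answers=min_answers,
            target_shown_stall_rate=target_shown_stall_rate,
        )
        conf = res.calls.table["confidence"].to_numpy()
        stalled_conf = conf[truths]
        flowing_conf = conf[~truths]
        cut = float(np.percentile(flowing_conf, 95)) if flowing_conf.size else 0.0
        ok = bool(np.all(stalled_conf > cut))
        per[t] = {"cutoff": cut, "min_stalled_conf": float(stalled_conf.min()), "ok": ok}
        if ok:
            return CalibrationResult(float(t), True, per)
    logger.warning(
        "no threshold on the grid ranks all known stalls above the flowing "
        "95th percentile; returning the largest candidate"
    )
    return CalibrationResult(float(max(grid)), False, per)
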
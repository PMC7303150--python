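"""Synthetic rodent behavioral event logs with tunable effect sizes.

Covers the four assays scored downstream: Y-maze arm-entry sequences
(working memory, spontaneous alternation), object-replacement
exploration times (spatial memory), three-chamber sociability sessions,
and balance-beam trials (sensory-motor function).  Every generator
parameter maps directly onto the expected value of the corresponding
score — e.g. an object-replacement preference of 0.6 yields logs whose
mean preference score is 60%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .._seeds import stream

ARMS = ("A", "B", "C")


@dataclass
class BehaviorParams:
    """Per-group generating parameters for one cohort.

    ``alternation_propensity`` is the probability that the next Y-maze
    arm differs from both of the last two (1.0 → perfect alternation);
    ``or_preference`` is the expected share of trial-2 exploration on the
    moved object; ``sociability_preference`` the expected share of
    stranger-side time.  Beam-crossing times are log-normal (seconds,
    capped at the 60 s trial limit) and hindpaw slips Poisson.
    """

    alternation_propensity: float = 0.7
    or_preference: float = 0.6
    sociability_preference: float = 0.65
    beam_time_mean_s: float = 10.0
    beam_time_cv: float = 0.3
    beam_slip_mean: float = 1.0
    n_entries_mean: float = 16.0
    exploration_total_mean_s: float = 40.0
    concentration: float = 50.0  # Beta concentration for preference shares

    def __post_init__(self):
        for name in ("alternation_propensity", "or_preference", "sociability_preference"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]; got {v}")


@dataclass
class BehaviorLog:
    """One mouse's raw behavioral events across the four assays."""

    mouse_id: str
    group: str
    arm_entries: list[str]
    exploration: dict  # object id -> seconds (trial 2)
    sociability: dict  # per-session chamber and contact seconds
    beam: list[tuple]  # (crossing time s, hindpaw slips) per trial

    def validate(self) -> None:
        if any(a not in ARMS for a in self.arm_entries):
            raise ValueError("arm labels must come from the 3-arm set")
        if any(v < 0 for v in self.exploration.values()):
            raise ValueError("exploration durations must be non-negative")
        for t, s in self.beam:
            if t < 0 or s < 0:
                raise ValueError("beam durations and slip counts must be non-negative")


def _beta_share(rng, mean: float, conc: float) -> float:
    if mean <= 0.0:
        return 0.0
    if mean >= 1.0:
        return 1.0
    return float(rng.beta(mean * conc, (1.0 - mean) * conc))


def _arm_sequence(rng, n: int, avoid_last_two: float) -> list[str]:
    seq = list(rng.choice(ARMS, size=1))
    second = [a for a in ARMS if a != seq[-1]]
    seq.append(second[rng.integers(len(second))])
    while len(seq) < n:
        others = [a for a in ARMS if a != seq[-1]]
        novel = [a for a in others if a != seq[-2]]
        if novel and rng.random() < avoid_last_two:
            seq.append(novel[0])
        else:
            seq.append(others[rng.integers(len(others))])
    return seq


def generate_behavior(
    group_params: dict[str, BehaviorParams],
    n_mice: int,
    seed: int = 0,
    *,
    session_s: float = 600.0,
) -> list[BehaviorLog]:
    """Generate ``n_mice`` logs for every group in ``group_params``."""
    rng = stream(seed, "behavior")
    logs = []
    for group in sorted(group_params):
        p = group_params[group]
        for i in range(n_mice):
            n_entries = max(int(rng.poisson(p.n_entries_mean)), 5)
            entries = _arm_sequence(rng, n_entries, p.alternation_propensity)

            total = rng.gamma(8.0, p.exploration_total_mean_s / 8.0)
            share = _beta_share(rng, p.or_preference, p.concentration)
            exploration = {
                "moved": share * total,
                "unmoved": (1.0 - share) * total,
            }

            soc = {}
            for session, (pref_side, other_side) in (
                ("session1", ("stranger", "empty")),
                ("session2", ("novel", "familiar")),
            ):
                center = rng.uniform(0.1, 0.3) * session_s
                side_total = session_s - center
                sshare = _beta_share(rng, p.sociability_preference, p.concentration)
                contact_total = rng.uniform(0.2, 0.4) * session_s
                cshare = _beta_share(rng, p.sociability_preference, p.concentration)
                soc[session] = {
                    "duration_s": session_s,
                    "chamber_s": {
                        pref_side: sshare * side_total,
                        "center": center,
                        other_side: (1.0 - sshare) * side_total,
                    },
                    "contact_s": {
                        pref_side: cshare * contact_total,
                        other_side: (1.0 - cshare) * contact_total,
                    },
                }

            sigma = np.sqrt(np.log(1.0 + p.beam_time_cv**2))
            trials = []
            for trial in range(3):
                mean = p.beam_time_mean_s * (2.0 if trial == 0 else 1.0)
                t = float(
                    np.exp(np.log(mean) - sigma**2 / 2 + sigma * rng.normal())
                )
                trials.append((min(t, 60.0), int(rng.poisson(p.beam_slip_mean))))

            log = BehaviorLog(
                mouse_id=f"{group}_m{i:03d}",
                group=group,
                arm_entries=entries,
                exploration=exploration,
                sociability=soc,
                beam=trials,
            )
            log.validate()
            logs.append(log)
    return logs


def behavior_to_frame(logs: list[BehaviorLog]) -> pd.DataFrame:
    """Flatten logs into one row per mouse for CSV export."""
    rows = []
    for log in logs:
        rows.append(
            {
                "mouse_id": log.mouse_id,
                "group": log.group,
                "arm_entries": "".join(log.arm_entries),
                "exploration_moved_s": log.exploration["moved"],
                "exploration_unmoved_s": log.exploration["unmoved"],
                "beam_times_s": ";".join(f"{t:.3f}" for t, _ in log.beam),
                "beam_slips": ";".join(str(s) for _, s in log.beam),
            }
        )
    return pd.DataFrame(rows)
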
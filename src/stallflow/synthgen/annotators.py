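"""Synthetic citizen-scientist pools.

Each simulated annotator has a fixed true sensitivity (probability of
answering "stalled" on a truly stalled item) and true specificity
(probability of answering "flowing" on a flowing item); answers are
independent Bernoulli draws from these rates.  Heterogeneity across the
pool comes from a Beta distribution, optionally rescaled into a
sub-interval of [0, 1] to model a floor on annotator competence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .._seeds import stream, substream


@dataclass
class Player:
    id: str
    true_sensitivity: float
    true_specificity: float
    rng: np.random.Generator = field(repr=False, default=None)

    def answer(self, truly_stalled: bool) -> str:
        """One Bernoulli response: 'stalled' or 'flowing'."""
        if truly_stalled:
            p_stalled = self.true_sensitivity
        else:
            p_stalled = 1.0 - self.true_specificity
        return "stalled" if self.rng.random() < p_stalled else "flowing"


@dataclass
class PlayerPool:
    players: list[Player]

    def __len__(self) -> int:
        return len(self.players)

    def __iter__(self):
        return iter(self.players)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "player_id": [p.id for p in self.players],
                "true_sensitivity": [p.true_sensitivity for p in self.players],
                "true_specificity": [p.true_specificity for p in self.players],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def generate_players(
    n: int,
    sensitivity_dist: tuple[float, float] = (8.0, 2.0),
    seed: int = 0,
    *,
    specificity_dist: tuple[float, float] | None = None,
    sensitivity_range: tuple[float, float] = (0.0, 1.0),
    specificity_range: tuple[float, float] | None = None,
    fixed_sensitivity: float | None = None,
    fixed_specificity: float | None = None,
) -> PlayerPool:
    """Draw a pool of ``n`` annotators.

    Sensitivities are Beta(``sensitivity_dist``) draws mapped affinely
    into ``sensitivity_range``; specificities follow the same
    distribution unless configured separately.  ``fixed_sensitivity`` /
    ``fixed_specificity`` bypass the draw entirely (e.g. perfect
    annotators with both fixed at 1.0).
    """
    if n < 1:
        raise ValueError(f"need at least one player; got n={n}")
    rng = stream(seed, "players")
    a, b = sensitivity_dist
    lo, hi = sensitivity_range
    if fixed_sensitivity is not None:
        sens = np.full(n, float(fixed_sensitivity))
    else:
        sens = lo + (hi - lo) * rng.beta(a, b, size=n)
    sa, sb = specificity_dist if specificity_dist is not None else (a, b)
    slo, shi = (
        specificity_range
        if specificity_range is not None
        else (lo, hi)
    )
    if fixed_specificity is not None:
        spec = np.full(n, float(fixed_specificity))
    else:
        spec = slo + (shi - slo) * rng.beta(sa, sb, size=n)
    players = [
        Player(
            id=f"p{i:04d}",
            true_sensitivity=float(np.clip(sens[i], 0, 1)),
            true_specificity=float(np.clip(spec[i], 0, 1)),
            rng=substream(seed, "players", i + 1),
        )
        for i in range(n)
    ]
    return PlayerPool(players)
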
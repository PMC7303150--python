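"""Named, reproducible random streams.

Every stochastic routine in the package derives its generator from a user
seed through :func:`stream`, so independent parts of a simulation (network
topology, stall assignment, rendering noise, annotator behavior, ...) draw
from decoupled streams.  Changing how one component consumes randomness
then never perturbs another component seeded from the same integer.
"""

from __future__ import annotations

import numpy as np

# Fixed stream labels.  The integer key is hashed into the SeedSequence
# spawn key, so streams are stable across runs and across library versions.
_STREAMS = {
    "topology": 0,
    "stalls": 1,
    "causes": 2,
    "speeds": 3,
    "render": 4,
    "linescan": 5,
    "players": 6,
    "behavior": 7,
    "crowd": 8,
}


def stream(seed: int, name: str) -> np.random.Generator:
    """Return the named child generator of ``seed``.

    Parameters
    ----------
    seed:
        Master integer seed (non-negative, < 2**31 recommended).
    name:
        One of the registered stream labels.
    """
    if name not in _STREAMS:
        raise KeyError(f"unknown random stream {name!r}; known: {sorted(_STREAMS)}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[name],))
    return np.random.default_rng(ss)


def substream(seed: int, name: str, index: int) -> np.random.Generator:
    """A per-item child of a named stream (e.g. one stream per rendered crop)."""
    if name not in _STREAMS:
        raise KeyError(f"unknown random stream {name!r}; known: {sorted(_STREAMS)}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[name], int(index)))
    return np.random.default_rng(ss)
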
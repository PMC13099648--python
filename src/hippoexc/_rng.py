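"""Seed-splitting scheme.

All randomness in the package flows from a single user-supplied integer seed.
Independent streams are derived with :class:`numpy.random.SeedSequence.spawn`,
so adding a consumer never perturbs the streams of existing ones as long as
the spawn *index* is stable.  Stream indices are allocated by name below.
"""

from __future__ import annotations

import numpy as np

# Stable spawn-key indices per consumer; append only, never reorder.
_STREAMS = {
    "lfp": 0,
    "current_clamp": 1,
    "synaptic": 2,
    "counts": 3,
    "kmeans": 4,
    "bootstrap": 5,
    "pipeline": 6,
}


def stream(seed: int, name: str) -> np.random.Generator:
    """Return the named child generator of ``seed``."""
    if name not in _STREAMS:
        raise KeyError(f"unknown RNG stream {name!r}; known: {sorted(_STREAMS)}")
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS[name]])


def child_seed(seed: int, name: str) -> int:
    """A 31-bit integer seed derived from the named stream (for sklearn etc.)."""
    return int(stream(seed, name).integers(0, 2**31 - 1))
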
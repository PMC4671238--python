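"""Named random substreams derived from one master seed.

Each stochastic stage of an assessment (bootstrap, DAF, AHU, OU, sigma_H,
inner variability draws, resampling) consumes its own independent stream so
that, e.g., changing the inner-loop sample count never re-pairs the
uncertainty draws of the outer loop.
"""

from __future__ import annotations

import numpy as np

_STREAMS = {
    "bootstrap": 0,
    "daf": 1,
    "ahu": 2,
    "ou": 3,
    "sigma_h": 4,
    "inner_z": 5,
    "resample": 6,
    "pool": 7,
    "data": 8,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for the named stage under a master seed."""
    if name not in _STREAMS:
        raise KeyError(f"unknown substream {name!r}; known: {sorted(_STREAMS)}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[name],))
    return np.random.default_rng(ss)


def as_generator(seed) -> np.random.Generator:
    """Accept an int seed or a Generator and return a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(int(seed))
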
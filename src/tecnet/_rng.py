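"""Named, reproducible random streams.

Every stochastic operation in the package draws from its own named
substream of a single integer seed, so that changing the replicate count
of one stage never perturbs another stage's draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream"]


def stream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the (seed, name) pair.

    The same pair always yields the same stream; distinct names yield
    statistically independent streams under the same seed.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))
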
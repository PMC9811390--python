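"""Named random streams derived from a single pipeline seed.

Every stochastic stage of the pipeline draws from its own named stream so
that, e.g., regenerating the cohort does not perturb the train/test split.
Streams are derived from (seed, crc32(name)) via numpy's SeedSequence, so
they are independent and reproducible individually.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream"]


def stream(seed: int, name: str) -> np.random.Generator:
    """Return the reproducible random generator for stage ``name``."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))
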
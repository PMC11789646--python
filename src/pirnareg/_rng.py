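"""Derivation of independent, labelled random streams from one root seed.

Every generator in the package draws from a stream derived from
``(root_seed, label)``.  Labels are fixed strings, so adding a new
generator (a new label) never perturbs the output of an existing one,
and removing an item removes exactly its own draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream"]


def stream(seed: int, label: str) -> np.random.Generator:
    """Return a ``numpy`` Generator for the given root seed and label.

    The label is hashed with CRC-32 into the ``spawn_key`` of a
    :class:`numpy.random.SeedSequence`, giving streams that are
    statistically independent of one another and of the root stream.
    """
    if seed < 0:
        raise ValueError("root seed must be non-negative")
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))
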
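"""Named random substreams.

A single user-facing seed is expanded into independent per-component streams
keyed by a stable string, so adding a new simulated component never perturbs
the draws of an existing one.
"""
from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a generator for the substream ``name`` of the global ``seed``."""
    key = zlib.crc32(name.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))
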
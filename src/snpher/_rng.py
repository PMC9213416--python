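"""Named random substreams.

All randomness in the package flows from a single integer master seed.  Each
stage draws from a named substream so that stages can be re-run independently
and adding a stage never perturbs the streams of existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "derive_seed"]


def derive_seed(master_seed: int, name: str) -> int:
    """Deterministic 31-bit child seed for a named stage."""
    h = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(master_seed) & 0x7FFFFFFF, spawn_key=(h,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Generator for the substream ``name`` of ``master_seed``."""
    h = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(master_seed) & 0x7FFFFFFF, spawn_key=(h,))
    return np.random.default_rng(ss)
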
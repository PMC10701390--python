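"""Deterministic seed derivation.

A single master seed drives every stage of a run. Stage seeds are derived
from ``SeedSequence([master, crc32(stage), *indices])`` so each stage (and
each replicate within a stage) can be re-run in isolation and still produce
bit-identical output.
"""

from __future__ import annotations

import zlib

import numpy as np


def derive_rng(master_seed: int, stage: str, *indices: int) -> np.random.Generator:
    """Return a Generator for ``stage`` (plus optional replicate indices)."""
    key = zlib.crc32(stage.encode("utf-8"))
    seq = np.random.SeedSequence([int(master_seed), key, *map(int, indices)])
    return np.random.default_rng(seq)


def derive_seed(master_seed: int, stage: str, *indices: int) -> int:
    """Integer form of :func:`derive_rng`'s entropy (for APIs that take seeds)."""
    key = zlib.crc32(stage.encode("utf-8"))
    seq = np.random.SeedSequence([int(master_seed), key, *map(int, indices)])
    return int(seq.generate_state(1, dtype=np.uint64)[0] % (2**63))
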
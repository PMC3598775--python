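"""Deterministic random-stream derivation.

Every stochastic stage of the pipeline draws from its own generator derived
from ``(seed, stage_name[, index])`` so that stages can be re-run in
isolation and whole-pipeline runs are bitwise reproducible.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng"]


def stage_rng(seed: int, stage: str, index: int = 0) -> np.random.Generator:
    """Return a Generator unique to ``(seed, stage, index)``.

    The stage name is hashed with CRC32 (stable across processes, unlike
    ``hash``) and folded into a SeedSequence together with the global seed.
    """
    if not 0 <= int(seed) < 2**31:
        raise ValueError(f"seed must be in [0, 2^31), got {seed}")
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key, int(index)]))
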
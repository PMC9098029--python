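"""Named, reproducible sub-seed derivation.

Every randomized stage draws from a sub-seed derived from the global seed and
a stage name, so any stage can be re-run in isolation with the same stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_seed", "stage_rng"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a deterministic 31-bit seed for a named stage."""
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def stage_rng(global_seed: int, stage: str) -> np.random.Generator:
    """Generator seeded from the global seed and a stage name."""
    return np.random.default_rng(stage_seed(global_seed, stage))
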
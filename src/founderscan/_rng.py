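"""Named, independently reproducible random streams.

Each pipeline stage draws from its own generator derived from the master
seed and a stable stage label, so re-running one stage never perturbs the
randomness of another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng"]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Return a Generator for ``stage`` derived from the master ``seed``.

    The stream is a deterministic function of (seed, stage): identical
    inputs give byte-identical draws, and distinct stage labels give
    statistically independent streams.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    tag = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))
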
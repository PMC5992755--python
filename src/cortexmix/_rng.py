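"""Deterministic fan-out of one user-facing seed into per-stage generators.

Every stochastic operation in the package draws from a child generator keyed by
the global seed plus a short string label (and optional integer indices).  The
rule is ``SeedSequence([seed, crc32(label), *indices])``, so stages are
independently reproducible: re-running one stage with the same seed gives the
same stream no matter which other stages ran before it.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed_sequence"]


def child_seed_sequence(seed: int, *keys: "int | str") -> np.random.SeedSequence:
    """Return the SeedSequence for stage ``keys`` under global ``seed``."""
    entropy: list[int] = [int(seed) & 0x7FFFFFFF]
    for key in keys:
        if isinstance(key, str):
            entropy.append(zlib.crc32(key.encode("utf-8")))
        else:
            entropy.append(int(key) & 0xFFFFFFFF)
    return np.random.SeedSequence(entropy)


def child_rng(seed: int, *keys: "int | str") -> np.random.Generator:
    """A ``numpy`` Generator seeded for the stage identified by ``keys``."""
    return np.random.default_rng(child_seed_sequence(seed, *keys))
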
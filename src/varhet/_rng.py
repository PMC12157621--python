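"""Seed-substream plumbing.

One root seed governs a whole analysis; every operation and every Monte-Carlo
replicate draws from its own deterministic substream, keyed by a path of
labels.  Adding replicates (or extra sample sizes to a power grid) therefore
never perturbs results already computed under the same root seed.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "child_seed"]


def _key_to_int(key) -> int:
    if isinstance(key, (bool,)):
        raise TypeError("boolean substream keys are ambiguous")
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    digest = hashlib.sha256(str(key).encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little")


def substream(seed: int, *path) -> np.random.Generator:
    """Return an independent generator for ``(seed, *path)``.

    ``path`` elements may be ints or strings; strings are hashed to 32-bit
    keys.  The same (seed, path) always yields the same stream.
    """
    ss = np.random.SeedSequence(
        entropy=int(seed), spawn_key=tuple(_key_to_int(k) for k in path)
    )
    return np.random.default_rng(ss)


def child_seed(seed: int, *path) -> int:
    """A derived integer seed (< 2**31) for APIs that take a plain seed."""
    return int(substream(seed, *path).integers(0, 2**31 - 1))
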
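"""Deterministic seed derivation.

Every stochastic component takes a seed derived from one root seed and a
tuple of string tags, so a whole pipeline run is reproducible from a single
integer and no two stages share a stream.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_seed", "rng"]


def child_seed(root: int, *tags: object) -> int:
    """Derive a sub-seed (< 2**31) from ``root`` and a tag path."""
    h = hashlib.sha256()
    h.update(str(int(root)).encode())
    for tag in tags:
        h.update(b"/")
        h.update(str(tag).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


def rng(root: int, *tags: object) -> np.random.Generator:
    """A numpy Generator seeded from :func:`child_seed`."""
    return np.random.default_rng(child_seed(root, *tags))
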
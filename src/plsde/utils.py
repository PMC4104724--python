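"""Small shared helpers."""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np

#: keep derived seeds strictly below 2**31 so they fit any RNG API
_SEED_MOD = 2**31


def derive_seed(base: int, *path: int) -> int:
    """Derive a child seed deterministically from a base seed and an index path.

    Uses :class:`numpy.random.SeedSequence` so that distinct paths give
    statistically independent streams and the same path always gives the
    same child seed, on every platform.
    """
    ss = np.random.SeedSequence([int(base) % _SEED_MOD, *[int(p) for p in path]])
    return int(ss.generate_state(1)[0]) % _SEED_MOD


def sha256_of(path: str | Path) -> str:
    """Hex SHA-256 digest of a file's bytes."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
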
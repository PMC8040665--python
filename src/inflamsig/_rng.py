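"""Deterministic random-stream derivation.

Every stage derives its generator from a master seed plus a stable string
key (stage name, feature id, ...), so adding a stage or reordering features
never perturbs another stream.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed", "derive_rng"]


def derive_seed(master_seed: int, *keys: object) -> int:
    """Derive a child seed (< 2**31) from a master seed and string keys.

    Uses SHA-256 of ``"seed|key1|key2|..."`` so the mapping is stable across
    runs, platforms and Python hash randomization.
    """
    payload = "|".join([str(int(master_seed)), *map(str, keys)])
    digest = hashlib.sha256(payload.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def derive_rng(master_seed: int, *keys: object) -> np.random.Generator:
    """A ``numpy.random.Generator`` seeded from :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(master_seed, *keys))
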
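"""Deterministic seed derivation.

Every stage of the pipeline draws its randomness from a seed derived by
hashing ``(master_seed, stage_name, *indices)``, so independent stages get
independent, reproducible streams and the whole experiment is a pure
function of the master seed.
"""

from __future__ import annotations

import hashlib

import numpy as np

_MOD = 2**31 - 1


def derive_seed(master_seed: int, *tokens: object) -> int:
    """Hash a master seed and context tokens into a seed below 2**31."""
    h = hashlib.sha256()
    h.update(str(int(master_seed)).encode())
    for t in tokens:
        h.update(b"\x1f")
        h.update(str(t).encode())
    return int.from_bytes(h.digest()[:8], "big") % _MOD


def rng_for(master_seed: int, *tokens: object) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master_seed, *tokens))
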
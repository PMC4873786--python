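"""Deterministic seed derivation: stage seeds are hashes of the master seed.

Deriving per-stage (and per-replicate) seeds from a single master seed by
hashing avoids correlated random streams between stages while keeping the
whole run reproducible from one integer.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(master: int, name: str, index: int = 0) -> int:
    """31-bit seed deterministically derived from (master, name, index)."""
    h = hashlib.blake2b(f"{master}:{name}:{index}".encode(), digest_size=4).digest()
    return int.from_bytes(h, "big") % (2**31)
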
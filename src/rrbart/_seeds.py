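"""Deterministic seed derivation.

Every stochastic stage receives a child seed derived by hashing the master
seed together with a stage label (and optional indices), so adding a new
stage or method never shifts the random stream of an existing one.
"""

from __future__ import annotations

import hashlib


def child_seed(master: int, *keys) -> int:
    """Derive a child seed < 2**31 from a master seed and a key path."""
    h = hashlib.sha256()
    h.update(str(int(master)).encode())
    for k in keys:
        h.update(b"/")
        h.update(str(k).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31 - 1)
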
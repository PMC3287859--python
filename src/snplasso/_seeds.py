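"""Deterministic derivation of stage seeds from a master seed.

Each stochastic stage gets ``derive_seed(master, stage, key)`` — a stable
hash of the master seed, the stage name, and an optional per-replicate
key — so reproducibility holds stage by stage, independent of execution
order.  Values stay below 2**31.
"""

from __future__ import annotations

import hashlib


def derive_seed(master: int, stage: str, key: str | int | None = None) -> int:
    token = f"{master}:{stage}:{key}".encode()
    digest = hashlib.sha256(token).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)
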
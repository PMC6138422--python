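"""Deterministic child-seed derivation.

Child seeds are derived by hashing the master seed together with a
descriptive name, so results are invariant to execution order and worker
count: deleting one grid run never changes the seeds of the others.
"""

from __future__ import annotations

import hashlib


def child_seed(master: int, name: str) -> int:
    """A reproducible 31-bit seed derived from (master seed, name)."""
    h = hashlib.sha256(f"{int(master)}|{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)
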
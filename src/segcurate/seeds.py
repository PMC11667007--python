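"""Deterministic sub-seed derivation.

Every run takes a single master seed; every internal source of randomness
(per-case phantom noise, corruption sampling, weight initialisation,
re-initialisation after curation, fold repeats) draws its own seed with
:func:`derive_seed` so that runs are pure functions of (config, master seed)
and sub-streams are independent of each other.
"""

from __future__ import annotations

import hashlib


def derive_seed(master: int, *purpose: object) -> int:
    """Derive a stable 31-bit seed from a master seed and a purpose tag."""
    tag = ":".join(str(p) for p in (master, *purpose))
    digest = hashlib.sha256(tag.encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31 - 1)
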
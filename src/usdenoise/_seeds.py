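"""Stable seed derivation.

Python's builtin ``hash`` is salted per process, so reproducible pipelines
derive per-item seeds from a cryptographic digest of the identifying tuple
instead.  Seeds are kept below 2**31 so they are valid for every RNG API
we touch.
"""

from __future__ import annotations

import hashlib

_MOD = 2**31


def stable_seed(*parts: object) -> int:
    """Derive a deterministic seed in ``[0, 2**31)`` from a tuple of parts.

    Parts are rendered with ``repr`` and joined with an unambiguous
    separator, so ``stable_seed(1, "ab")`` differs from ``stable_seed(1, "a", "b")``.
    """
    payload = "\x1f".join(repr(p) for p in parts).encode("utf-8")
    digest = hashlib.sha256(payload).digest()
    return int.from_bytes(digest[:8], "big") % _MOD
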
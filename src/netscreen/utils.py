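"""Small shared helpers."""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(seed: int, label: str) -> int:
    """Fan a global seed out into a stage-specific seed, reproducibly.

    Uses SHA-256 of ``"{seed}:{label}"`` reduced below 2**31, so each
    pipeline stage gets an independent stream that is a pure function of
    the global seed and the stage name.
    """
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)
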
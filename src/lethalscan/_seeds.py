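"""Deterministic seed derivation.

Every stage of the pipeline draws randomness from a child seed derived from a
single root seed and a stage name, so stages are independently rerunnable and
the full run is reproducible bit-for-bit.
"""

from __future__ import annotations

import hashlib


def child_seed(root_seed: int, name: str) -> int:
    """Derive a stable 31-bit child seed from a root seed and a stream name."""
    digest = hashlib.sha256(f"{int(root_seed)}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
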
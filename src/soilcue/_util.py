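"""Shared helpers: seed derivation and reason-coded missing values."""

from __future__ import annotations

import hashlib


def derive_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from a master seed and a stage name.

    Stages draw from independent streams so that adding or reordering one
    stage never perturbs another. The result is always in [0, 2**31).
    """
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def join_reasons(*reasons: str) -> str:
    """Combine non-empty reason codes into a single ';'-separated flag string."""
    return ";".join(r for r in reasons if r)
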
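"""Reproducibility helpers."""

from __future__ import annotations

import hashlib
import json


def derive_seed(master: int, tag: str) -> int:
    """Deterministically fan a master seed out to per-component seeds."""
    digest = hashlib.sha256(f"{master}:{tag}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
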
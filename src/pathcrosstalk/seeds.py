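"""Stable seed derivation for reproducible, stage-independent randomness.

Child seeds are a deterministic hash of the master seed plus arbitrary
string/int context parts (stage name, repeat index, ...), so every stage
and repeat draws from an independent stream while the whole run remains
a pure function of the master seed.
"""

from __future__ import annotations

import hashlib
import logging

logger = logging.getLogger(__name__)


def derive_seed(master_seed: int, *parts) -> int:
    """Derive a child seed (< 2**31) from a master seed and context parts."""
    token = ":".join([str(int(master_seed)), *map(str, parts)])
    digest = hashlib.sha256(token.encode()).digest()
    child = int.from_bytes(digest[:4], "big") % (2**31)
    logger.debug("seed %s -> %d", token, child)
    return child
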
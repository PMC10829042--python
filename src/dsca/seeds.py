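"""Deterministic seed derivation shared by all modules.

Every stage derives its own sub-seed by stable hashing of the global
seed and a name path, so stages are independently reproducible and
insensitive to Python's per-process string-hash randomisation.
"""

from __future__ import annotations

import hashlib


def derive_seed(seed: int, *names: str | int) -> int:
    """Stable sub-seed from (seed, *names); always in [0, 2^31)."""
    h = hashlib.sha256(("/".join(str(n) for n in (seed, *names))).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)
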
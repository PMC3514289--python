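"""Deterministic seed derivation for independent RNG substreams.

A single pipeline master seed fans out into per-stage / per-test
substreams keyed by strings (e.g. ``("permtest", "age", "COE")``), so
adding or reordering stages never perturbs the draws of another stage.
"""

from __future__ import annotations

import hashlib

_MOD = 2**31


def derive_seed(master: int, *keys: object) -> int:
    """Derive a reproducible child seed < 2**31 from a master seed and keys."""
    token = "|".join([str(int(master)), *map(str, keys)])
    digest = hashlib.sha256(token.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big") % _MOD
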
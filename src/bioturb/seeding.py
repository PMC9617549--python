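"""Deterministic child seeds.

One global seed fans out to per-stage / per-species / per-replicate child seeds
by stable string hashing, so adding a species or an algorithm never perturbs the
random streams of the others.  Children stay below 2**31.
"""

from __future__ import annotations

import zlib


def child_seed(global_seed: int, *tags) -> int:
    """Stable child seed from a global seed and a sequence of string-able tags."""
    key = "|".join([str(int(global_seed))] + [str(t) for t in tags])
    return zlib.crc32(key.encode("utf-8")) & 0x7FFFFFFF
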
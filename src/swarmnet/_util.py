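"""Deterministic seed derivation shared by all stochastic stages."""

from __future__ import annotations

from zlib import crc32

import numpy as np

_MASK31 = 0x7FFFFFFF


def derive_seeds(*keys: int | str, n: int = 2) -> list[int]:
    """Derive ``n`` independent 31-bit seeds from a tuple of keys.

    String keys (gene symbols) are hashed with CRC32 so seeding is keyed to
    gene identity, not to row position — results are then invariant to input
    file row order.  Built on :class:`numpy.random.SeedSequence` so derived
    streams are statistically independent.
    """
    ints = []
    for k in keys:
        if isinstance(k, str):
            ints.append(crc32(k.encode("utf-8")))
        else:
            k = int(k)
            if k < 0:
                raise ValueError(f"seed keys must be non-negative, got {k}")
            ints.append(k)
    ss = np.random.SeedSequence(ints)
    return [int(s) & _MASK31 for s in ss.generate_state(n, dtype=np.uint32)]
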
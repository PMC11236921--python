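"""Small shared helpers."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed"]


def derive_seed(base: int, label: str, index: int = 0) -> int:
    """Stable sub-seed below 2**31 derived from a base seed and a label.

    Uses crc32 for the label so the derivation is identical across
    processes (the builtin ``hash`` is salted per interpreter run).
    """
    h = np.random.SeedSequence(
        [int(base), zlib.crc32(label.encode()) % (2**31), int(index)]
    )
    return int(h.generate_state(1)[0] % (2**31))
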
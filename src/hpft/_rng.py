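"""Named substreams derived from one root seed.

Every source of randomness in the package (feature budgeting, RANSAC,
synthetic noise, scene layout) draws from ``substream(root_seed, name)`` so
that a single root seed reproduces a whole run byte-for-byte while distinct
stages stay statistically independent.
"""

from __future__ import annotations

import zlib

__all__ = ["substream"]


def substream(seed: int, name: str) -> int:
    """A deterministic child seed (< 2**31) for the stage called ``name``."""
    return (int(seed) * 2654435761 + zlib.crc32(name.encode())) % (2**31 - 1)
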
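"""Seed handling.

Every stochastic routine in the package draws from a ``numpy`` Generator
obtained through :func:`stream`, which derives an independent child stream
from a single user-supplied integer seed and a short purpose label. The
scheme is the documented one: ``SeedSequence(seed, spawn_key=hash(label))``
via ``SeedSequence.spawn`` ordering is avoided in favour of explicit keys so
that adding a new consumer never perturbs existing streams.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream"]


def stream(seed: int, label: str, index: int = 0) -> np.random.Generator:
    """Return the deterministic random stream for (seed, label, index).

    Parameters
    ----------
    seed : int
        Top-level seed supplied by the user (or CLI ``--seed``).
    label : str
        Purpose of the stream, e.g. ``"t2w-noise"``. Hashed with CRC32 so
        the mapping is stable across sessions and platforms.
    index : int
        Optional extra key for per-item streams (tumor index, replicate).
    """
    key = zlib.crc32(label.encode("utf-8"))
    ss = np.random.SeedSequence([int(seed) % (2**31), key, int(index)])
    return np.random.default_rng(ss)
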
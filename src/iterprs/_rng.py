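"""Seed management: one master seed fanning out into named substreams.

Every stochastic stage derives its generator from the master seed plus a
stable textual key (and optional integer indices), so that a full pipeline
run is exactly reproducible and individual stages can be re-run in isolation
with identical randomness.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key_entropy(name: str) -> int:
    # crc32 is stable across platforms and Python versions
    return zlib.crc32(name.encode("utf-8"))


def substream(seed: int, name: str, *indices: int) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    Parameters
    ----------
    seed : master integer seed.
    name : stable stream label, e.g. ``"genotypes"`` or ``"split"``.
    indices : optional integer coordinates (e.g. iteration number).
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    ss = np.random.SeedSequence(
        entropy=int(seed), spawn_key=(_key_entropy(name), *map(int, indices))
    )
    return np.random.default_rng(ss)
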
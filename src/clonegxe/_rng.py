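"""Deterministic per-component random streams.

All randomness in the package flows from a single integer seed.  Each
logical component (e.g. the population effects of one trait, the residuals
of one site) gets its own independent stream derived from the seed and a
tuple of string/int keys, so enlarging one part of a simulation (adding a
site, adding a trait) never perturbs draws made for another part.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["component_rng"]


def _key_entropy(keys: tuple) -> list[int]:
    h = hashlib.blake2b(repr(keys).encode("utf-8"), digest_size=16).digest()
    return [int.from_bytes(h[i : i + 4], "little") for i in range(0, 16, 4)]


def component_rng(seed: int, *keys) -> np.random.Generator:
    """Return a Generator for component ``keys`` under master ``seed``.

    The stream depends only on (seed, keys): stable across sessions and
    platforms, and independent of the order in which components are drawn.
    """
    ss = np.random.SeedSequence(entropy=[int(seed)] + _key_entropy(tuple(keys)))
    return np.random.default_rng(ss)
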
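"""Seeded randomness.

All stochastic stages draw from named substreams of a single root seed, so
each stage is individually reproducible and stages do not perturb each
other's streams when one is re-run in isolation.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def _name_key(name: str) -> int:
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big")


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The same (seed, name) pair always yields an identical stream; distinct
    names yield statistically independent streams.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), _name_key(name)]))


def substream_seed(seed: int, name: str) -> int:
    """A small (< 2**31) integer seed derived from (seed, name).

    For libraries that take a plain integer seed rather than a Generator.
    """
    ss = np.random.SeedSequence([int(seed), _name_key(name)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
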
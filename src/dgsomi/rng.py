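"""Seed management.

Every stochastic stage of the pipeline draws from a named child stream derived
from a single session seed, so stages are reproducible independently of each
other and of execution order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["child_rng", "child_seed"]


def _name_key(name: str) -> list[int]:
    # Stable, platform-independent mapping from a stream name to entropy words.
    return list(name.encode("utf-8"))


def child_rng(seed: int, name: str) -> np.random.Generator:
    """Return the generator for the named child stream of ``seed``.

    The same (seed, name) pair always yields the same stream; distinct names
    yield statistically independent streams.
    """
    seq = np.random.SeedSequence([int(seed)] + _name_key(name))
    return np.random.default_rng(seq)


def child_seed(seed: int, name: str) -> int:
    """A scalar sub-seed (< 2**31) for APIs that take an integer seed."""
    seq = np.random.SeedSequence([int(seed)] + _name_key(name))
    return int(seq.generate_state(1, dtype=np.uint32)[0] % (2**31))
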
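"""Deterministic seed derivation.

A single root seed is split into named, independent random streams so that
any one stage of the pipeline (fold assignment, test-set draw, transfer
draw, model initialisation, data generation) can be varied in isolation
without perturbing the others.
"""

from __future__ import annotations

import numpy as np

# Stable stream identifiers; order must never change once released.
STREAMS = {
    "generate": 0,
    "folds": 1,
    "test": 2,
    "transfer": 3,
    "model": 4,
    "sweep": 5,
}


def spawn_rng(root_seed: int, stream: str, *keys: int) -> np.random.Generator:
    """Return a Generator for ``stream`` derived from ``root_seed``.

    Extra integer ``keys`` (fold index, cell index, ...) further qualify the
    stream. The same (seed, stream, keys) always yields the same stream.
    """
    if stream not in STREAMS:
        raise KeyError(f"unknown random stream {stream!r}")
    entropy = [int(root_seed), STREAMS[stream], *[int(k) for k in keys]]
    return np.random.default_rng(np.random.SeedSequence(entropy))
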
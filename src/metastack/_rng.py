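"""Named pseudo-random streams.

One master integer seed fans out to independent, reproducible streams, one
per pipeline stage (generation, missingness, imputation copy, bootstrap
plan, learner fit, ...).  Stage names are hashed with CRC32 so a stream
depends only on the master seed and its own name, never on execution order.
"""

from __future__ import annotations

import zlib

import numpy as np

MAX_SKLEARN_SEED = 2**31 - 1


def _keys(master: int, names: tuple) -> list[int]:
    return [int(master)] + [zlib.crc32(str(n).encode()) for n in names]


def stream(master: int, *names) -> np.random.Generator:
    """Return the named child generator of ``master``."""
    return np.random.default_rng(np.random.SeedSequence(_keys(master, names)))


def stream_seed(master: int, *names) -> int:
    """Integer seed (< 2^31) for libraries that take one, e.g. scikit-learn."""
    seq = np.random.SeedSequence(_keys(master, names))
    return int(seq.generate_state(1)[0] % MAX_SKLEARN_SEED)
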
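"""Named child RNG streams.

One global seed enters the pipeline; every stochastic stage draws from a
child stream derived from (seed, stage name) so that stages are
independently reproducible and reordering one does not perturb another.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_seed(seed: int, name: str) -> int:
    """Deterministic 31-bit child seed for a named stream."""
    return int(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])
        .generate_state(1)[0]
        % (2**31)
    )


def child_rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, name))
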
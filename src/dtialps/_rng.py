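"""Named random substreams derived from a single top-level seed."""

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    Each (seed, name) pair maps to an independent, reproducible stream, so
    pipeline stages (phantom geometry, acquisition noise, cohort draws) can be
    re-run in isolation without replaying earlier stages.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))
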
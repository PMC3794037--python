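"""Seed-splitting rule shared by every stochastic stage.

All randomness in the package flows from one integer seed.  Each stage
(road generation, tree placement, nest thinning, coverage assignment,
survey detection draws, replicate loop) draws from its own substream so
that stages are independently reproducible: changing the tree process
cannot perturb the detection draws.

The rule: the substream for stage ``name`` is seeded with
``SeedSequence(seed, spawn_key=(crc32(name),))``.  The CRC is stable
across platforms and Python versions, so a (seed, stage-name) pair
always denotes the same stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def substream(seed: int, stage: str) -> np.random.Generator:
    """Return the dedicated random generator for one named stage."""
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def substream_seed(seed: int, stage: str) -> int:
    """A derived integer seed (< 2**31) for the named stage.

    Used where a plain integer must be passed on to another seeded
    operation (e.g. one seed per replicate of an experiment).
    """
    key = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence(seed, spawn_key=(key,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
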
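"""Deterministic per-stage random substreams.

One user-facing integer seed drives the whole pipeline; each stage draws from
its own substream keyed by a stable hash of the stage name, so re-running a
single stage reproduces its stream regardless of which other stages ran.
"""

from __future__ import annotations

import zlib

import numpy as np


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Return a Generator for *stage* derived deterministically from *seed*.

    The stage name is folded in through CRC32, so the substream depends only
    on (seed, stage) and is stable across sessions and platforms.
    """
    key = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))
    return np.random.default_rng(ss)
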
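"""Seed-derivation scheme.

All randomness in a simulation flows from one root seed. Each (replicate,
purpose) pair gets its own independent stream via a ``SeedSequence`` spawn
key, so toggling an unrelated option (output format, remove_QTN, ...) never
perturbs the draws of another stream, and partial reruns reproduce exactly.
"""

from __future__ import annotations

import numpy as np

#: stream tags; the integer is part of the spawn key and must never change
STREAMS = {
    "qtn": 0,      # QTN / linking-marker selection
    "noise": 1,    # non-genetic error draws
    "fixture": 2,  # synthetic genotype panel generation
}


def derive_rng(root_seed: int, replicate: int = 0, stream: str = "qtn") -> np.random.Generator:
    """Return the dedicated random generator for one (replicate, purpose) pair."""
    if stream not in STREAMS:
        raise ValueError(f"unknown random stream {stream!r}; known: {sorted(STREAMS)}")
    ss = np.random.SeedSequence(root_seed, spawn_key=(replicate, STREAMS[stream]))
    return np.random.default_rng(ss)


def spawn_key(replicate: int, stream: str) -> tuple[int, int]:
    """The spawn key used for a stream (persisted to the seeds file)."""
    return (replicate, STREAMS[stream])
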
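"""Named random-stream derivation.

Every source of randomness in the package flows from a single master seed via
named streams, so that stages are reproducible independently of execution
order.  Derived integer seeds stay below 2**31.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "stream"]


def _token(name: object) -> int:
    return zlib.crc32(str(name).encode("utf-8"))


def child_seed(master_seed: int, *names: object) -> int:
    """Derive a deterministic integer seed (< 2**31) for a named stream."""
    ss = np.random.SeedSequence([int(master_seed)] + [_token(n) for n in names])
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31))


def stream(master_seed: int, *names: object) -> np.random.Generator:
    """A Generator for the named stream derived from ``master_seed``."""
    ss = np.random.SeedSequence([int(master_seed)] + [_token(n) for n in names])
    return np.random.default_rng(ss)
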
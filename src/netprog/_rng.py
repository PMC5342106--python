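"""Named random substreams derived from a single master seed.

Every randomized stage of the pipeline draws from an independent stream so
that adding draws to one stage never perturbs another, and the whole run is
bit-reproducible from the master seed alone.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named stage, derived from ``seed``.

    The stream key is ``(seed, crc32(name))`` fed to a SeedSequence, so the
    mapping is stable across sessions and platforms.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
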
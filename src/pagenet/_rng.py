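"""Named random substreams derived from a single global seed.

Each stage of the synthetic generator draws from its own named stream so
that adding or reordering a stage never perturbs the draws of another.
"""

import hashlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator deterministically keyed by (seed, name)."""
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    key = int.from_bytes(digest[:4], "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), key]))
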
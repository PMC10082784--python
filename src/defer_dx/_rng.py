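"""Named substreams derived from a single master seed.

Every stochastic stage (cohort, ratings, scores, audit, bootstrap) draws
from its own named substream so that stages are independently reproducible:
regenerating AI scores does not perturb the reader panel, and vice versa.
"""

import hashlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator keyed by (master seed, stream name).

    The stream name is hashed into a SeedSequence spawn key, so distinct
    names yield statistically independent streams for the same master seed.
    """
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    key = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))
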
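"""Deterministic seed derivation.

Every stochastic stage (generation, sampling, weight init, minibatch order,
bootstrap, subset draws) gets its own child seed derived from one master seed
plus a stream path of small integers, so whole experiments are reproducible
and independent stages never share a stream.
"""

from __future__ import annotations

import numpy as np

# stream-path tags; purely namespacing, values are arbitrary but frozen
GENERATOR, SAMPLING, TRAINING, BOOTSTRAP, SUBSETS, EXPERIMENT = range(6)


def derive_seed(master_seed: int, *path: int) -> int:
    """Child seed (< 2**31) for the stream identified by ``path``."""
    ss = np.random.SeedSequence([int(master_seed), *map(int, path)])
    return int(ss.generate_state(1)[0] % (2**31))
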
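"""Named RNG substreams derived from one global seed.

All randomness in the package flows from a single integer seed. Each stage
draws from its own substream, derived as ``SeedSequence([seed, index])``
with a fixed stage->index table, so regenerating one stage never perturbs
another and runs are reproducible across platforms (NumPy Generator
guarantees).
"""

from __future__ import annotations

import numpy as np

_STREAMS = {
    "expression": 0,
    "interactome": 1,
    "gene_sets": 2,
    "sam_permutations": 3,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Return the named substream's Generator for a global seed."""
    if name not in _STREAMS:
        raise KeyError(f"unknown RNG substream {name!r}; known: {sorted(_STREAMS)}")
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[name]]))
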
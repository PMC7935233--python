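"""Named random sub-streams derived from one master seed.

Every stochastic stage of the pipeline draws from its own generator, keyed by
(master seed, stage name, round index), so any stage can be reproduced in
isolation and adding a stage never perturbs the draws of another.
"""

from __future__ import annotations

import numpy as np

_STREAMS = {
    "assignment": 0,
    "sign_split": 1,
    "stability_pre": 2,
    "finalize": 3,
    "stability_post": 4,
    "generic": 5,
    "genotypes": 6,
    "outcomes": 7,
}


def stream_rng(master_seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Generator for sub-stream ``name`` (round ``index``) of ``master_seed``."""
    try:
        stream_id = _STREAMS[name]
    except KeyError:
        raise KeyError(f"unknown seed stream {name!r}; known: {sorted(_STREAMS)}") from None
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), stream_id, int(index)]))
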
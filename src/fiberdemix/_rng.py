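"""Named random substreams derived from a single top-level seed.

Every stochastic stage (traces, camera noise, speckle texture, scattering
layer) draws from its own substream so that changing, say, the noise seed
never perturbs the ground-truth traces.
"""

from __future__ import annotations

import numpy as np

# Fixed stream ids; never reorder — they are part of the reproducibility
# contract of saved run configs.
_STREAMS = {
    "traces": 11,
    "noise": 23,
    "texture": 37,
    "layer": 41,
    "positions": 53,
    "misc": 67,
}


def substream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    ``index`` distinguishes per-source streams within one name.
    """
    try:
        sid = _STREAMS[name]
    except KeyError:  # pragma: no cover - programming error
        raise KeyError(f"unknown substream {name!r}; known: {sorted(_STREAMS)}")
    return np.random.default_rng(np.random.SeedSequence([int(seed), sid, int(index)]))
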
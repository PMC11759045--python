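"""Seed fan-out.

A single root seed is expanded into named per-stage child seeds through
``numpy.random.SeedSequence`` so every pipeline stage is independently
reproducible: re-running one stage with the same root seed always sees the
same stream regardless of what other stages consumed.
"""

from __future__ import annotations

import numpy as np

# Fixed, documented stage keys.  The integer key of a stage is derived from
# the stable hash of its name so adding a stage never shifts the others.
_STAGE_KEYS = {
    "phylogeny": 11,
    "traits": 13,
    "communities": 17,
    "spectral_library": 19,
    "cubes": 23,
    "ses_null": 29,
    "cluster": 31,
    "mcmc": 37,
    "pcd": 41,
    "split": 43,
    "imputation": 47,
}


def child_seed(root_seed: int, stage: str) -> int:
    """Return a deterministic 31-bit child seed for a named stage."""
    if stage not in _STAGE_KEYS:
        raise KeyError(f"unknown seed stage {stage!r}; known: {sorted(_STAGE_KEYS)}")
    ss = np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF, _STAGE_KEYS[stage]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def rng_for(root_seed: int, stage: str) -> np.random.Generator:
    """Generator seeded with the child seed of *stage*."""
    return np.random.default_rng(child_seed(root_seed, stage))
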
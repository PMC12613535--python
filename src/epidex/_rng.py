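"""Seed-stream management.

A single master seed drives every stochastic component.  Each component gets
its own child stream derived from the master ``SeedSequence`` through a fixed
integer key, so adding a new component (or re-ordering calls inside one) never
perturbs the draws of an existing one.
"""

from __future__ import annotations

import numpy as np

# Fixed component keys.  Append only; never renumber.
STREAM_KEYS = {
    "allocation": 0,
    "covariates": 1,
    "sites": 2,
    "outcome": 3,
    "events": 4,
    "missingness": 5,
    "deviations": 6,
    "followup": 7,
    "screening": 8,
    "mcmc": 9,
    "design": 10,
    "oc": 11,
    "surveys": 12,
    "safety": 13,
}


def child_rng(seed: int, component: str, extra: int = 0) -> np.random.Generator:
    """Return the generator for ``component`` under master ``seed``.

    ``extra`` distinguishes repeated uses inside one component (e.g. replicate
    indices in a simulation loop).
    """
    key = STREAM_KEYS[component]
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key, extra)))


def child_seed(seed: int, component: str, extra: int = 0) -> int:
    """A plain integer seed (< 2**31) derived from the component stream."""
    return int(child_rng(seed, component, extra).integers(0, 2**31 - 1))
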
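import numpy as np
import pandas as pd
import pytest

import callspace as cs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def clean_call():
    """A noiseless 0.15 s constant-contour call at 3 kHz, 19 kHz rate."""
    proto = cs.CallPrototype([3000.0, 3000.0], 0.15, amplitude=0.8, harmonics=1)
    return cs.synthesize_call(proto, 19000, noise_level=0.0, seed=0)


@pytest.fixture(scope="session")
def flock_profiles():
    gen = np.random.default_rng(7)
    return [
        cs.make_profile(f"B{i}", "young", gen, drift_rate=0.0,
                        convergence_rate=0.3, call_rate=20.0)
        for i in range(4)
    ]


@pytest.fixture(scope="session")
def mini_trait_space():
    """One simulated flock run through features + joint embedding.

    Returns (coords, meta) for metric-level tests: 4 birds x 5 blocks x 20
    calls, converging contours.
    """
    gen = np.random.default_rng(11)
    profiles = [
        cs.make_profile(f"B{i}", "young", gen, drift_rate=5.0,
                        convergence_rate=0.3)
        for i in range(4)
    ]
    sim = cs.simulate_flock_calls(profiles, blocks=5, calls_per_block=20,
                                  sample_rate=19000, noise_level=0.02, seed=3)
    rows = [cs.extract_features(w, 19000) for w in sim.waveforms]
    meta = sim.calls[["individual", "age_class", "block"]].copy()
    meta["flock"] = "F1"
    table = cs.feature_table(rows, meta)
    scaled = cs.scale_features(table)
    emb = cs.embed(scaled[cs.FEATURE_NAMES], perplexity=25, iterations=500,
                   seed=9)
    return emb.coords, table[["individual", "flock", "age_class", "block"]]
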
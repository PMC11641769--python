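import numpy as np
import pytest

from s1domains import profile_scan, synthetic_data


@pytest.fixture(scope="session")
def family():
    """A small generated S1-like family: root, conservation, seed alignment, profile."""
    rng = np.random.default_rng(7)
    ancestor = synthetic_data.random_sequence(80, rng)
    conservation = np.zeros(80)
    conservation[rng.choice(80, size=24, replace=False)] = 1.0
    seed = [
        synthetic_data.mutate_sequence(ancestor, 0.1, conservation, rng)
        for _ in range(8)
    ]
    profile = profile_scan.build_profile(seed)
    return {
        "ancestor": ancestor,
        "conservation": conservation,
        "seed": seed,
        "profile": profile,
        "rng_seed": 7,
    }


@pytest.fixture(scope="session")
def endosym_truth():
    """One endosymbiosis family (transfer from position 3), generated once."""
    from s1domains import benchmark

    spec = benchmark.endosymbiosis_spec(seed=42)
    return synthetic_data.generate_family(spec)
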
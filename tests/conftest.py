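import numpy as np
import pytest
from hypothesis import settings

from msmhdx import synthetic as syn

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def simulate_chain(T, n, seed, start=0):
    """Plain reference simulator for discrete Markov chains (test oracle)."""
    rng = np.random.default_rng(seed)
    cum = np.cumsum(np.asarray(T, dtype=float), axis=1)
    seq = np.empty(n, dtype=np.int64)
    seq[0] = start
    u = rng.random(n)
    for t in range(1, n):
        seq[t] = np.searchsorted(cum[seq[t - 1]], u[t], side="right")
    return seq


@pytest.fixture(scope="session")
def three_state():
    """Moderate three-metastable-state ensemble with ground truth."""
    spec = syn.benchmark_three_state()
    ensemble, truth = syn.generate_ensemble(spec, n_traj=5, n_frames=8000, seed=42)
    return spec, ensemble, truth


@pytest.fixture(scope="session")
def protection_bench():
    """Two-state protected/exposed hydrogen-bond benchmark ensemble."""
    spec = syn.benchmark_protection()
    ensemble, truth = syn.generate_ensemble(spec, n_traj=4, n_frames=4000, seed=5)
    return spec, ensemble, truth
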
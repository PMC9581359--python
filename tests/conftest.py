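import numpy as np
import pytest
from hypothesis import settings

import stochid as st

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")


def straight_tube_spec(L=1000.0, sigma_eps=2.0, sigma_eta=2.0, n=20, seed=0,
                       m_samples=200, **kw):
    """Straight-line task with constant (possibly anisotropic) in-plane noise:
    the simplest geometry with closed-form expectations everywhere."""
    def profile(u):
        u = np.asarray(u, dtype=float)
        return np.full_like(u, sigma_eps), np.full_like(u, sigma_eta)

    return st.GeneratorSpec(
        waypoints=np.array([[0.0, 0.0, 0.0], [L, 0.0, 0.0]]),
        lift=0.0, n=n, seed=seed, m_samples=m_samples,
        sigma_profile=profile, **kw)


@pytest.fixture
def straight_trials():
    """Three parallel straight trials along x, offset in y."""
    t = np.linspace(0.0, 1.0, 11)
    x = np.linspace(0.0, 10.0, 11)

    def make(off, tid):
        pts = np.column_stack([x, np.full_like(x, off), np.zeros_like(x)])
        return st.Trajectory(tid, t, pts)

    return st.TrialEnsemble("s1", "c1", [make(-1.0, "a"), make(1.0, "b"), make(0.0, "c")])


@pytest.fixture
def default_ensemble():
    spec = st.GeneratorSpec(seed=42)
    path = st.make_mean_path(spec)
    return spec, path, st.simulate_trials(path, spec)
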
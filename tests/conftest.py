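import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import refstab as rs

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_ct(rng, n_genes=5, n_samples=12, groups=("a", "b"), noise=0.5):
    """A random but valid CtMatrix: baselines + shared sample shifts + noise."""
    baselines = rng.uniform(16, 28, size=n_genes)
    shifts = rng.normal(0, 0.5, size=n_samples)
    vals = baselines[:, None] + shifts[None, :] + rng.normal(0, noise, size=(n_genes, n_samples))
    labels = [groups[i % len(groups)] for i in range(n_samples)]
    return rs.from_arrays(
        vals,
        [f"g{i}" for i in range(n_genes)],
        [{"sample_id": f"s{j}", "group": labels[j]} for j in range(n_samples)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20200914)


@pytest.fixture
def small_ct():
    """The 3-gene hand-example matrix: g3 has one swapped sample."""
    return rs.from_arrays(
        [[20, 21, 22], [20, 21, 22], [20, 22, 21]],
        ["g1", "g2", "g3"],
        [{"sample_id": f"s{i}", "group": "a"} for i in range(3)],
    )


@pytest.fixture
def trauma_ct():
    """One draw from the fracture-design preset (planted Actb shift)."""
    return rs.generate(rs.preset("paper_d3_bone", seed=7))
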
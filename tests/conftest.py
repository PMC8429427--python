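import numpy as np
import pytest

import fcbrainage as f


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_z_matrix(rng: np.random.Generator, n: int, scale: float = 0.15) -> np.ndarray:
    m = rng.normal(0, scale, (n, n))
    z = (m + m.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return z


def make_connectivity(rng, n=20, subject_id="sub-x", residualized=True):
    z = random_z_matrix(rng, n)
    return f.ConnectivityMatrix(
        subject_id=subject_id,
        z=z,
        region_labels=[f"R{i:03d}" for i in range(n)],
        n_frames_used=150,
        mr_residualized=residualized,
    )


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small on-disk cohort shared by pipeline-level tests."""
    out = tmp_path_factory.mktemp("cohort")
    spec = f.CohortSpec(
        n_subjects_per_group=(100, 12),
        T_frames=120,
        site_labels=("siteA", "siteA", "siteA", "siteB"),
        seed=99,
    )
    f.generate_cohort(spec, out, overwrite=True)
    return out, spec
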
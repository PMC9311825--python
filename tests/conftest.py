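import numpy as np
import pytest
from sklearn.cluster import KMeans

from segtbm.synthetic import SyntheticSpec, generate_cohort

# synthetic Jacobians routinely dip below 0 with strong factors; the cohort
# container warns about it by design
pytestmark = pytest.mark.filterwarnings("ignore:Jacobian values")


def pytest_collection_modifyitems(items):
    for item in items:
        item.add_marker(pytest.mark.filterwarnings("ignore:Jacobian values"))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_group_cohort():
    """Small cohort with 2 planted blocks, no group effects."""
    spec = SyntheticSpec(
        grid_shape=(6, 6, 4),
        levels_planted=2,
        factor_sd=1.0,
        noise_sd=0.1,
        n_per_group={"C9orf72:non-carrier": 25, "C9orf72:asymptomatic": 25},
        seed=7,
    )
    return generate_cohort(spec)


def two_block_matrix(n_subjects=60, n_voxels=200, factor_sd=1.0, noise_sd=0.1, seed=0):
    """Plain subjects x voxels matrix with two strongly separated voxel blocks.

    Returns (data, true_labels).
    """
    rng = np.random.default_rng(seed)
    half = n_voxels // 2
    data = np.ones((n_subjects, n_voxels))
    for block, sl in enumerate((slice(0, half), slice(half, n_voxels))):
        f = rng.normal(0, factor_sd, n_subjects)
        loadings = rng.uniform(0.5, 1.0, sl.stop - sl.start)
        data[:, sl] += np.outer(f, loadings)
    data += rng.normal(0, noise_sd, data.shape)
    labels = np.repeat([0, 1], [half, n_voxels - half])
    return data, labels


def dense_spectral_oracle(data, cols=None, k=2, n_init=50, seed=0):
    """Independent reference pipeline: dense Pearson affinity, normalized
    Laplacian by definition, full eigendecomposition, single k-means with many
    restarts.  Deliberately avoids the package's code paths."""
    if cols is None:
        cols = np.arange(data.shape[1])
    X = data[:, cols]
    corr = np.corrcoef(X, rowvar=False)
    A = 0.5 * (corr + 1.0)
    d = A.sum(axis=0)
    L = A / np.sqrt(np.outer(d, d))
    vals, vecs = np.linalg.eigh(L)
    top = vecs[:, np.argsort(vals)[::-1][:k]]
    top = top / np.maximum(np.linalg.norm(top, axis=1, keepdims=True), 1e-30)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(top)
    return km.labels_, top, np.sort(vals)[::-1][:k]
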
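"""Per-segment size and shape features.

Size is the mean Jacobian over a segment's voxels.  Shape is the
size-normalized within-segment pattern (each subject's values divided by that
subject's segmental size), summarized by principal components; the number of
retained components is chosen by parallel analysis against a column-permutation
null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._utils import _as_matrix
from .errors import DataError

__all__ = [
    "SizeFeature",
    "ShapeFeature",
    "segmental_size",
    "size_normalized_residuals",
    "shape_space",
    "parallel_analysis",
    "compute_tree_features",
]

_SV_TOL = 1e-12


@dataclass
class SizeFeature:
    segment_id: int
    values: np.ndarray  # one mean Jacobian per subject

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise DataError("non-finite size values")


@dataclass
class ShapeFeature:
    segment_id: int
    scores: np.ndarray            # n_subjects x k_retained
    loadings: np.ndarray          # k_retained x n_segment_voxels, rows orthonormal
    explained_variance: np.ndarray
    k_retained: int

    def truncate(self, k: int) -> "ShapeFeature":
        k = int(min(k, self.scores.shape[1]))
        return ShapeFeature(
            self.segment_id,
            self.scores[:, :k],
            self.loadings[:k],
            self.explained_variance[:k],
            k,
        )


def _segment_columns(cohort, segment):
    data = _as_matrix(cohort)
    voxels = getattr(segment, "voxels", segment)
    voxels = np.asarray(voxels, dtype=np.intp)
    if voxels.size == 0:
        raise ValueError("segment is empty")
    return data, voxels


def segmental_size(cohort, segment, segment_id: int = -1) -> SizeFeature:
    """Average Jacobian across all voxels within a segment, per subject."""
    data, voxels = _segment_columns(cohort, segment)
    sid = getattr(segment, "id", segment_id)
    return SizeFeature(sid, data[:, voxels].mean(axis=1))


def size_normalized_residuals(cohort, segment) -> np.ndarray:
    """Divide each subject's segment values by that subject's segmental size.

    Every row of the result has mean exactly 1.
    """
    data, voxels = _segment_columns(cohort, segment)
    block = data[:, voxels]
    size = block.mean(axis=1)
    zero = np.flatnonzero(size == 0)
    if zero.size:
        raise ZeroDivisionError(
            f"zero segmental size for subject row(s) {zero.tolist()} "
            f"in segment {getattr(segment, 'id', '?')}"
        )
    return block / size[:, None]


def shape_space(residuals: np.ndarray, segment_id: int = -1) -> ShapeFeature:
    """PCA (via SVD) of the column-centered residuals.

    Scores are left singular vectors scaled by singular values, so
    ``scores @ loadings`` reconstructs the centered residuals at full rank.
    Components with numerically zero singular values are dropped.
    """
    residuals = np.asarray(residuals, dtype=float)
    n = residuals.shape[0]
    if n < 3:
        raise ValueError("shape_space requires at least 3 subjects")
    centered = residuals - residuals.mean(axis=0)
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    keep = S > max(S[0], 1.0) * max(centered.shape) * np.finfo(float).eps
    if S.size == 0 or not keep.any():
        k = 0
        return ShapeFeature(
            segment_id,
            np.zeros((n, 0)),
            np.zeros((0, residuals.shape[1])),
            np.zeros(0),
            0,
        )
    k = int(keep.sum())
    scores = U[:, :k] * S[:k]
    return ShapeFeature(segment_id, scores, Vt[:k], S[:k] ** 2 / (n - 1), k)


def parallel_analysis(
    residuals: np.ndarray,
    n_null: int = 100,
    percentile: float = 95.0,
    seed=None,
) -> int:
    """Number of principal components whose eigenvalues beat a permutation null.

    Each null dataset permutes every (centered) column independently across
    subjects.  Component ``j`` is retained iff its eigenvalue exceeds the
    ``percentile`` percentile of the null's ``j``-th eigenvalue; retention
    stops at the first failure.
    """
    residuals = np.asarray(residuals, dtype=float)
    rng = np.random.default_rng(seed)
    centered = residuals - residuals.mean(axis=0)
    n, m = centered.shape
    observed = np.linalg.svd(centered, compute_uv=False) ** 2
    k_max = observed.size
    null = np.zeros((n_null, k_max))
    col = np.arange(m)
    for r in range(n_null):
        # independent permutation of each column across subjects; permuting a
        # centered column keeps its mean at zero
        perm_rows = np.argsort(rng.random((n, m)), axis=0)
        perm = centered[perm_rows, col]
        sv = np.linalg.svd(perm, compute_uv=False) ** 2
        null[r, : sv.size] = sv[:k_max]
    cutoffs = np.percentile(null, percentile, axis=0)
    k = 0
    for j in range(k_max):
        if observed[j] > cutoffs[j] and observed[j] > _SV_TOL:
            k += 1
        else:
            break
    return k


def compute_tree_features(
    cohort,
    tree,
    n_null: int = 100,
    percentile: float = 95.0,
    seed=None,
):
    """Size and retained-shape features for every node of a segment tree.

    Returns ``{node_id: (SizeFeature, ShapeFeature)}``; shape features are
    truncated to the parallel-analysis retention count (possibly 0 components).
    """
    rng = np.random.default_rng(seed)
    out = {}
    for node_id in sorted(tree.nodes):
        node = tree.nodes[node_id]
        size = segmental_size(cohort, node)
        residuals = size_normalized_residuals(cohort, node)
        shape = shape_space(residuals, node.id)
        k = parallel_analysis(residuals, n_null=n_null, percentile=percentile, seed=rng)
        out[node_id] = (size, shape.truncate(k))
    return out
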
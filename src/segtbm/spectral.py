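"""Population-level spectral segmentation of voxels into a binary hierarchy.

The affinity between two voxels is ``0.5 * (corr + 1)`` where ``corr`` is the
Pearson correlation of their value vectors across subjects.  Voxels are
embedded with the top-2 eigenvectors of the normalized Laplacian
``D^{-1/2} A D^{-1/2}`` (estimated by averaged Nyström runs on random landmark
subsets) and bipartitioned by consensus k-means.  Recursing on each side
yields the global-to-local segment tree.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh, orthogonal_procrustes
from sklearn.cluster import KMeans

from ._utils import _as_matrix
from .errors import DegenerateVoxelError, SplitFailureError

__all__ = [
    "SpectralConfig",
    "SpectralEmbedding",
    "SegmentNode",
    "SegmentTree",
    "pairwise_affinity",
    "affinity_matrix",
    "normalized_laplacian",
    "nystrom_embedding",
    "average_nystrom",
    "consensus_kmeans",
    "split_segment",
    "build_hierarchy",
]

logger = logging.getLogger(__name__)

_EIG_TOL = 1e-10


@dataclass(frozen=True)
class SpectralConfig:
    """Tuning knobs for the segmentation.

    ``n_landmarks`` per segment defaults to ``max(ceil(landmark_frac * n),
    min_landmarks)`` capped at the segment size; with all voxels as landmarks
    the Nyström estimate equals the dense eigendecomposition.
    """

    landmark_frac: float = 0.1
    min_landmarks: int = 100
    nystrom_reps: int = 50
    kmeans_reps: int = 50
    k: int = 2
    min_segment_voxels: int = 32
    row_normalize: bool = True

    def landmarks_for(self, n_voxels: int) -> int:
        m = max(int(np.ceil(self.landmark_frac * n_voxels)), self.min_landmarks)
        return min(m, n_voxels)


@dataclass
class SpectralEmbedding:
    """Top-k normalized-Laplacian eigenvector coordinates of a voxel subset."""

    coordinates: np.ndarray  # (n_subset, k)
    eigenvalues: np.ndarray  # (k,), descending

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite embedding coordinates")


# ---------------------------------------------------------------------------
# tree container


@dataclass
class SegmentNode:
    id: int
    level: int
    parent: int | None
    children: tuple
    voxels: np.ndarray  # column positions into the cohort matrix

    @property
    def is_leaf(self) -> bool:
        return len(self.children) == 0


@dataclass
class SegmentTree:
    """Binary hierarchy of voxel segments; node ids are assigned in BFS order."""

    nodes: dict = field(default_factory=dict)
    depth: int = 0

    @property
    def root(self) -> SegmentNode:
        return self.nodes[1]

    @property
    def n_segments(self) -> int:
        return len(self.nodes)

    def at_level(self, level: int) -> list:
        return [n for n in self.nodes.values() if n.level == level]

    @property
    def is_complete(self) -> bool:
        return self.n_segments == 2 ** self.depth - 1

    def labels_at_level(self, level: int, n_voxels: int) -> np.ndarray:
        """Node id covering each voxel at ``level`` (early-stopped leaves keep
        their own id at deeper levels)."""
        labels = np.zeros(n_voxels, dtype=np.int64)
        for node in self.nodes.values():
            if node.level == level or (node.level < level and node.is_leaf):
                labels[node.voxels] = node.id
        return labels

    def to_json(self, path=None) -> str:
        payload = {
            "depth": self.depth,
            "nodes": [
                {
                    "id": n.id,
                    "level": n.level,
                    "parent": n.parent,
                    "children": list(n.children),
                    "voxel_indices": n.voxels.tolist(),
                }
                for n in sorted(self.nodes.values(), key=lambda n: n.id)
            ],
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SegmentTree":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        tree = cls(depth=payload["depth"])
        for nd in payload["nodes"]:
            tree.nodes[nd["id"]] = SegmentNode(
                id=nd["id"],
                level=nd["level"],
                parent=nd["parent"],
                children=tuple(nd["children"]),
                voxels=np.asarray(nd["voxel_indices"], dtype=np.intp),
            )
        tree.validate()
        return tree

    def validate(self) -> None:
        root = self.root
        if root.level != 1 or root.parent is not None:
            raise ValueError("malformed root node")
        for node in self.nodes.values():
            if node.children:
                if len(node.children) != 2:
                    raise ValueError(f"node {node.id} has {len(node.children)} children")
                kids = [self.nodes[c] for c in node.children]
                merged = np.sort(np.concatenate([k.voxels for k in kids]))
                if kids[0].voxels.size == 0 or kids[1].voxels.size == 0:
                    raise ValueError(f"node {node.id} has an empty child")
                if not np.array_equal(merged, np.sort(node.voxels)):
                    raise ValueError(f"children of node {node.id} do not partition it")


# ---------------------------------------------------------------------------
# affinity and Laplacian


def _standardize(data: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Z-score the selected columns across subjects (population std)."""
    X = data[:, cols]
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegenerateVoxelError(
            f"zero-variance voxel column(s) at subset positions {bad[:10].tolist()}"
        )
    return (X - mu) / sd


def pairwise_affinity(cohort, i: int, j: int) -> float:
    """Affinity ``0.5 * (corr(J_i, J_j) + 1)`` between two voxel columns."""
    data = _as_matrix(cohort)
    if i == j:
        # exact by definition (corr = 1)
        _standardize(data, np.asarray([i]))
        return 1.0
    Z = _standardize(data, np.asarray([i, j]))
    corr = float(Z[:, 0] @ Z[:, 1] / Z.shape[0])
    return 0.5 * (np.clip(corr, -1.0, 1.0) + 1.0)


def affinity_matrix(cohort, cols=None) -> np.ndarray:
    """Dense affinity over a voxel subset (small subsets / oracle checks)."""
    data = _as_matrix(cohort)
    if cols is None:
        cols = np.arange(data.shape[1])
    Z = _standardize(data, np.asarray(cols, dtype=np.intp))
    corr = np.clip(Z.T @ Z / Z.shape[0], -1.0, 1.0)
    A = 0.5 * (corr + 1.0)
    np.fill_diagonal(A, 1.0)
    return A


def normalized_laplacian(A: np.ndarray):
    """``L = D^{-1/2} A D^{-1/2}`` with ``d_ii`` the i-th column sum of A."""
    A = np.asarray(A, dtype=float)
    if not np.allclose(A, A.T):
        raise ValueError("affinity matrix must be symmetric")
    d = A.sum(axis=0)
    if np.any(d <= 0):
        raise ValueError("zero column sum in affinity matrix")
    inv_sqrt = 1.0 / np.sqrt(d)
    L = A * np.outer(inv_sqrt, inv_sqrt)
    return L, d


def _psd_inv_sqrt(W: np.ndarray):
    """Pseudo-inverse square root of a (near-)PSD matrix; warns if singular."""
    vals, vecs = eigh((W + W.T) / 2.0)
    tol = max(vals[-1], 0.0) * len(vals) * np.finfo(float).eps
    keep = vals > max(tol, _EIG_TOL)
    if keep.sum() < len(vals):
        warnings.warn(
            "rank-deficient landmark block; using pseudo-inverse", stacklevel=3
        )
    inv = np.zeros_like(vals)
    inv[keep] = 1.0 / np.sqrt(vals[keep])
    return (vecs * inv) @ vecs.T


def nystrom_embedding(cohort, voxel_subset, n_landmarks: int, k: int = 2, seed=None) -> SpectralEmbedding:
    """Estimate the top-k eigenvectors of the subset's normalized Laplacian
    from a random landmark column subset of the affinity matrix.

    With ``n_landmarks == len(voxel_subset)`` the estimate coincides with the
    dense eigendecomposition (up to sign) because the affinity is positive
    semi-definite.
    """
    data = _as_matrix(cohort)
    subset = np.asarray(voxel_subset, dtype=np.intp)
    rng = np.random.default_rng(seed)
    Z = _standardize(data, subset)
    return _nystrom_from_z(Z, n_landmarks, k, rng)


def _nystrom_from_z(Z: np.ndarray, n_landmarks: int, k: int, rng) -> SpectralEmbedding:
    s, n = Z.shape
    if not 2 <= n_landmarks <= n:
        raise ValueError("n_landmarks must be in [2, n_subset]")
    if k > n_landmarks:
        raise ValueError("k must not exceed n_landmarks")
    lm = np.sort(rng.choice(n, size=n_landmarks, replace=False))
    # n x m slice of the affinity matrix, via correlation against landmarks
    C = 0.5 * (np.clip(Z.T @ Z[:, lm] / s, -1.0, 1.0) + 1.0)
    C[lm, np.arange(n_landmarks)] = 1.0
    W = C[lm, :]
    W_inv_sqrt = _psd_inv_sqrt(W)
    W_pinv = W_inv_sqrt @ W_inv_sqrt
    # approximate degrees: d = A_hat @ 1 with A_hat = C W^+ C^T
    d = C @ (W_pinv @ (C.sum(axis=0)))
    d = np.maximum(d, _EIG_TOL)
    Ct = C / np.sqrt(d)[:, None]
    # eigenproblem of L_hat = Ct W^+ Ct^T reduced to the m x m matrix
    G = Ct.T @ Ct
    M = W_inv_sqrt @ G @ W_inv_sqrt
    vals, vecs = eigh((M + M.T) / 2.0)
    order = np.argsort(vals)[::-1][:k]
    top_vals = vals[order]
    pos = np.maximum(top_vals, _EIG_TOL)
    U = Ct @ (W_inv_sqrt @ (vecs[:, order] / np.sqrt(pos)))
    # columns of U are unit-norm eigenvector estimates of L_hat
    return SpectralEmbedding(U, top_vals)


def _align(ref: np.ndarray, est: np.ndarray) -> np.ndarray:
    """Sign-flip each component toward ``ref``, then orthogonal Procrustes."""
    est = est.copy()
    for j in range(est.shape[1]):
        if est[:, j] @ ref[:, j] < 0:
            est[:, j] = -est[:, j]
    R, _ = orthogonal_procrustes(est, ref)
    return est @ R


def average_nystrom(
    cohort,
    voxel_subset,
    n_landmarks: int,
    k: int = 2,
    n_estimations: int = 50,
    seed=None,
) -> SpectralEmbedding:
    """Average ``n_estimations`` Nyström runs on independent landmark draws.

    Each estimation is aligned to the first (per-component sign flip, then
    orthogonal Procrustes) before element-wise averaging, since raw
    eigenvectors carry arbitrary sign/rotation.
    """
    data = _as_matrix(cohort)
    subset = np.asarray(voxel_subset, dtype=np.intp)
    rng = np.random.default_rng(seed)
    Z = _standardize(data, subset)
    first = _nystrom_from_z(Z, n_landmarks, k, rng)
    acc = first.coordinates.copy()
    vals = first.eigenvalues.copy()
    for _ in range(n_estimations - 1):
        est = _nystrom_from_z(Z, n_landmarks, k, rng)
        acc += _align(first.coordinates, est.coordinates)
        vals += est.eigenvalues
    return SpectralEmbedding(acc / n_estimations, vals / n_estimations)


# ---------------------------------------------------------------------------
# consensus clustering


def consensus_kmeans(embedding, k: int = 2, n_repeats: int = 50, seed=None) -> np.ndarray:
    """Merge repeated k-means runs into one bipartition by normalized voting.

    Each repeat's labels are matched to the first valid repeat by maximal
    overlap; every voxel's vote is weighted by the inverse size of its voting
    cluster, and the final label is the vote majority (ties toward label 0).
    """
    if k != 2:
        raise ValueError("only binary splits (k=2) are supported")
    coords = embedding.coordinates if hasattr(embedding, "coordinates") else np.asarray(embedding)
    n = coords.shape[0]
    rng = np.random.default_rng(seed)
    votes = np.zeros((n, 2))
    reference = None
    n_valid = 0
    for _ in range(n_repeats):
        km = KMeans(
            n_clusters=2,
            n_init=1,
            random_state=int(rng.integers(0, 2**31 - 1)),
        ).fit(coords)
        labels = km.labels_.astype(np.intp)
        sizes = np.bincount(labels, minlength=2)
        if sizes.min() == 0:
            continue  # degenerate repeat, discarded
        if reference is None:
            reference = labels
        elif np.sum(labels == reference) < n / 2:
            labels = 1 - labels
            sizes = sizes[::-1]
        votes[np.arange(n), labels] += 1.0 / sizes[labels]
        n_valid += 1
    if n_valid == 0:
        raise SplitFailureError("all k-means repeats produced an empty cluster")
    final = (votes[:, 1] > votes[:, 0]).astype(np.intp)
    if final.min() == final.max():
        raise SplitFailureError("consensus vote produced a single cluster")
    return final


# ---------------------------------------------------------------------------
# recursive splitting


def _fallback_split(coords_or_order: np.ndarray, n: int) -> np.ndarray:
    """Deterministic split: threshold the 2nd eigenvector at its median."""
    order = np.argsort(coords_or_order, kind="stable")
    labels = np.zeros(n, dtype=np.intp)
    labels[order[n // 2:]] = 1
    return labels


def split_segment(cohort, voxel_subset, config: SpectralConfig = None, seed=None):
    """Bipartition a voxel subset; affinity is recomputed from scratch on the
    subset's columns.  Returns two disjoint, nonempty index arrays whose union
    is the subset (order: the side containing the lowest voxel index first).
    """
    if config is None:
        config = SpectralConfig()
    data = _as_matrix(cohort)
    subset = np.asarray(voxel_subset, dtype=np.intp)
    n = subset.size
    if n < 2:
        raise ValueError("cannot split a segment with fewer than 2 voxels")
    if n == 2:
        return subset[:1], subset[1:]

    sd = data[:, subset].std(axis=0)
    good = np.flatnonzero(sd > 0)
    degenerate = np.flatnonzero(sd == 0)
    if good.size < 2:
        labels = _fallback_split(np.arange(n), n)
        return subset[labels == 0], subset[labels == 1]

    active = subset[good]
    rng = np.random.default_rng(seed)
    m = config.landmarks_for(active.size)
    embedding = average_nystrom(
        data,
        active,
        n_landmarks=m,
        k=config.k,
        n_estimations=config.nystrom_reps,
        seed=rng,
    )
    coords = embedding.coordinates
    if config.row_normalize:
        norms = np.linalg.norm(coords, axis=1, keepdims=True)
        coords = np.where(norms > 0, coords / np.maximum(norms, 1e-30), coords)
    try:
        labels_active = consensus_kmeans(
            SpectralEmbedding(coords, embedding.eigenvalues),
            k=config.k,
            n_repeats=config.kmeans_reps,
            seed=rng,
        )
    except SplitFailureError:
        logger.warning("consensus split failed on %d voxels; median fallback", n)
        labels_active = _fallback_split(embedding.coordinates[:, 1], active.size)

    labels = np.empty(n, dtype=np.intp)
    labels[good] = labels_active
    if degenerate.size:
        # zero-variance voxels join the cluster of their spatially nearest
        # informative voxel (correlation is undefined for them)
        labels[degenerate] = _assign_degenerate(cohort, subset, good, degenerate, labels_active)

    if labels[0] == 1:
        labels = 1 - labels
    left, right = subset[labels == 0], subset[labels == 1]
    if left.size == 0 or right.size == 0:
        raise SplitFailureError("split produced an empty side")
    return left, right


def _assign_degenerate(cohort, subset, good, degenerate, labels_active):
    mask = getattr(cohort, "mask", None)
    if mask is not None:
        coords = mask.coordinates()
        good_xyz = coords[subset[good]]
        out = np.empty(degenerate.size, dtype=np.intp)
        for i, pos in enumerate(degenerate):
            d2 = ((good_xyz - coords[subset[pos]]) ** 2).sum(axis=1)
            out[i] = labels_active[np.argmin(d2)]
        return out
    # no geometry available: nearest informative column position
    nearest = np.searchsorted(good, degenerate).clip(0, good.size - 1)
    return labels_active[nearest]


def build_hierarchy(cohort, levels: int = 8, config: SpectralConfig = None, seed: int = 0) -> SegmentTree:
    """Recursively split the full voxel set into a binary tree of ``levels``
    levels.  Nodes smaller than ``config.min_segment_voxels`` become early
    leaves (logged).  The result is a pure function of (cohort, config, seed).
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if config is None:
        config = SpectralConfig()
    data = _as_matrix(cohort)
    n_voxels = data.shape[1]
    tree = SegmentTree(depth=levels)
    root = SegmentNode(1, 1, None, (), np.arange(n_voxels, dtype=np.intp))
    tree.nodes[1] = root
    frontier = [root]
    next_id = 2
    for level in range(1, levels):
        new_frontier = []
        for node in frontier:
            if node.voxels.size < max(config.min_segment_voxels, 2):
                logger.info(
                    "node %d (%d voxels) below min size at level %d; early leaf",
                    node.id, node.voxels.size, level,
                )
                continue
            # per-node seed stream: reproducible regardless of traversal order
            left, right = split_segment(
                cohort, node.voxels, config, seed=np.random.default_rng([seed, node.id])
            )
            kids = []
            for vox in (left, right):
                child = SegmentNode(next_id, level + 1, node.id, (), vox)
                tree.nodes[next_id] = child
                kids.append(child)
                next_id += 1
            node.children = (kids[0].id, kids[1].id)
            new_frontier.extend(kids)
        frontier = new_frontier
    tree.validate()
    return tree
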
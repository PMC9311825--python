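"""Thresholded significance maps, weighted Jacobians, Dice overlap and
dendrogram export."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from ._utils import _as_matrix
from .errors import NotComputableError

__all__ = [
    "ThresholdedMap",
    "thresholded_map",
    "weighted_jacobian",
    "phenotype_anova",
    "dice_between",
    "dendrogram_export",
    "plot_dendrogram",
]


@dataclass
class ThresholdedMap:
    """Per-level binary maps of significant segments and their voxel-wise sum.

    ``per_level`` is a (depth, n_voxels) boolean array; ``summed`` counts, per
    voxel, the number of levels at which it lies inside a significant segment
    (0..depth).
    """

    per_level: np.ndarray
    feature: str
    contrast: str

    def __post_init__(self):
        self.per_level = np.asarray(self.per_level, dtype=bool)

    @property
    def depth(self) -> int:
        return self.per_level.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.per_level.shape[1]

    @property
    def summed(self) -> np.ndarray:
        return self.per_level.sum(axis=0).astype(np.int32)

    @property
    def concatenated(self) -> np.ndarray:
        """Level-concatenated binary vector (length depth * n_voxels)."""
        return self.per_level.reshape(-1)


def thresholded_map(results, tree, contrast: str, feature: str) -> ThresholdedMap:
    """Mark, per level, the voxels inside any FDR-significant segment."""
    n_voxels = tree.root.voxels.size
    per_level = np.zeros((tree.depth, n_voxels), dtype=bool)
    frame = results.frame
    hits = frame[
        (frame["contrast"] == contrast)
        & (frame["feature"] == feature)
        & frame["significant"]
    ]
    for node_id in hits["segment_id"]:
        node = tree.nodes[int(node_id)]
        per_level[node.level - 1, node.voxels] = True
    return ThresholdedMap(per_level, feature, contrast)


def weighted_jacobian(cohort, tmap: ThresholdedMap) -> np.ndarray:
    """Per-subject average Jacobian weighted by the summed threshold map."""
    data = _as_matrix(cohort)
    w = tmap.summed.astype(float)
    total = w.sum()
    if total == 0:
        raise NotComputableError("all-zero weights: no significant segments")
    return data @ w / total


def phenotype_anova(values: np.ndarray, phenotypes) -> tuple:
    """One-way fixed-effects ANOVA of per-subject values across phenotypes."""
    from scipy.stats import f_oneway

    values = np.asarray(values, dtype=float)
    labels = np.asarray(phenotypes)
    groups = [values[labels == lvl] for lvl in np.unique(labels)]
    groups = [g for g in groups if g.size >= 2]
    if len(groups) < 2:
        raise NotComputableError("need at least 2 phenotype groups with >= 2 subjects")
    F, p = f_oneway(*groups)
    return float(F), float(p)


def dice_between(map_x: ThresholdedMap, map_y: ThresholdedMap) -> float:
    """Dice overlap of the level-concatenated binary maps.

    Returns NaN when both maps are empty (the coefficient is undefined).
    """
    if map_x.per_level.shape != map_y.per_level.shape:
        raise ValueError("maps must share mask and depth")
    x = map_x.concatenated
    y = map_y.concatenated
    denom = int(x.sum()) + int(y.sum())
    if denom == 0:
        return math.nan
    return 2.0 * int(np.logical_and(x, y).sum()) / denom


def dendrogram_export(tree, results, contrast: str, feature: str, path=None) -> dict:
    """Dendrogram-ready node table (level, parent, -log10 p, significance).

    Only significant nodes are flagged for display; insignificant p-values are
    still exported for completeness.
    """
    frame = results.frame
    sub = frame[(frame["contrast"] == contrast) & (frame["feature"] == feature)]
    by_id = {int(r.segment_id): r for r in sub.itertuples()}
    nodes = []
    for node_id in sorted(tree.nodes):
        node = tree.nodes[node_id]
        row = by_id.get(node_id)
        nodes.append(
            {
                "id": node.id,
                "level": node.level,
                "parent": node.parent,
                "n_voxels": int(node.voxels.size),
                "neg_log10_p": (None if row is None else float(row.neg_log10_p)),
                "significant": (False if row is None else bool(row.significant)),
            }
        )
    payload = {
        "contrast": contrast,
        "feature": feature,
        "alpha": results.alpha,
        "fdr_threshold": results.fdr_threshold,
        "nodes": nodes,
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    return payload


def plot_dendrogram(payload: dict, ax=None):
    """Minimal circular dendrogram of the exported node table.

    Marks significant nodes; not a faithful reproduction of any publication
    figure.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    nodes = {n["id"]: n for n in payload["nodes"]}
    # angular position: leaves spread evenly, parents at the mean of children
    depth = max(n["level"] for n in nodes.values())
    theta = {}
    per_level = {}
    for n in sorted(nodes.values(), key=lambda n: (n["level"], n["id"])):
        per_level.setdefault(n["level"], []).append(n["id"])
    leaf_ids = per_level[depth]
    for i, nid in enumerate(leaf_ids):
        theta[nid] = 2 * np.pi * i / max(len(leaf_ids), 1)
    for level in range(depth - 1, 0, -1):
        for nid in per_level.get(level, []):
            kids = [c for c in nodes if nodes[c]["parent"] == nid]
            theta[nid] = (
                np.mean([theta[c] for c in kids]) if kids else 2 * np.pi * nid / len(nodes)
            )
    for nid, n in nodes.items():
        r = n["level"]
        if n["parent"] is not None:
            ax.plot([theta[n["parent"]], theta[nid]], [r - 1, r], color="0.7", lw=0.8)
        color = "crimson" if n["significant"] else "0.4"
        size = 24 if n["significant"] else 6
        ax.scatter([theta[nid]], [r], s=size, c=color, zorder=3)
    ax.set_rticks(range(1, depth + 1))
    ax.set_xticks([])
    ax.set_title(f"{payload['contrast']} / {payload['feature']}")
    return ax
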
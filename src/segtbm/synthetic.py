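"""Synthetic Jacobian cohorts with a planted binary voxel hierarchy.

A cohort is built as::

    J(s, v) = 1 + f(s, block(v)) * loading(v)          # block latent factor
                + size_effect[group(s), block]          # mean shift (size)
                + shape_effect[group(s), block] * p(v)  # zero-mean pattern (shape)
                + covariate terms + N(0, noise_sd)

Leaf blocks are contiguous runs of mask columns nested into a binary tree, so
the planted ground truth is itself a :class:`~segtbm.spectral.SegmentTree`.
Shape effects use patterns with exactly zero mean over the block's voxels, so
they move the within-block pattern without moving segmental size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .spectral import SegmentNode, SegmentTree
from .volume_io import JacobianCohort, VoxelMask

__all__ = [
    "SyntheticSpec",
    "generate_cohort",
    "plant_group_size_effect",
    "planted_tree",
    "group_mask",
    "PHENOTYPES",
]

PHENOTYPES = ("bvFTD", "PPA", "ALS")


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic cohort.

    ``n_per_group`` maps ``"<mutation>:<status>"`` keys (e.g.
    ``"C9orf72:asymptomatic"``) to subject counts.  Effects are keyed by
    ``(group_key, block_node_id)`` where node ids refer to the planted tree
    (1 = root, leaves at level ``levels_planted``).
    """

    grid_shape: tuple = (10, 10, 10)
    levels_planted: int = 3
    n_per_group: dict = field(
        default_factory=lambda: {"C9orf72:non-carrier": 30, "C9orf72:asymptomatic": 30}
    )
    factor_sd: float = 1.0
    hierarchical_factors: bool = False
    loading_range: tuple = (0.5, 1.0)
    group_size_effect: dict = field(default_factory=dict)
    group_shape_effect: dict = field(default_factory=dict)
    age_slope: float = 0.0
    sex_slope: float = 0.0
    site_slope: float = 0.0
    noise_sd: float = 0.1
    n_sites: int = 2
    n_families: int = 10
    seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(x) for x in self.grid_shape)
        self.loading_range = tuple(float(x) for x in self.loading_range)
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.levels_planted < 1:
            raise ValueError("levels_planted must be >= 1")
        for n in self.n_per_group.values():
            if n < 2:
                raise ValueError("n_per_group entries must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("group_size_effect", "group_shape_effect"):
            if key in raw and raw[key]:
                raw[key] = {
                    (k.split("@")[0], int(k.split("@")[1])): v
                    for k, v in raw[key].items()
                }
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["grid_shape"] = list(self.grid_shape)
        raw["loading_range"] = list(self.loading_range)
        for key in ("group_size_effect", "group_shape_effect"):
            raw[key] = {f"{g}@{b}": float(v) for (g, b), v in raw[key].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh)


def planted_tree(n_voxels: int, levels: int) -> SegmentTree:
    """Binary hierarchy over column positions by recursive contiguous halving."""
    if n_voxels < 2 ** (levels - 1):
        raise ValueError("too few voxels for the requested planted depth")
    tree = SegmentTree(depth=levels)
    root = SegmentNode(1, 1, None, (), np.arange(n_voxels, dtype=np.intp))
    tree.nodes[1] = root
    frontier = [root]
    next_id = 2
    for _ in range(1, levels):
        new_frontier = []
        for node in frontier:
            half = node.voxels.size // 2
            parts = (node.voxels[:half], node.voxels[half:])
            kids = []
            for vox in parts:
                child = SegmentNode(next_id, node.level + 1, node.id, (), vox)
                tree.nodes[next_id] = child
                kids.append(child)
                next_id += 1
            node.children = (kids[0].id, kids[1].id)
            new_frontier.extend(kids)
        frontier = new_frontier
    tree.validate()
    return tree


def _make_table(spec: SyntheticSpec, rng) -> pd.DataFrame:
    rows = []
    sid = 0
    for key in sorted(spec.n_per_group):
        mutation, status = key.split(":")
        for _ in range(spec.n_per_group[key]):
            rows.append(
                {
                    "subject_id": f"sub-{sid:04d}",
                    "mutation": mutation,
                    "status": status,
                    "phenotype": (
                        PHENOTYPES[rng.integers(0, len(PHENOTYPES))]
                        if status == "symptomatic"
                        else ""
                    ),
                    "age": float(rng.uniform(20, 80)),
                    "sex": int(rng.integers(0, 2)),
                    "site": int(sid % spec.n_sites),
                    "family": int(sid % spec.n_families),
                    "group": key,
                }
            )
            sid += 1
    return pd.DataFrame(rows)


def group_mask(table: pd.DataFrame, group: str) -> np.ndarray:
    """Boolean subject mask for a ``"<mutation>:<status>"`` group key."""
    mutation, status = group.split(":")
    sel = (table["mutation"] == mutation) & (table["status"] == status)
    if not sel.any():
        raise KeyError(f"group {group!r} not present in cohort table")
    return sel.to_numpy()


def generate_cohort(spec: SyntheticSpec):
    """Generate ``(JacobianCohort, cohort table, ground-truth SegmentTree)``.

    Identical specs (including seed) produce bitwise-identical outputs.
    """
    # independent child streams so that toggling one ingredient (e.g. a shape
    # effect) does not perturb the draws of the others
    rng = np.random.default_rng([spec.seed, 0])
    rng_factors = np.random.default_rng([spec.seed, 1])
    rng_effects = np.random.default_rng([spec.seed, 2])
    rng_noise = np.random.default_rng([spec.seed, 3])
    mask_arr = np.ones(spec.grid_shape, dtype=bool)
    mask = VoxelMask.from_array(mask_arr, np.eye(4))
    n_voxels = mask.n_voxels
    tree = planted_tree(n_voxels, spec.levels_planted)
    table = _make_table(spec, rng)
    n_subjects = len(table)

    data = np.ones((n_subjects, n_voxels))

    # block latent factors with positive loadings: within-block correlation.
    # In hierarchical mode every non-root node carries its own factor, so
    # voxels sharing a deeper ancestry are more correlated; splits then track
    # the planted tree at every level.
    lo, hi = spec.loading_range
    if spec.hierarchical_factors:
        factor_nodes = [n for n in tree.nodes.values() if n.level > 1]
    else:
        factor_nodes = tree.at_level(spec.levels_planted)
    for node in sorted(factor_nodes, key=lambda n: n.id):
        loadings = rng_factors.uniform(lo, hi, size=node.voxels.size)
        factors = rng_factors.normal(0.0, spec.factor_sd, size=n_subjects)
        data[:, node.voxels] += np.outer(factors, loadings)

    # group mean shifts (size effects)
    for (group, block_id), delta in sorted(spec.group_size_effect.items()):
        sel = group_mask(table, group)
        data[np.ix_(sel, tree.nodes[block_id].voxels)] += delta

    # group pattern shifts (shape effects): exactly zero-mean over the block
    for (group, block_id), strength in sorted(spec.group_shape_effect.items()):
        vox = tree.nodes[block_id].voxels
        pattern = rng_effects.normal(size=vox.size)
        pattern -= pattern.mean()
        pattern /= np.sqrt(np.mean(pattern**2))
        sel = group_mask(table, group)
        data[np.ix_(sel, vox)] += strength * pattern

    # covariate confounds, uniform across voxels
    age = table["age"].to_numpy()
    sex = table["sex"].to_numpy(dtype=float)
    site = table["site"].to_numpy(dtype=float)
    conf = (
        spec.age_slope * (age - 50.0) / 30.0
        + spec.sex_slope * (sex - 0.5)
        + spec.site_slope * (site - site.mean())
    )
    data += conf[:, None]

    data += rng_noise.normal(0.0, spec.noise_sd, size=data.shape)

    cohort = JacobianCohort(data, mask, table["subject_id"].tolist())
    return cohort, table, tree


def plant_group_size_effect(cohort, table, block, group: str, delta: float) -> JacobianCohort:
    """Return a copy of the cohort with ``delta`` added to one group's rows on
    the given block's columns; all other entries untouched."""
    block = np.asarray(block, dtype=np.intp)
    if block.size and (block.min() < 0 or block.max() >= cohort.n_voxels):
        raise ValueError("block contains invalid voxel indices")
    sel = group_mask(table, group)
    data = cohort.data.copy()
    data[np.ix_(sel, block)] += delta
    return JacobianCohort(data, cohort.mask, list(cohort.subject_ids))


def write_cohort(cohort, table, tree, out_dir) -> None:
    """Write volumes, mask, cohort CSV and ground-truth tree JSON to a directory."""
    from .volume_io import save_cohort_volumes
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_cohort_volumes(cohort, out_dir / "volumes")
    nib.save(cohort.mask.to_nifti(), str(out_dir / "mask.nii.gz"))
    table.to_csv(out_dir / "cohort.csv", index=False)
    tree.to_json(out_dir / "ground_truth_tree.json")
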
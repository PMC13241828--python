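"""Synthetic cortical parcellations on mirrored unit hemispheres.

A parcellation places an even number of nodes on two mirror-symmetric unit
hemispheres (the geometry the spin-permutation null requires), groups them
into spatially contiguous modules (functional networks), and assigns each
node a sensorimotor-association (SA) axis rank with spatial autocorrelation
so that spatial nulls are non-degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: ratio of sphere-surface millimetres to unit-sphere coordinates; a radius
#: of 100 mm makes the default 30 mm short-range exclusion meaningful.
VOLUME_SCALE_MM = 100.0

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class Parcellation:
    """Node metadata for a bilateral spherical parcellation.

    Attributes
    ----------
    node_id : (P,) int array, 0..P-1
    hemisphere : (P,) array of "left"/"right"
    sphere_xyz : (P, 3) unit-norm coordinates; left nodes are the x-mirror
        of right nodes
    volume_xyz : (P, 3) coordinates in millimetres used for the short-range
        distance exclusion
    sa_rank : (P,) int array, a permutation of 1..P (1 = most sensorimotor)
    module : (P,) int array of module labels in 0..M-1
    association_modules : frozenset of module labels counted as association
        (transmodal) cortex
    """

    node_id: np.ndarray
    hemisphere: np.ndarray
    sphere_xyz: np.ndarray
    volume_xyz: np.ndarray
    sa_rank: np.ndarray
    module: np.ndarray
    association_modules: frozenset = field(default_factory=frozenset)

    @property
    def n_nodes(self) -> int:
        return int(self.node_id.size)

    @property
    def n_modules(self) -> int:
        return int(np.unique(self.module).size)

    def is_association_node(self) -> np.ndarray:
        """Boolean mask of nodes belonging to association modules."""
        return np.isin(self.module, sorted(self.association_modules))

    def validate(self) -> None:
        p = self.n_nodes
        if sorted(self.sa_rank.tolist()) != list(range(1, p + 1)):
            raise ValueError("sa_rank must be a permutation of 1..P")
        norms = np.linalg.norm(self.sphere_xyz, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("sphere coordinates must have unit norm")
        if self.n_modules < 2:
            raise ValueError("at least 2 modules required")
        right = self.hemisphere == "right"
        left = self.hemisphere == "left"
        if right.sum() != left.sum():
            raise ValueError("hemispheres must have equal node counts")
        mirrored = self.sphere_xyz[right] * np.array([-1.0, 1.0, 1.0])
        if not np.allclose(np.sort(mirrored, axis=0),
                           np.sort(self.sphere_xyz[left], axis=0), atol=1e-9):
            raise ValueError("hemispheres are not mirror-symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": self.node_id,
                "hemisphere": self.hemisphere,
                "x": self.sphere_xyz[:, 0],
                "y": self.sphere_xyz[:, 1],
                "z": self.sphere_xyz[:, 2],
                "vx": self.volume_xyz[:, 0],
                "vy": self.volume_xyz[:, 1],
                "vz": self.volume_xyz[:, 2],
                "sa_rank": self.sa_rank,
                "module": self.module,
                "is_association": self.is_association_node().astype(int),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Parcellation":
        df = pd.read_csv(path, sep="\t", comment="#")
        assoc = frozenset(df.loc[df["is_association"] == 1, "module"].unique().tolist())
        return cls(
            node_id=df["node_id"].to_numpy(int),
            hemisphere=df["hemisphere"].to_numpy(str),
            sphere_xyz=df[["x", "y", "z"]].to_numpy(float),
            volume_xyz=df[["vx", "vy", "vz"]].to_numpy(float),
            sa_rank=df["sa_rank"].to_numpy(int),
            module=df["module"].to_numpy(int),
            association_modules=assoc,
        )


def _hemisphere_lattice(n: int, rng: np.random.Generator) -> np.ndarray:
    """Quasi-uniform jittered Fibonacci lattice on the x > 0 hemisphere."""
    i = np.arange(n)
    # cos(theta) uniform on (0, 1) gives uniform area on the hemisphere
    cos_t = (i + 0.5) / n
    sin_t = np.sqrt(1.0 - cos_t**2)
    psi = i * _GOLDEN_ANGLE
    pts = np.column_stack([cos_t, sin_t * np.cos(psi), sin_t * np.sin(psi)])
    jitter = rng.normal(scale=0.25 / np.sqrt(n), size=(n, 3))
    pts = pts + jitter
    pts[:, 0] = np.maximum(pts[:, 0], 1e-3)  # stay on the right hemisphere
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts


def make_parcellation(n_nodes: int, n_modules: int, seed: int) -> Parcellation:
    """Build a bilateral synthetic parcellation.

    Nodes are split evenly across two mirror-symmetric hemispheres. Modules
    are contiguous angular sectors (latitude bands around the lateral axis),
    assigned on the right hemisphere and copied to the mirrored left, so a
    random rotation genuinely scrambles module geometry. The SA rank is the
    rank of a smooth function of position plus a small seeded perturbation,
    giving it the spatial autocorrelation the spin null is designed for.
    Association modules are the half of modules with the highest mean SA rank.

    Parameters
    ----------
    n_nodes : even total node count
    n_modules : number of modules (>= 2, <= n_nodes // 2)
    seed : RNG seed; identical seeds give identical parcellations
    """
    if n_nodes % 2 != 0:
        raise ValueError(f"n_nodes must be even, got {n_nodes}")
    if n_modules < 2:
        raise ValueError("n_modules must be >= 2")
    if n_modules > n_nodes // 2:
        raise ValueError("n_modules cannot exceed nodes per hemisphere")

    rng = np.random.default_rng(seed)
    half = n_nodes // 2
    right = _hemisphere_lattice(half, rng)
    left = right * np.array([-1.0, 1.0, 1.0])
    xyz = np.vstack([right, left])
    hemi = np.array(["right"] * half + ["left"] * half)

    # contiguous sectors: order right-hemisphere nodes by polar angle from
    # the superior (+z) axis, break ties by azimuth, chunk into M groups
    theta = np.arccos(np.clip(right[:, 2], -1, 1))
    phi = np.arctan2(right[:, 1], right[:, 0])
    order = np.lexsort((phi, theta))
    module_half = np.empty(half, dtype=int)
    bounds = np.linspace(0, half, n_modules + 1).astype(int)
    for m in range(n_modules):
        module_half[order[bounds[m]:bounds[m + 1]]] = m
    module = np.concatenate([module_half, module_half])

    # multi-scale positional score + seeded perturbation -> autocorrelated SA
    # rank; mixing low- and mid-frequency components makes rotated copies
    # decorrelate at realistic rates (a pure low-order gradient would leave
    # the spin null nearly as wide as the statistic's full range)
    score = (
        0.4 * xyz[:, 2]
        + 0.5 * np.sin(2.5 * xyz[:, 1])
        + 0.5 * np.cos(4.0 * xyz[:, 2]) * np.sin(3.0 * xyz[:, 1])
        + 0.4 * np.sin(4.0 * np.abs(xyz[:, 0])) * np.cos(3.0 * xyz[:, 1])
        + rng.normal(scale=0.25, size=n_nodes)
    )
    sa_rank = np.empty(n_nodes, dtype=int)
    sa_rank[np.argsort(score, kind="stable")] = np.arange(1, n_nodes + 1)

    mean_rank = pd.Series(sa_rank).groupby(module).mean()
    n_assoc = n_modules // 2
    assoc = frozenset(mean_rank.sort_values(ascending=False).index[:n_assoc].tolist())

    parc = Parcellation(
        node_id=np.arange(n_nodes),
        hemisphere=hemi,
        sphere_xyz=xyz,
        volume_xyz=xyz * VOLUME_SCALE_MM,
        sa_rank=sa_rank,
        module=module,
        association_modules=assoc,
    )
    parc.validate()
    return parc
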
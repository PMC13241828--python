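"""Signed weighted graph construction and node-level topology metrics.

Graphs are built in three ordered steps: (1) short-range distance exclusion
(Euclidean on volume coordinates), (2) edge-sign treatment (absolute value
or positive-only rectification), (3) proportional thresholding retaining a
fixed top fraction of the eligible (non-excluded) edges by weight so every
session's graph has the same density. Weights of retained edges are kept
(weighted graphs, not binarized).

Metrics follow the standard weighted conventions: Onnela's clustering
coefficient C_i = (1/(k_i(k_i-1))) * sum_{j,k} (w_ij w_jk w_ki)^{1/3} with
binary degree k_i and weights max-normalized to [0, 1]; local efficiency as
the mean inverse weighted shortest-path length (edge length 1/w) between a
node's neighbors inside the neighbor-induced subgraph; and the participation
coefficient P_i = 1 - sum_m (k_im / k_i)^2 over module strengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import squareform, pdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

TREATMENTS = ("absolute", "positive_only")
METRICS = ("clustering", "local_efficiency", "participation")


@dataclass
class SignedNetwork:
    """A thresholded nonnegative weighted graph under one sign treatment.

    ``weights`` is symmetric with zero diagonal; absent edges (excluded,
    sub-threshold, or rectified away) are 0. ``mask`` marks
    distance-excluded pairs. ``density`` is the realized fraction of
    eligible pairs retained.
    """

    weights: np.ndarray
    treatment: str
    density: float
    mask: np.ndarray
    module_map: Optional[np.ndarray] = None
    n_eligible: int = 0
    n_retained: int = 0

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def distance_mask(parcellation, min_dist_mm: float = 30.0) -> np.ndarray:
    """Boolean matrix of node pairs closer than ``min_dist_mm`` (True =
    excluded). Euclidean distance on volume coordinates; diagonal False."""
    if parcellation.volume_xyz is None:
        raise ValueError("parcellation has no volume coordinates")
    d = squareform(pdist(parcellation.volume_xyz))
    mask = d < min_dist_mm
    np.fill_diagonal(mask, False)
    return mask


def apply_distance_exclusion(matrix, parcellation, min_dist_mm: float = 30.0):
    """Mask short-range pairs out of a connectivity matrix.

    Returns ``(masked, mask)`` where ``masked`` has NaN at excluded pairs
    (and keeps the NaN diagonal) and ``mask`` is the boolean excluded-pair
    matrix for reuse in later stages.
    """
    v = matrix.values.copy() if hasattr(matrix, "values") else np.asarray(matrix, float).copy()
    mask = distance_mask(parcellation, min_dist_mm)
    v[mask] = np.nan
    np.fill_diagonal(v, np.nan)
    return v, mask


def construct_network(masked_matrix: np.ndarray, treatment: str) -> np.ndarray:
    """Apply the edge-sign treatment to a masked matrix.

    absolute: |w|; positive_only: max(w, 0). NaN (absent) entries are
    preserved.
    """
    if treatment not in TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}")
    v = np.asarray(masked_matrix, dtype=float)
    if treatment == "absolute":
        return np.abs(v)
    return np.where(np.isnan(v), np.nan, np.maximum(v, 0.0))


def proportional_threshold(weights: np.ndarray, density: float = 0.25,
                           treatment: str = "absolute",
                           module_map: Optional[np.ndarray] = None) -> SignedNetwork:
    """Retain the top ``density`` fraction of eligible edges by weight.

    Eligible pairs are the finite off-diagonal entries of ``weights`` (NaN
    marks distance-excluded pairs). Exactly k = floor(density * n_eligible)
    edges are retained, ties broken deterministically by (weight desc,
    node-pair lexicographic). Retained edges keep their weights.
    """
    if not (0.0 < density <= 1.0):
        raise ValueError("density must lie in (0, 1]")
    v = np.asarray(weights, dtype=float)
    p = v.shape[0]
    iu, ju = np.triu_indices(p, k=1)
    vals = v[iu, ju]
    eligible = np.isfinite(vals)
    n_eligible = int(eligible.sum())
    k = int(np.floor(density * n_eligible))
    if k == 0:
        raise ValueError(
            f"density {density} retains zero of {n_eligible} eligible edges")
    ei, ej, ev = iu[eligible], ju[eligible], vals[eligible]
    order = np.lexsort((ej, ei, -ev))  # weight desc, then (i, j) lexicographic
    keep = order[:k]
    w = np.zeros((p, p))
    w[ei[keep], ej[keep]] = ev[keep]
    w = w + w.T
    if np.any(w < 0):
        raise ValueError("proportional_threshold expects nonnegative weights")
    mask = np.isnan(v)
    np.fill_diagonal(mask, False)
    return SignedNetwork(
        weights=w, treatment=treatment, density=k / n_eligible, mask=mask,
        module_map=module_map, n_eligible=n_eligible, n_retained=k,
    )


def build_signed_network(matrix, parcellation, treatment: str,
                         density: float = 0.25,
                         min_dist_mm: float = 30.0) -> SignedNetwork:
    """Convenience: exclusion -> sign treatment -> proportional threshold."""
    masked, _ = apply_distance_exclusion(matrix, parcellation, min_dist_mm)
    w = construct_network(masked, treatment)
    return proportional_threshold(w, density, treatment=treatment,
                                  module_map=parcellation.module)


def threshold_sweep(weights: np.ndarray, densities=(0.05, 0.1, 0.15, 0.2,
                                                    0.25, 0.3, 0.35, 0.4),
                    treatment: str = "absolute",
                    module_map: Optional[np.ndarray] = None) -> dict:
    """Multi-density sensitivity mode: proportional thresholding at several
    densities; returns {density: SignedNetwork}."""
    return {d: proportional_threshold(weights, d, treatment=treatment,
                                      module_map=module_map)
            for d in densities}


def _weights_of(network) -> np.ndarray:
    return network.weights if isinstance(network, SignedNetwork) else np.asarray(network, float)


def clustering_coefficient(network) -> np.ndarray:
    """Onnela weighted clustering per node.

    Weights are normalized by the maximum retained weight so the cube-root
    triple products, and hence C_i, lie in [0, 1]. Nodes with binary degree
    <= 1 get 0.
    """
    w = _weights_of(network)
    wmax = w.max()
    if wmax <= 0:
        return np.zeros(w.shape[0])
    wn = np.cbrt(w / wmax)
    triples = np.diagonal(wn @ wn @ wn)
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    return np.divide(triples, denom, out=np.zeros(w.shape[0]), where=denom > 0)


def local_efficiency(network, edge_length: str = "inverse") -> np.ndarray:
    """Weighted local efficiency per node.

    For each node i with >= 2 neighbors: the mean over ordered neighbor
    pairs of 1/d_jk, where d_jk is the weighted shortest-path length inside
    the subgraph induced by i's neighbors (i itself removed). Edge length is
    1/w on max-normalized weights (``edge_length="inverse"``, default) or
    1/w^(1/3) (``"inverse_cbrt"``, the cube-root toolbox convention, for
    cross-checks). Unreachable pairs contribute 0.
    """
    if edge_length not in ("inverse", "inverse_cbrt"):
        raise ValueError("edge_length must be 'inverse' or 'inverse_cbrt'")
    w = _weights_of(network)
    p = w.shape[0]
    wmax = w.max()
    if wmax <= 0:
        return np.zeros(p)
    wn = w / wmax
    if edge_length == "inverse_cbrt":
        wn = np.cbrt(wn)
    lengths = np.zeros_like(wn)
    nz = wn > 0
    lengths[nz] = 1.0 / wn[nz]
    out = np.zeros(p)
    adj = wn > 0
    for i in range(p):
        nbrs = np.flatnonzero(adj[i])
        n = nbrs.size
        if n < 2:
            continue
        sub = lengths[np.ix_(nbrs, nbrs)]
        d = shortest_path(csr_matrix(sub), method="D", directed=False)
        off = ~np.eye(n, dtype=bool)
        inv = np.zeros_like(d)
        reach = np.isfinite(d) & off & (d > 0)
        inv[reach] = 1.0 / d[reach]
        out[i] = inv[off].sum() / (n * (n - 1))
    return out


def participation_coefficient(network, module_map: Optional[np.ndarray] = None) -> np.ndarray:
    """Participation coefficient P_i = 1 - sum_m (k_im / k_i)^2 with
    weighted strengths. Nodes with zero strength get 0."""
    w = _weights_of(network)
    if module_map is None and isinstance(network, SignedNetwork):
        module_map = network.module_map
    if module_map is None:
        raise ValueError("module_map required for participation coefficient")
    module_map = np.asarray(module_map)
    if module_map.shape[0] != w.shape[0]:
        raise ValueError("every node needs a module assignment")
    k = w.sum(axis=1)
    mods = np.unique(module_map)
    onehot = (module_map[None, :] == mods[:, None]).astype(float)  # M x P
    kim = w @ onehot.T  # P x M
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(k[:, None] > 0, kim / k[:, None], 0.0)
    pi = 1.0 - (frac**2).sum(axis=1)
    pi[k <= 0] = 0.0
    return pi


_METRIC_FUNCS = {
    "clustering": lambda net: clustering_coefficient(net),
    "local_efficiency": lambda net: local_efficiency(net),
    "participation": lambda net: participation_coefficient(net),
}


def compute_metric(network: SignedNetwork, metric: str) -> np.ndarray:
    if metric not in _METRIC_FUNCS:
        raise ValueError(f"unknown metric {metric!r}")
    return _METRIC_FUNCS[metric](network)


class SignedGraphMetrics(BaseEstimator, TransformerMixin):
    """Transformer: session FC matrices -> node-level graph-metric panels.

    Fisher z-transforms each correlation matrix, applies the distance
    exclusion and sign treatment, thresholds to the target density, and
    computes the requested metrics.

    Parameters
    ----------
    parcellation : Parcellation (coordinates + module labels)
    treatment : "absolute" | "positive_only"
    density : proportional threshold, fraction of eligible edges retained
    min_dist_mm : short-range exclusion radius in millimetres
    metrics : subset of {"clustering", "local_efficiency", "participation"}

    After ``transform``, ``realized_densities_`` records per-session
    realized densities.
    """

    def __init__(self, parcellation=None, treatment="absolute", density=0.25,
                 min_dist_mm=30.0, metrics=METRICS):
        self.parcellation = parcellation
        self.treatment = treatment
        self.density = density
        self.min_dist_mm = min_dist_mm
        self.metrics = metrics

    def fit(self, X, y=None):
        if self.parcellation is None:
            raise ValueError("parcellation is required")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        for m in self.metrics:
            if m not in _METRIC_FUNCS:
                raise ValueError(f"unknown metric {m!r}")
        self.mask_ = distance_mask(self.parcellation, self.min_dist_mm)
        self.n_nodes_ = self.parcellation.n_nodes
        return self

    def transform(self, X) -> dict:
        """X: (n_sessions, P, P) correlation matrices. Returns a dict
        metric -> (n_sessions, P) array."""
        from .connectivity import ConnectivityMatrix, fisher_z

        check_is_fitted(self, "mask_")
        X = np.asarray(X, dtype=float)
        panels = {m: np.empty(X.shape[:2]) for m in self.metrics}
        self.realized_densities_ = np.empty(X.shape[0])
        for s, mat in enumerate(X):
            m = mat.copy()
            np.fill_diagonal(m, np.nan)
            z = fisher_z(ConnectivityMatrix(values=m)).values
            z[self.mask_] = np.nan
            w = construct_network(z, self.treatment)
            net = proportional_threshold(w, self.density,
                                         treatment=self.treatment,
                                         module_map=self.parcellation.module)
            self.realized_densities_[s] = net.density
            for name in self.metrics:
                panels[name][s] = compute_metric(net, name)
        return panels


def panel_to_frame(panel: np.ndarray, phenotypes: pd.DataFrame,
                   metric: str, treatment: str) -> pd.DataFrame:
    """Long-format (subject, session, node_id, treatment, metric, value)."""
    n_sessions, p = panel.shape
    rows = phenotypes[["subject", "session"]].to_numpy()
    df = pd.DataFrame({
        "subject": np.repeat(rows[:, 0], p),
        "session": np.repeat(rows[:, 1], p),
        "node_id": np.tile(np.arange(p), n_sessions),
        "treatment": treatment,
        "metric": metric,
        "value": panel.ravel(),
    })
    return df
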
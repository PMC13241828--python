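"""Functional-connectivity matrices and sign-resolved node strength.

Convention used throughout the package: a "masked matrix" is a square
symmetric array in which absent entries (the removed diagonal and any
distance-excluded pairs) are ``NaN``. All downstream sums, thresholds and
graph constructions treat ``NaN`` as "no edge".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

_CLIP = 1.0 - 1e-7

STRENGTH_VARIANTS = ("positive", "negative", "absolute")


@dataclass
class ConnectivityMatrix:
    """ROI x ROI connectivity with the diagonal removed (NaN).

    ``scale`` is ``"pearson_r"`` (entries in [-1, 1]) or ``"fisher_z"``.
    """

    values: np.ndarray
    scale: str = "pearson_r"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        off = ~np.eye(v.shape[0], dtype=bool)
        finite = off & np.isfinite(v)
        if not np.allclose(np.where(finite & finite.T, v - v.T, 0.0), 0.0, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if self.scale == "pearson_r" and finite.any():
            if np.nanmax(np.abs(v[finite])) > 1.0 + 1e-12:
                raise ValueError("pearson_r entries must lie in [-1, 1]")
        self.values = v

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def pearson_fc(timeseries) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of regional time series.

    Parameters
    ----------
    timeseries : (T, P) array or DataFrame, frames x nodes. Columns are
        z-scored internally (a no-op for the correlation itself, mirroring
        the usual normalization step).
    """
    if isinstance(timeseries, pd.DataFrame):
        names = list(timeseries.columns)
        x = timeseries.to_numpy(dtype=float)
    else:
        x = np.asarray(timeseries, dtype=float)
        names = list(range(x.shape[1] if x.ndim == 2 else 0))
    if x.ndim != 2:
        raise ValueError("timeseries must be 2-D (frames x nodes)")
    t, p = x.shape
    if t < 3:
        raise ValueError(f"need at least 3 frames, got {t}")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = [str(names[i]) for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant time series for node(s): {', '.join(bad)}")
    z = (x - x.mean(axis=0)) / sd
    r = (z.T @ z) / t
    r = np.clip(0.5 * (r + r.T), -1.0, 1.0)
    np.fill_diagonal(r, np.nan)
    return ConnectivityMatrix(values=r, scale="pearson_r")


def fisher_z(matrix: ConnectivityMatrix) -> ConnectivityMatrix:
    """Entrywise Fisher z-transform (atanh), sign-preserving.

    Correlations at |r| >= 1 are clipped to 1 - 1e-7 with a warning so the
    transform stays finite.
    """
    if matrix.scale != "pearson_r":
        raise ValueError("fisher_z expects a pearson_r-scale matrix")
    v = matrix.values.copy()
    finite = np.isfinite(v)
    n_clip = int(np.sum(np.abs(v[finite]) >= _CLIP))
    if n_clip:
        warnings.warn(f"clipped {n_clip} near-unit correlations before atanh",
                      RuntimeWarning)
        logger.warning("fisher_z clipped %d entries at +/-%.0e", n_clip, 1 - _CLIP)
    v[finite] = np.arctanh(np.clip(v[finite], -_CLIP, _CLIP))
    return ConnectivityMatrix(values=v, scale="fisher_z")


def node_strength(matrix, variant: str, as_mean: bool = False) -> np.ndarray:
    """Sign-resolved node strength on a masked matrix.

    positive: sum_j max(w_ij, 0); negative: sum_j max(-w_ij, 0) (reported as
    a magnitude); absolute: sum_j |w_ij|. Absent (NaN) entries contribute 0.
    With ``as_mean`` the sum is divided by each node's count of present
    entries.
    """
    if variant not in STRENGTH_VARIANTS:
        raise ValueError(f"unknown strength variant {variant!r}")
    v = matrix.values if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix, float)
    w = np.nan_to_num(v, nan=0.0)
    if variant == "positive":
        s = np.maximum(w, 0.0).sum(axis=1)
    elif variant == "negative":
        s = np.maximum(-w, 0.0).sum(axis=1)
    else:
        s = np.abs(w).sum(axis=1)
    if as_mean:
        n_present = np.isfinite(v).sum(axis=1)
        s = np.divide(s, n_present, out=np.zeros_like(s), where=n_present > 0)
    return s


class NodeStrength(BaseEstimator, TransformerMixin):
    """Transformer mapping session FC matrices to node-strength vectors.

    Applies Fisher z and the short-range distance exclusion before summing,
    matching the strength arm of the analysis (strength is computed on full,
    unthresholded matrices).

    Parameters
    ----------
    parcellation : Parcellation supplying volume coordinates for exclusion
    variant : "positive" | "negative" | "absolute"
    min_dist_mm : exclusion radius; 0 disables
    as_mean : report mean over present edges instead of the sum
    density : optional proportional threshold applied (on |z|) before
        summing, as a sensitivity switch; default None sums full matrices
    """

    def __init__(self, parcellation=None, variant="positive",
                 min_dist_mm=30.0, as_mean=False, density=None):
        self.parcellation = parcellation
        self.variant = variant
        self.min_dist_mm = min_dist_mm
        self.as_mean = as_mean
        self.density = density

    def fit(self, X, y=None):
        from .graphs import distance_mask

        if self.variant not in STRENGTH_VARIANTS:
            raise ValueError(f"unknown strength variant {self.variant!r}")
        X = np.asarray(X, dtype=float)
        p = X.shape[-1]
        if self.parcellation is not None and self.min_dist_mm > 0:
            self.mask_ = distance_mask(self.parcellation, self.min_dist_mm)
        else:
            self.mask_ = np.zeros((p, p), dtype=bool)
        self.n_nodes_ = p
        return self

    def transform(self, X) -> np.ndarray:
        """X: (n_sessions, P, P) stack of correlation matrices (r scale).
        Returns (n_sessions, P) strengths on the Fisher-z scale."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "mask_")
        X = np.asarray(X, dtype=float)
        out = np.empty(X.shape[:2])
        for k, mat in enumerate(X):
            m = mat.copy()
            np.fill_diagonal(m, np.nan)
            z = fisher_z(ConnectivityMatrix(values=m))
            zv = z.values
            zv[self.mask_] = np.nan
            if self.density is not None:
                from .graphs import proportional_threshold

                net = proportional_threshold(np.abs(zv), self.density)
                zv = np.where(net.weights > 0, zv, np.nan)
            out[k] = node_strength(zv, self.variant, as_mean=self.as_mean)
        return out
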
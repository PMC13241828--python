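"""Per-node age-effect maps: delta R^2, smooth p-values, FDR flags.

For every node of a metric panel, a full model (penalized age spline +
covariates + subject random intercept) and a null model (same minus the age
smooth) are fit on identical rows; delta R^2 is the adjusted-R^2 difference
and quantifies the unique variance in the metric explained by age. Smooth
p-values are corrected across nodes with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .gamm import GAMMFit, build_design, fit_gamm_design, smooth_lrt_pvalue

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("sex", "alcohol", "cannabis", "fd")


@dataclass
class ModelSpec:
    """Specification of the per-node developmental model.

    The null model is the full model minus the age smooth, everything else
    identical.
    """

    covariates: Sequence[str] = DEFAULT_COVARIATES
    basis_dim: int = 5
    q_fdr: float = 0.05
    standardize: bool = True

    def __post_init__(self):
        if self.basis_dim < 4:
            raise ValueError("basis_dim must be >= 4")
        if not (0 < self.q_fdr < 1):
            raise ValueError("q_fdr must lie in (0, 1)")


@dataclass
class AgeEffectMap:
    """Per-node age-effect estimates for one metric panel."""

    delta_r2: np.ndarray
    edf: np.ndarray
    p_smooth: np.ndarray
    fdr_significant: np.ndarray
    converged: np.ndarray
    failed_nodes: list = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.delta_r2.size

    def to_frame(self, metric: str = "", treatment: str = "") -> pd.DataFrame:
        return pd.DataFrame({
            "node_id": np.arange(self.n_nodes),
            "metric": metric,
            "treatment": treatment,
            "delta_r2": self.delta_r2,
            "edf": self.edf,
            "p_smooth": self.p_smooth,
            "fdr_significant": self.fdr_significant.astype(int),
            "converged": self.converged.astype(int),
        })


def _phenotype_arrays(phenotypes: pd.DataFrame, spec: ModelSpec):
    missing = [c for c in ("subject", "age", *spec.covariates)
               if c not in phenotypes.columns]
    if missing:
        raise ValueError(f"phenotype table lacks column(s): {', '.join(missing)}")
    cov = phenotypes[list(spec.covariates)]
    return phenotypes["age"].to_numpy(float), cov, phenotypes["subject"].to_numpy()


def fit_node_model(y, phenotypes: pd.DataFrame, spec: Optional[ModelSpec] = None,
                   include_age: bool = True) -> GAMMFit:
    """Fit the full (or null) model for one node's metric values."""
    spec = spec or ModelSpec()
    age, cov, subject = _phenotype_arrays(phenotypes, spec)
    from .gamm import fit_gamm

    return fit_gamm(np.asarray(y, float), age, cov, subject,
                    include_age=include_age, basis_dim=spec.basis_dim,
                    standardize=spec.standardize)


def delta_r2(full_fit: GAMMFit, null_fit: GAMMFit) -> float:
    """Adjusted-R^2 difference between full and null fits on identical rows.

    May be slightly negative when the smooth earns less than its degrees of
    freedom; negative values are retained (rank-based downstream analyses
    are unaffected).
    """
    if full_fit.n_obs != null_fit.n_obs:
        raise ValueError("full and null fits were not computed on the same rows")
    return float(full_fit.r2_adj - null_fit.r2_adj)


def fdr_correct(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up at level ``q``; returns a boolean vector."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def age_effect_map(panel: np.ndarray, phenotypes: pd.DataFrame,
                   spec: Optional[ModelSpec] = None) -> AgeEffectMap:
    """Fit full/null models for every node of a panel.

    Parameters
    ----------
    panel : (n_sessions, P) metric values, rows aligned with ``phenotypes``
    phenotypes : table with subject, age and the spec's covariates
    spec : ModelSpec (defaults used when omitted)

    Nodes whose fits fail or do not converge are excluded from the FDR set
    (p = NaN is treated as non-significant) and listed in ``failed_nodes``;
    more than 20% failures aborts.
    """
    spec = spec or ModelSpec()
    panel = np.asarray(panel, dtype=float)
    if panel.ndim != 2:
        raise ValueError("panel must be 2-D (sessions x nodes)")
    if panel.shape[0] != len(phenotypes):
        raise ValueError("panel rows and phenotype rows differ")
    age, cov, subject = _phenotype_arrays(phenotypes, spec)
    design_full = build_design(age, cov, subject, include_age=True,
                               basis_dim=spec.basis_dim,
                               standardize=spec.standardize)
    design_null = build_design(age, cov, subject, include_age=False,
                               basis_dim=spec.basis_dim,
                               standardize=spec.standardize)
    p_nodes = panel.shape[1]
    dr2 = np.full(p_nodes, np.nan)
    edf = np.full(p_nodes, np.nan)
    p_smooth = np.full(p_nodes, np.nan)
    converged = np.zeros(p_nodes, dtype=bool)
    failed = []
    warm = {"full": None, "full_ml": None, "null": None, "null_ml": None}
    for j in range(p_nodes):
        y = panel[:, j]
        try:
            full = fit_gamm_design(design_full, y, start=warm["full"],
                                   start_ml=warm["full_ml"])
            null = fit_gamm_design(design_null, y, start=warm["null"],
                                   start_ml=warm["null_ml"])
        except (RuntimeError, ValueError) as exc:
            logger.warning("node %d fit failed: %s", j, exc)
            failed.append(j)
            continue
        if not (full.converged and null.converged):
            logger.warning("node %d did not converge; excluded from maps", j)
            failed.append(j)
            continue
        warm["full"] = warm["full_ml"] = full.log_gamma_reml
        warm["null"] = warm["null_ml"] = null.log_gamma_reml
        dr2[j] = delta_r2(full, null)
        edf[j] = full.edf_smooth
        p_smooth[j] = smooth_lrt_pvalue(full, null)
        converged[j] = True
    if len(failed) > 0.2 * p_nodes:
        raise RuntimeError(
            f"{len(failed)}/{p_nodes} node fits failed: nodes {failed[:10]}...")
    fdr_sig = np.zeros(p_nodes, dtype=bool)
    ok = np.isfinite(p_smooth)
    if ok.any():
        fdr_sig[ok] = fdr_correct(p_smooth[ok], q=spec.q_fdr)
    return AgeEffectMap(delta_r2=dr2, edf=edf, p_smooth=p_smooth,
                        fdr_significant=fdr_sig, converged=converged,
                        failed_nodes=failed)


class AgeEffectMapper(BaseEstimator):
    """Estimator mapping a metric panel to per-node age effects.

    Parameters mirror :class:`ModelSpec`. After ``fit(panel, phenotypes)``
    the fitted attributes ``delta_r2_``, ``edf_``, ``p_smooth_``,
    ``fdr_significant_``, ``converged_`` and ``failed_nodes_`` hold the map.
    """

    def __init__(self, covariates=DEFAULT_COVARIATES, basis_dim=5,
                 q_fdr=0.05, standardize=True):
        self.covariates = covariates
        self.basis_dim = basis_dim
        self.q_fdr = q_fdr
        self.standardize = standardize

    def _spec(self) -> ModelSpec:
        return ModelSpec(covariates=self.covariates, basis_dim=self.basis_dim,
                         q_fdr=self.q_fdr, standardize=self.standardize)

    def fit(self, X, y=None, phenotypes: Optional[pd.DataFrame] = None):
        if phenotypes is None:
            raise ValueError("phenotypes table is required")
        amap = age_effect_map(X, phenotypes, self._spec())
        self.delta_r2_ = amap.delta_r2
        self.edf_ = amap.edf
        self.p_smooth_ = amap.p_smooth
        self.fdr_significant_ = amap.fdr_significant
        self.converged_ = amap.converged
        self.failed_nodes_ = amap.failed_nodes
        self.map_ = amap
        return self

    def transform(self, X=None):
        check_is_fitted(self, "delta_r2_")
        return self.delta_r2_
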
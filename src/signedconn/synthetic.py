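"""Synthetic longitudinal signed-connectome cohorts with planted ground truth.

The generator emulates the structure a sign-aware developmental analysis is
designed to detect, using an explicit latent-correlation model on the
Fisher-z scale:

* block-structured baseline connectivity — strong within-module coupling,
  weaker positive between-module coupling, and a minority of anticorrelated
  edges concentrated between association (transmodal) modules;
* positive-edge age effects graded along the SA axis (strongest in
  sensorimotor-ranked nodes), negative-edge age effects spatially uniform;
* subject random intercepts, covariate effects (sex, alcohol, cannabis,
  head motion), and session-level edge noise;
* three roughly biennial timepoints per subject across adolescence.

Every planted quantity is recorded in ``LongitudinalDataset.ground_truth``
so downstream recovery is checkable. Session matrices can be returned
directly (fast, default) or realized through sampled time series and
empirical Pearson correlation (``ts_length`` set).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .parcellation import Parcellation, make_parcellation

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Latent edge values live on the Fisher-z scale; ``tanh`` maps them back
    to correlations. Age effects are per-year slopes of latent z, centered
    at the midpoint of ``age_range``.
    """

    n_subjects: int = 60
    n_timepoints: int = 3
    age_range: tuple = (12.0, 18.0)
    n_nodes: int = 100
    n_modules: int = 13
    ts_length: Optional[int] = None

    # planted developmental structure
    pos_age_effect_scale: float = 0.008  # z/year at the sensorimotor pole
    neg_age_effect_scale: float = 0.004  # z/year magnitude growth, uniform
    neg_edge_fraction: float = 0.16
    #: which positive edges carry the SA-graded age effect: "all",
    #: "between_module", or "within_module" (the latter leaves the
    #: between-module background static so thresholded graphs show no
    #: compensatory edge churn)
    pos_effect_edges: str = "all"

    # baseline block structure (correlation scale unless noted)
    within_module_r: float = 0.35
    #: optional stronger within-module coupling for association modules
    within_module_r_assoc: Optional[float] = None
    between_module_r: float = 0.12
    assoc_block_z: float = -0.15  # starting mean for anticorrelated blocks
    calibrate_negative_fraction: bool = True

    # variance components (z scale)
    subject_sd: float = 0.025
    noise_sd: float = 0.05
    edge_sd: float = 0.06  # static edge heterogeneity within blocks

    covariate_betas: dict = field(
        default_factory=lambda: {
            "sex": 0.01, "alcohol": -0.004, "cannabis": -0.004, "fd": -0.05,
        }
    )
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.pos_effect_edges not in ("all", "between_module", "within_module"):
            raise ValueError(
                "pos_effect_edges must be 'all', 'between_module' or 'within_module'")
        if not (0.0 < self.neg_edge_fraction < 0.5):
            raise ValueError("neg_edge_fraction must lie in (0, 0.5)")
        if self.n_timepoints < 1:
            raise ValueError("n_timepoints must be >= 1")
        if self.age_range[1] <= self.age_range[0]:
            raise ValueError("age_range must be increasing")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def age_mid(self) -> float:
        return 0.5 * (self.age_range[0] + self.age_range[1])


def reversal_config(**overrides) -> SimulationConfig:
    """Scenario with age-strengthening anticorrelations between association
    modules, against a backdrop of sensorimotor-graded strengthening of
    within-module coupling (association within-module coupling is stronger
    but static). Anticorrelations start clearly negative (no sign crossing
    over the age window) and deepen uniformly, so absolute-value and
    positive-only graph constructions disagree on where development
    concentrates."""
    base = dict(
        assoc_block_z=-0.30,
        calibrate_negative_fraction=False,
        neg_age_effect_scale=0.035,
        pos_age_effect_scale=0.018,
        pos_effect_edges="within_module",
        within_module_r=0.30,
        within_module_r_assoc=0.55,
        neg_edge_fraction=0.2,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@dataclass
class SessionRecord:
    """One scan session: connectivity (or time series) plus phenotypes."""

    subject: int
    session: int
    age: float
    sex: int
    alcohol: float
    cannabis: float
    fd: float
    matrix: np.ndarray
    timeseries: Optional[np.ndarray] = None


@dataclass
class LongitudinalDataset:
    parcellation: Parcellation
    sessions: list
    ground_truth: dict
    config: SimulationConfig

    @property
    def n_sessions(self) -> int:
        return len(self.sessions)

    def phenotypes(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subject": s.subject, "session": s.session, "age": s.age,
                    "sex": s.sex, "alcohol": s.alcohol,
                    "cannabis": s.cannabis, "fd": s.fd,
                }
                for s in self.sessions
            ]
        )

    def matrices(self) -> np.ndarray:
        """Stack of session correlation matrices, shape (n_sessions, P, P)."""
        return np.stack([s.matrix for s in self.sessions])

    def validate(self) -> None:
        pheno = self.phenotypes()
        for _, grp in pheno.groupby("subject"):
            ages = grp.sort_values("session")["age"].to_numpy()
            if not np.all(np.diff(ages) > 0):
                raise ValueError("ages must be strictly increasing within subject")
        for s in self.sessions:
            m = s.matrix
            if not np.allclose(m, m.T, atol=1e-12):
                raise ValueError("session matrix not symmetric")
            if not np.allclose(np.diag(m), 1.0):
                raise ValueError("session matrix diagonal must be 1")

    def to_dir(self, path) -> None:
        from pathlib import Path

        out = Path(path)
        out.mkdir(parents=True, exist_ok=True)
        self.parcellation.to_tsv(out / "parcellation.tsv")
        self.phenotypes().to_csv(out / "phenotypes.tsv", sep="\t", index=False)
        p = self.parcellation.n_nodes
        iu = np.triu_indices(p, k=1)
        rows = []
        for idx, s in enumerate(self.sessions):
            rows.append(
                pd.DataFrame(
                    {"session_idx": idx, "i": iu[0], "j": iu[1],
                     "value": s.matrix[iu]}
                )
            )
        pd.concat(rows).to_csv(out / "matrices.tsv", sep="\t", index=False)
        gt = {k: np.asarray(v).tolist() for k, v in self.ground_truth.items()}
        (out / "ground_truth.json").write_text(json.dumps(gt, indent=2))
        cfg = asdict(self.config)
        cfg["age_range"] = list(cfg["age_range"])
        (out / "config.json").write_text(json.dumps(cfg, indent=2))


class _CohortLatent:
    """Cohort-level latent structure shared across all sessions."""

    def __init__(self, parcellation: Parcellation, config: SimulationConfig,
                 rng: np.random.Generator):
        p = parcellation.n_nodes
        mod = parcellation.module
        assoc = parcellation.is_association_node()
        same_mod = mod[:, None] == mod[None, :]
        both_assoc = assoc[:, None] & assoc[None, :]
        off = ~np.eye(p, dtype=bool)

        self.within = same_mod & off
        self.neg_block = both_assoc & ~same_mod  # between association modules
        self.between_pos = ~same_mod & ~self.neg_block
        self.pos_block = self.within | self.between_pos

        sigma = float(np.hypot(config.edge_sd, config.noise_sd))
        mu_w = np.arctanh(config.within_module_r)
        mu_wa = (np.arctanh(config.within_module_r_assoc)
                 if config.within_module_r_assoc is not None else mu_w)
        within_assoc = self.within & both_assoc
        within_other = self.within & ~both_assoc
        if config.calibrate_negative_fraction:
            nu = _calibrate_assoc_mean(
                config.neg_edge_fraction, sigma,
                positive_blocks=[
                    (within_other[off].mean(), mu_w),
                    (within_assoc[off].mean(), mu_wa),
                    (self.between_pos[off].mean(), np.arctanh(config.between_module_r)),
                ],
                s_a=self.neg_block[off].mean(),
            )
        else:
            nu = config.assoc_block_z
        self.assoc_mean = nu

        self.mean = np.zeros((p, p))
        self.mean[within_other] = mu_w
        self.mean[within_assoc] = mu_wa
        self.mean[self.between_pos] = np.arctanh(config.between_module_r)
        self.mean[self.neg_block] = nu

        # static edge heterogeneity, symmetric
        g = rng.normal(scale=config.edge_sd, size=(p, p))
        self.edge_hetero = np.triu(g, 1) + np.triu(g, 1).T

        # SA gradient: 1 at the sensorimotor pole (rank 1), 0 at the
        # association pole; positive-edge age slopes are graded by it
        self.gradient = (p - parcellation.sa_rank) / (p - 1)
        gi = self.gradient
        self.pos_slope = config.pos_age_effect_scale * 0.5 * (gi[:, None] + gi[None, :])
        self.pos_effect_block = {
            "all": self.pos_block,
            "between_module": self.between_pos,
            "within_module": self.within,
        }[config.pos_effect_edges]


def _calibrate_assoc_mean(target, sigma, positive_blocks, s_a):
    """Solve the association-block mean so the expected fraction of negative
    latent edges matches ``target`` under Gaussian edge dispersion.

    ``positive_blocks`` is a list of (pair share, mean z) for the
    positive-mean blocks."""
    other = sum(s * stats.norm.sf(mu / sigma) for s, mu in positive_blocks)
    need = (target - other) / s_a
    if not (0.0 < need < 1.0):
        warnings.warn(
            "negative-edge target unreachable by scaling the association "
            f"block alone (needed block fraction {need:.2f}); clamping",
            RuntimeWarning,
        )
        need = float(np.clip(need, 0.02, 0.98))
    return float(-sigma * stats.norm.ppf(need))


def _session_z(latent: _CohortLatent, config: SimulationConfig, age: float,
               subject_intercept: float, covariates: dict,
               rng: np.random.Generator) -> np.ndarray:
    d_age = age - config.age_mid
    z = latent.mean + latent.edge_hetero
    z = z + np.where(latent.pos_effect_block, latent.pos_slope * d_age, 0.0)
    z = z - config.neg_age_effect_scale * d_age * latent.neg_block
    b = config.covariate_betas
    shift = (
        subject_intercept
        + b.get("sex", 0.0) * covariates.get("sex", 0)
        + b.get("alcohol", 0.0) * covariates.get("alcohol", 0.0)
        + b.get("cannabis", 0.0) * covariates.get("cannabis", 0.0)
        + b.get("fd", 0.0) * (covariates.get("fd", 0.15) - 0.15)
    )
    p = z.shape[0]
    off = ~np.eye(p, dtype=bool)
    z = z + shift * off
    e = rng.normal(scale=config.noise_sd, size=(p, p))
    z = z + np.triu(e, 1) + np.triu(e, 1).T
    return z


def _nearest_correlation(r: np.ndarray) -> np.ndarray:
    """Eigenvalue-clipping repair to the nearest valid correlation matrix."""
    w, v = np.linalg.eigh(r)
    if w.min() >= 1e-10:
        return r
    logger.info("nearest-correlation repair applied (min eigenvalue %.2e)", w.min())
    w = np.clip(w, 1e-8, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return 0.5 * (fixed + fixed.T)


def simulate_session_matrix(
    parcellation: Parcellation,
    subject_effects: float,
    age: float,
    covariates: dict,
    config: SimulationConfig,
    latent: Optional[_CohortLatent] = None,
    rng: Optional[np.random.Generator] = None,
):
    """Draw one session's correlation matrix (and time series in ts mode).

    Returns the matrix alone, or ``(matrix, timeseries)`` when
    ``config.ts_length`` is set, in which case the matrix is the empirical
    Pearson correlation of frames sampled from the (repaired) latent
    correlation.
    """
    if not (config.age_range[0] - 1e-9 <= age <= config.age_range[1] + 0.6):
        raise ValueError(f"age {age} outside configured range")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if latent is None:
        latent = _CohortLatent(parcellation, config, rng)
    z = _session_z(latent, config, age, subject_effects, covariates, rng)
    r = np.tanh(z)
    np.fill_diagonal(r, 1.0)
    if config.ts_length is None:
        return r
    sigma = _nearest_correlation(r)
    chol = np.linalg.cholesky(sigma + 1e-10 * np.eye(sigma.shape[0]))
    ts = rng.standard_normal((config.ts_length, sigma.shape[0])) @ chol.T
    emp = np.corrcoef(ts, rowvar=False)
    np.fill_diagonal(emp, 1.0)
    return emp, ts


def _draw_covariates(age: float, rng: np.random.Generator) -> dict:
    fd = float(rng.lognormal(mean=np.log(0.15), sigma=0.4))
    p_alc = np.clip(0.10 + 0.09 * (age - 12.0), 0.0, 0.9)
    p_can = np.clip(0.05 + 0.06 * (age - 12.0), 0.0, 0.8)
    alcohol = float(rng.gamma(2.0, 1.0)) if rng.random() < p_alc else 0.0
    cannabis = float(rng.gamma(2.0, 1.0)) if rng.random() < p_can else 0.0
    return {"alcohol": alcohol, "cannabis": cannabis, "fd": fd}


def simulate_cohort(config: SimulationConfig) -> LongitudinalDataset:
    """Simulate a full longitudinal cohort.

    Subjects enter at a uniformly drawn baseline age and return at roughly
    biennial follow-ups (strictly increasing ages). Sessions are dropped
    completely at random at rate ``config.dropout``; subjects losing every
    session are removed. The planted per-node age-effect sizes (average
    incident positive-edge slope; uniform negative-edge magnitude slope)
    are stored in ``ground_truth`` together with the SA gradient used.
    """
    rng = np.random.default_rng(config.seed)
    parc = make_parcellation(config.n_nodes, config.n_modules, config.seed)
    latent = _CohortLatent(parc, config, rng)

    lo, hi = config.age_range
    span = hi - lo
    gap_mean = span / max(config.n_timepoints, 2)

    gt_pos = config.pos_age_effect_scale * 0.5 * (latent.gradient + latent.gradient.mean())
    gt_neg = np.full(parc.n_nodes, config.neg_age_effect_scale)
    if config.pos_age_effect_scale != 0:
        rho = stats.spearmanr(gt_pos, parc.sa_rank).statistic
        target = -np.sign(config.pos_age_effect_scale)
        if abs(rho - target) > 0.05:
            raise AssertionError(
                f"planted positive gradient mis-specified (spearman {rho:.3f})"
            )

    sessions = []
    for subj in range(config.n_subjects):
        sex = int(rng.integers(0, 2))
        u = float(rng.normal(scale=config.subject_sd))
        age = float(rng.uniform(lo, lo + 0.35 * span))
        ages = [age]
        for _ in range(config.n_timepoints - 1):
            gap = max(0.25, rng.normal(gap_mean, 0.25 * gap_mean))
            ages.append(ages[-1] + gap)
        if ages[-1] > hi + 0.5:  # compress follow-up gaps into the window
            scale = (hi + 0.5 - ages[0]) / (ages[-1] - ages[0])
            ages = [ages[0] + (a - ages[0]) * scale for a in ages]
        kept = [a for a in ages if rng.random() >= config.dropout]
        for t, a in enumerate(kept):
            cov = _draw_covariates(a, rng)
            cov["sex"] = sex
            out = simulate_session_matrix(parc, u, a, cov, config,
                                          latent=latent, rng=rng)
            mat, ts = out if config.ts_length is not None else (out, None)
            sessions.append(
                SessionRecord(subject=subj, session=t, age=a, sex=sex,
                              alcohol=cov["alcohol"], cannabis=cov["cannabis"],
                              fd=cov["fd"], matrix=mat, timeseries=ts)
            )

    ds = LongitudinalDataset(
        parcellation=parc,
        sessions=sessions,
        ground_truth={
            "positive_age_effect": gt_pos,
            "negative_age_effect": gt_neg,
            "sa_gradient": latent.gradient,
            "assoc_block_mean_z": latent.assoc_mean,
        },
        config=config,
    )
    ds.validate()
    return ds
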
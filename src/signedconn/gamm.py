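"""Penalized-spline mixed models for developmental trajectories.

Fits, per response, the model

    y_ij = beta0 + f(age_ij) + beta' covariates_ij + u_i + eps_ij

where f is a penalized cubic spline (P-spline: B-spline basis with a
second-order difference penalty) and u_i is a subject random intercept.
The smooth enters through its mixed-model representation: the penalty null
space (the linear age trend) joins the fixed effects and the wiggle
coefficients become an iid variance component, so REML estimation of the
variance ratios performs the smoothness selection.

All likelihood evaluations use the Woodbury/Henderson form, so the cost per
evaluation scales with the number of random-effect columns (spline wiggles +
subjects), not with the number of observations; per-node model grids over
hundreds of nodes stay cheap.

Reported per fit:

* ``r2_adj`` — adjusted R^2 of the marginal (fixed + smooth; random
  intercept excluded) fitted values, with model degrees of freedom counting
  the smooth's effective degrees of freedom (edf). The subject intercept
  contributes to neither the full nor the null marginal fit, so it cancels
  in the full-minus-null difference (delta R^2).
* ``edf_smooth`` — effective degrees of freedom of the age smooth (linear
  column plus shrunk wiggle columns), from the Henderson-system hat
  diagonal.
* ``p_smooth`` (via :func:`smooth_lrt_pvalue`) — maximum-likelihood
  likelihood-ratio test of the smooth (age coefficient and wiggle variance
  jointly zero) against a 0.5*chi2(1) + 0.5*chi2(2) boundary mixture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import interpolate, linalg, optimize, stats

_LOG_GAMMA_BOUNDS = (-14.0, 14.0)


def pspline_basis(x: np.ndarray, basis_dim: int = 5):
    """Cubic B-spline basis in mixed-model form.

    Returns ``(x_lin, z_wiggle)``: the centered linear trend (penalty null
    space beyond the intercept) and the penalized wiggle columns
    ``Z = B D' (D D')^{-1}`` for the second-difference penalty matrix D.
    ``x`` is internally scaled to [0, 1].
    """
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise ValueError("age has no variation")
    if basis_dim < 4:
        raise ValueError("basis_dim must be >= 4 for a cubic spline")
    xs = (x - lo) / (hi - lo)
    degree = 3
    n_interior = basis_dim - degree - 1
    interior = np.linspace(0, 1, n_interior + 2)[1:-1] if n_interior > 0 else np.array([])
    knots = np.concatenate([[0.0] * (degree + 1), interior, [1.0] * (degree + 1)])
    b = interpolate.BSpline.design_matrix(xs, knots, degree).toarray()
    d = np.diff(np.eye(basis_dim), n=2, axis=0)  # (k-2) x k
    z = b @ d.T @ np.linalg.inv(d @ d.T)
    x_lin = xs - xs.mean()
    # project the null space out of the wiggle columns for conditioning
    null = np.column_stack([np.ones_like(xs), x_lin])
    z = z - null @ np.linalg.lstsq(null, z, rcond=None)[0]
    return x_lin, z


@dataclass
class GAMMFit:
    """Result of one penalized-spline mixed-model fit."""

    beta: np.ndarray
    fixed_names: list
    var_spline: float
    var_subject: float
    sigma2: float
    edf_smooth: float
    r2: float
    r2_adj: float
    fitted_marginal: np.ndarray
    minus2ll_ml: float
    converged: bool
    n_obs: int
    n_fixed: int
    include_age: bool
    log_gamma_reml: Optional[np.ndarray] = None
    b_spline: Optional[np.ndarray] = None
    u_subject: Optional[np.ndarray] = None


def _check_full_rank(x: np.ndarray, names: Sequence[str]) -> None:
    _, r, piv = linalg.qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps * 10
    bad = diag < tol
    if bad.any():
        cols = [names[piv[i]] for i in np.flatnonzero(bad)]
        raise ValueError(
            f"design is rank deficient; collinear column(s): {', '.join(cols)}")


class MixedDesign:
    """Fixed design plus random-effect blocks with cached cross-products.

    Reusable across responses sharing the same rows (per-node model grids).
    """

    def __init__(self, x: np.ndarray, z_blocks: Sequence[np.ndarray],
                 names: Sequence[str]):
        self.x = x
        self.names = list(names)
        self.blocks = [np.asarray(z, float) for z in z_blocks]
        self.sizes = [z.shape[1] for z in self.blocks]
        self.z = np.hstack(self.blocks) if self.blocks else np.zeros((x.shape[0], 0))
        self.ztz = self.z.T @ self.z
        self.ztx = self.z.T @ self.x
        self.xtx = self.x.T @ self.x
        self.n, self.p = x.shape
        _check_full_rank(x, names)

    def prepare(self, y: np.ndarray):
        return {"zty": self.z.T @ y, "xty": self.x.T @ y,
                "yty": float(y @ y), "y": y}

    def _ginv_diag(self, log_gammas) -> np.ndarray:
        return np.concatenate([
            np.full(k, np.exp(-lg)) for k, lg in zip(self.sizes, log_gammas)
        ]) if self.sizes else np.zeros(0)

    def criterion(self, log_gammas, cache, reml: bool):
        """Profiled -2 log (restricted) likelihood up to an additive
        constant, via the Woodbury identity on the random-effect columns."""
        log_gammas = np.clip(np.asarray(log_gammas, float), *_LOG_GAMMA_BOUNDS)
        n, p = self.n, self.p
        m = self.ztz + np.diag(self._ginv_diag(log_gammas))
        try:
            cf = linalg.cho_factor(m, lower=True)
        except linalg.LinAlgError:
            return np.inf, None
        logdet_v = 2.0 * np.log(np.diag(cf[0])).sum() + float(
            np.dot(self.sizes, log_gammas)) if self.sizes else 0.0
        minv_ztx = linalg.cho_solve(cf, self.ztx) if self.sizes else self.ztx
        minv_zty = linalg.cho_solve(cf, cache["zty"]) if self.sizes else cache["zty"]
        xvx = self.xtx - self.ztx.T @ minv_ztx
        xvy = cache["xty"] - self.ztx.T @ minv_zty
        yvy = cache["yty"] - cache["zty"] @ minv_zty
        try:
            beta = np.linalg.solve(xvx, xvy)
        except np.linalg.LinAlgError:
            return np.inf, None
        q = float(yvy - beta @ xvy)
        if q <= 0:
            return np.inf, None
        if reml:
            sign, logdet_xx = np.linalg.slogdet(xvx)
            if sign <= 0:
                return np.inf, None
            crit = logdet_v + logdet_xx + (n - p) * np.log(q)
        else:
            crit = logdet_v + n * np.log(q)
        return crit, (cf, beta, q, log_gammas)

    def solve(self, y, reml=True, start=None):
        """Optimize variance ratios for one response; returns
        (log_gammas, aux, converged)."""
        cache = self.prepare(y)
        k = len(self.sizes)
        if k == 0:
            _, aux = self.criterion([], cache, reml)
            return np.zeros(0), aux, aux is not None, cache
        starts = []
        if start is not None:
            starts.append(np.asarray(start, float))
        starts.extend([np.zeros(k), np.full(k, -4.0), np.full(k, 3.0)])
        best, best_res = np.inf, None
        for s0 in starts:
            res = optimize.minimize(
                lambda lg: self.criterion(lg, cache, reml)[0], s0,
                method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 300},
            )
            if res.fun < best:
                best, best_res = res.fun, res
            if start is not None and res.success and np.isfinite(res.fun):
                break  # warm start succeeded; skip cold starts
        lg = np.clip(best_res.x, *_LOG_GAMMA_BOUNDS)
        crit, aux = self.criterion(lg, cache, reml)
        return lg, aux, bool(best_res.success and aux is not None), cache

    def blups(self, aux, cache):
        cf, beta, _, lg = aux
        if not self.sizes:
            return np.zeros(0)
        ztr = cache["zty"] - self.ztx @ beta
        g_diag = np.concatenate([
            np.full(k, np.exp(lgj)) for k, lgj in zip(self.sizes, lg)])
        return g_diag * (ztr - self.ztz @ linalg.cho_solve(cf, ztr))

    def edf_columns(self, log_gammas) -> np.ndarray:
        """Per-column effective degrees of freedom from the Henderson ridge
        system on [X, Z]; fixed columns are unpenalized."""
        ginv = self._ginv_diag(log_gammas)
        a = np.block([[self.xtx, self.ztx.T], [self.ztx, self.ztz]])
        b = a.copy()
        idx = np.arange(self.p, self.p + ginv.size)
        a[idx, idx] += ginv
        return np.diag(np.linalg.solve(a, b))


def build_design(age, covariates, subject, include_age=True, basis_dim=5,
                 covariate_names=None, standardize=True):
    """Assemble the :class:`MixedDesign` for the full or null model."""
    age = np.asarray(age, dtype=float)
    n = age.size
    if hasattr(covariates, "columns"):
        covariate_names = [str(c) for c in covariates.columns]
        c = covariates.to_numpy(dtype=float)
    else:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        if covariate_names is None:
            covariate_names = [f"cov{i}" for i in range(c.shape[1])]
    if np.isnan(c).any():
        raise ValueError("missing values in covariates")
    if include_age and np.unique(age).size < 3:
        raise ValueError("need >= 3 distinct ages to fit an age smooth")
    if standardize and c.size:
        sd = c.std(axis=0)
        c = np.where(sd > 0, (c - c.mean(axis=0)) / np.where(sd > 0, sd, 1.0), c)

    subj_codes, subj_idx = np.unique(subject, return_inverse=True)
    zu = np.zeros((n, subj_codes.size))
    zu[np.arange(n), subj_idx] = 1.0

    if include_age:
        x_lin, zs = pspline_basis(age, basis_dim)
        x = np.column_stack([np.ones(n), x_lin, c])
        names = ["intercept", "age"] + list(covariate_names)
        design = MixedDesign(x, [zs, zu], names)
        design.zs = zs
    else:
        x = np.column_stack([np.ones(n), c])
        names = ["intercept"] + list(covariate_names)
        design = MixedDesign(x, [zu], names)
        design.zs = None
    design.include_age = include_age
    design.n_covariates = len(covariate_names)
    design.subject_codes = subj_codes
    return design


def fit_gamm_design(design: MixedDesign, y: np.ndarray,
                    start=None, start_ml=None) -> GAMMFit:
    """Fit one response on a prebuilt design (REML, plus an ML pass for the
    likelihood-ratio test)."""
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("missing values in response")
    lg, aux, ok, cache = design.solve(y, reml=True, start=start)
    if aux is None:
        raise RuntimeError("REML optimization failed to produce a finite fit")
    cf, beta, q, lg = aux
    n, p = design.n, design.p
    sigma2 = q / (n - p)
    b_all = design.blups(aux, cache)
    if design.include_age:
        ks = design.sizes[0]
        gamma_s, gamma_u = np.exp(lg)
        b = b_all[:ks]
        u = b_all[ks:]
        fitted = design.x @ beta + design.zs @ b
    else:
        gamma_s, gamma_u = 0.0, float(np.exp(lg[0]))
        b, u = None, b_all
        fitted = design.x @ beta

    if design.include_age:
        edf_cols = design.edf_columns(lg)
        ks = design.sizes[0]
        edf_smooth = float(edf_cols[1] + edf_cols[p:p + ks].sum())
    else:
        edf_smooth = 0.0

    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_res = float(((y - fitted) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    df_model = design.n_covariates + edf_smooth
    denom = n - 1.0 - df_model
    r2_adj = 1.0 - (1.0 - r2) * (n - 1.0) / denom if denom > 1 else np.nan

    lg_ml, aux_ml, ok_ml, _ = design.solve(y, reml=False, start=start_ml)
    crit_ml = np.inf if aux_ml is None else design.criterion(lg_ml, design.prepare(y), reml=False)[0]

    return GAMMFit(
        beta=beta, fixed_names=design.names,
        var_spline=float(gamma_s * sigma2), var_subject=float(gamma_u * sigma2),
        sigma2=float(sigma2), edf_smooth=edf_smooth,
        r2=float(r2), r2_adj=float(r2_adj), fitted_marginal=fitted,
        minus2ll_ml=float(crit_ml), converged=bool(ok and ok_ml),
        n_obs=n, n_fixed=p, include_age=design.include_age,
        log_gamma_reml=lg, b_spline=b, u_subject=u,
    )


def fit_gamm(
    y: np.ndarray,
    age: np.ndarray,
    covariates,
    subject: np.ndarray,
    include_age: bool = True,
    basis_dim: int = 5,
    covariate_names: Optional[Sequence[str]] = None,
    standardize: bool = True,
) -> GAMMFit:
    """Fit the penalized-spline random-intercept model by REML.

    Parameters
    ----------
    y : (n,) response
    age : (n,) ages
    covariates : (n, c) array or DataFrame of fixed covariates
    subject : (n,) subject identifiers (any hashable)
    include_age : False fits the null model (covariates + random intercept
        only) used for the delta R^2 contrast
    basis_dim : spline basis dimension (default 5; three visit waves do not
        identify more)
    standardize : z-score continuous covariates before fitting

    Requires >= 3 distinct ages when the smooth is included.
    """
    design = build_design(age, covariates, subject, include_age=include_age,
                          basis_dim=basis_dim, covariate_names=covariate_names,
                          standardize=standardize)
    return fit_gamm_design(design, y)


def smooth_lrt_pvalue(full: GAMMFit, null: GAMMFit) -> float:
    """LRT p-value for the age smooth: ML criterion difference against a
    0.5*chi2(1) + 0.5*chi2(2) mixture (one fixed coefficient plus one
    variance component on its boundary)."""
    if full.n_obs != null.n_obs:
        raise ValueError("full and null fits use different rows")
    lam = max(null.minus2ll_ml - full.minus2ll_ml, 0.0)
    return float(0.5 * stats.chi2.sf(lam, 1) + 0.5 * stats.chi2.sf(lam, 2))
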
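"""Marginal linear models for family-clustered data.

Identity-link Gaussian generalized estimating equations with an
exchangeable working correlation, solved by iteratively reweighted
estimating equations. The exchangeable correlation is re-estimated each
iteration by the standard moment (Pearson-residual pair-product)
estimator, the scale uses the bias-corrected n − p denominator, and
standard errors are the cluster-robust (sandwich) estimator.

The exchangeable working inverse has the closed form

    R⁻¹ v = (v − c · 1·Σv) / (1 − ρ),   c = ρ / (1 + (m − 1)ρ),

so every per-cluster accumulation reduces to segment sums over rows
sorted by cluster (``np.add.reduceat``); there is no per-cluster Python
loop and fits stay cheap enough to re-run thousands of times inside the
cluster bootstrap.

``working="independence"`` gives ordinary least squares point estimates
with the same cluster-robust sandwich — the "OLS with robust SEs"
reading of GEE-for-standard-errors-only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConvergenceError, RankDeficiencyError, SingleClusterError

__all__ = ["ModelSpec", "GEEFit", "fit_gee", "wald_pvalue"]

INTERCEPT = "Intercept"


@dataclass(frozen=True)
class ModelSpec:
    """One marginal linear model: response ~ 1 + regressors, clustered."""

    response: str
    regressors: tuple[str, ...]
    cluster: str = "family_id"

    def __post_init__(self) -> None:
        if self.response in self.regressors:
            raise ValueError(f"response {self.response!r} appears among regressors")

    @property
    def terms(self) -> list[str]:
        return [INTERCEPT, *self.regressors]


@dataclass
class GEEFit:
    """Coefficients and cluster-robust inference for one marginal model."""

    spec: ModelSpec
    params: pd.Series
    robust_se: pd.Series | None
    rho: float                 # estimated exchangeable correlation
    scale: float               # residual variance, denominator n − p
    n_obs: int
    n_clusters: int
    converged: bool
    n_iter: int
    working: str = "exchangeable"

    def summary_frame(self) -> pd.DataFrame:
        """Term / estimate / robust SE / p table (one row per coefficient)."""
        out = pd.DataFrame({"term": self.params.index, "estimate": self.params.values})
        if self.robust_se is not None:
            z = self.params.values / self.robust_se.values
            out["robust_se"] = self.robust_se.values
            out["p_value"] = 2.0 * stats.norm.sf(np.abs(z))
        return out


class _ClusteredDesign:
    """Design sorted by cluster, with segment-sum helpers."""

    def __init__(self, x: np.ndarray, y: np.ndarray, codes: np.ndarray):
        order = np.argsort(codes, kind="stable")
        sorted_codes = codes[order]
        self.starts = np.flatnonzero(np.r_[True, np.diff(sorted_codes) != 0])
        self.sizes = np.diff(np.r_[self.starts, codes.size])
        self.x = x[order]
        self.y = y[order]
        self.n, self.p = x.shape
        self.n_clusters = self.starts.size
        self.m_max = int(self.sizes.max())
        self.xtx = self.x.T @ self.x
        self.xty = self.x.T @ self.y
        self.sx = np.add.reduceat(self.x, self.starts, axis=0)  # per-cluster Σx
        self.sy = np.add.reduceat(self.y, self.starts)
        self.n_pairs = int((self.sizes * (self.sizes - 1) // 2).sum())

    def estimate_rho(self, resid: np.ndarray, scale: float) -> float:
        """Moment estimator: mean within-cluster pair product of Pearson
        residuals, with p subtracted from the pair count."""
        if self.n_pairs == 0:
            return 0.0
        e = resid / np.sqrt(scale)
        se = np.add.reduceat(e, self.starts)
        se2 = np.add.reduceat(e * e, self.starts)
        pair_sum = float(((se * se - se2) / 2.0).sum())
        denom = self.n_pairs - self.p if self.n_pairs > self.p else self.n_pairs
        return pair_sum / denom

    def weighted_normal_equations(self, rho: float) -> tuple[np.ndarray, np.ndarray]:
        c = rho / (1.0 + (self.sizes - 1.0) * rho)
        a = (self.xtx - (self.sx * c[:, None]).T @ self.sx) / (1.0 - rho)
        b = (self.xty - self.sx.T @ (c * self.sy)) / (1.0 - rho)
        return a, b

    def sandwich(self, resid: np.ndarray, rho: float) -> np.ndarray:
        c = rho / (1.0 + (self.sizes - 1.0) * rho)
        a, _ = self.weighted_normal_equations(rho)
        xr = np.add.reduceat(self.x * resid[:, None], self.starts, axis=0)
        sr = np.add.reduceat(resid, self.starts)
        g = (xr - (c * sr)[:, None] * self.sx) / (1.0 - rho)  # per-cluster scores
        bread = np.linalg.inv(a)
        return bread @ (g.T @ g) @ bread


def fit_gee(
    data: pd.DataFrame,
    spec: ModelSpec,
    working: str = "exchangeable",
    compute_se: bool = True,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> GEEFit:
    """Fit one marginal linear model.

    Convergence: max absolute coefficient change < ``tol`` (default
    1e−8) within ``maxiter`` iterations, else :class:`ConvergenceError`.
    Requires at least two clusters and a full-rank design.
    """
    if working not in ("exchangeable", "independence"):
        raise ValueError(f"unknown working correlation {working!r}")
    y = data[spec.response].to_numpy(dtype=float)
    n = y.size
    x = np.empty((n, len(spec.regressors) + 1))
    x[:, 0] = 1.0
    for j, c in enumerate(spec.regressors):
        x[:, j + 1] = data[c].to_numpy(dtype=float)
    p = x.shape[1]
    codes = pd.factorize(data[spec.cluster])[0]
    design = _ClusteredDesign(x, y, codes)
    if design.n_clusters < 2:
        raise SingleClusterError("need at least two clusters")
    if np.linalg.matrix_rank(x) < p:
        raise RankDeficiencyError(f"design for {spec.response!r} is rank deficient")

    rho_floor = -1.0 / (design.m_max - 1) + 1e-6 if design.m_max > 1 else 0.0

    beta, *_ = np.linalg.lstsq(design.x, design.y, rcond=None)
    rho = 0.0
    # Singleton-only clustering makes the working correlation irrelevant:
    # the estimating equations reduce to OLS with no iteration needed.
    iterate = working == "exchangeable" and design.m_max > 1
    converged = not iterate
    n_iter = 0
    if iterate:
        for n_iter in range(1, maxiter + 1):
            resid = design.y - design.x @ beta
            scale = (resid @ resid) / (n - p)
            rho = float(np.clip(design.estimate_rho(resid, scale),
                                rho_floor, 0.9999))
            a_mat, b_vec = design.weighted_normal_equations(rho)
            beta_new = np.linalg.solve(a_mat, b_vec)
            delta = float(np.max(np.abs(beta_new - beta)))
            beta = beta_new
            if delta < tol:
                converged = True
                break
        if not converged:
            raise ConvergenceError(
                f"GEE for {spec.response!r} did not converge in {maxiter} iterations"
            )

    resid = design.y - design.x @ beta
    scale = float((resid @ resid) / (n - p))
    if iterate:
        rho = float(np.clip(design.estimate_rho(resid, scale), rho_floor, 0.9999))

    robust_se = None
    if compute_se:
        cov = design.sandwich(resid, rho)
        robust_se = pd.Series(np.sqrt(np.diag(cov)), index=spec.terms)

    return GEEFit(
        spec=spec,
        params=pd.Series(beta, index=spec.terms),
        robust_se=robust_se,
        rho=rho,
        scale=scale,
        n_obs=n,
        n_clusters=design.n_clusters,
        converged=converged,
        n_iter=n_iter,
        working=working,
    )


def wald_pvalue(fit: GEEFit, coefficient: str) -> float:
    """Two-sided normal-reference Wald p-value for one coefficient."""
    if coefficient not in fit.params.index:
        raise KeyError(f"unknown coefficient {coefficient!r}")
    if fit.robust_se is None:
        raise ValueError("fit was computed without standard errors")
    z = fit.params[coefficient] / fit.robust_se[coefficient]
    return float(2.0 * stats.norm.sf(abs(z)))
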
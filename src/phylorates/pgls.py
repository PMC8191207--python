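"""Phylogenetic generalized least squares with Pagel's λ estimated by
maximum likelihood.

The model is ``y = β₀ + β₁ x + ε`` with ``ε ~ N(0, σ² V(λ))`` where
``V(λ)`` is the Brownian-motion covariance of the tree with off-diagonal
entries scaled by λ ∈ [0, 1].  λ is profiled out by maximizing the Gaussian
likelihood (coarse grid then bounded scalar refinement); at the optimum the
slope, its standard error and a two-sided t-test with n−2 degrees of freedom
are reported.  λ = 0 reduces exactly to ordinary least squares; λ = 1 is the
pure Brownian model.

In the genome scan, ``y`` is the log10 root-to-tip ω of one gene and ``x``
is a log10 phenotype (head-body length in cm or body mass in g).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .errors import FitError, TooFewSpeciesError
from .phylo import PhyloCovariance, PhyloTree, lambda_transform, vcv_matrix

__all__ = [
    "PGLSFit",
    "gls_fit",
    "profile_lambda",
    "pgls_gene",
    "DEFAULT_MIN_SPECIES",
]

DEFAULT_MIN_SPECIES = 10
LAMBDA_GRID_STEP = 0.05
LAMBDA_TOL = 1e-6


@dataclass
class PGLSFit:
    """Result of a (phylogenetic) GLS regression of y on a single predictor."""

    n: int
    intercept: float
    slope: float
    slope_se: float
    t_stat: float
    p_value: float
    sigma2_hat: float          # unbiased (n-2 divisor), used for the t-test
    loglik: float              # ML profile log-likelihood
    residuals: np.ndarray      # response scale, in species order
    lambda_hat: float | None = None
    species: list[str] | None = None


def gls_fit(y: np.ndarray, x: np.ndarray, V: np.ndarray) -> PGLSFit:
    """Generalized least squares of ``y`` on ``[1, x]`` with error covariance
    ``σ² V``.

    Point estimates are ``β̂ = (XᵀV⁻¹X)⁻¹ XᵀV⁻¹y``; the reported σ̂² uses the
    unbiased n−2 divisor (t-test convention) while the log-likelihood uses
    the ML divisor n.  ``V`` must be symmetric positive definite.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    V = np.asarray(V, dtype=float)
    n = y.size
    if x.size != n or V.shape != (n, n):
        raise FitError(f"shape mismatch: y {y.shape}, x {x.shape}, V {V.shape}")
    if n < 3:
        raise TooFewSpeciesError(f"need at least 3 observations, got {n}")
    if np.ptp(x) == 0:
        raise FitError("constant predictor: slope undefined")
    try:
        cf = cho_factor(V, lower=True)
    except LinAlgError as exc:
        raise FitError(f"covariance matrix not positive definite: {exc}") from exc

    X = np.column_stack([np.ones(n), x])
    ViX = cho_solve(cf, X)
    Viy = cho_solve(cf, y)
    XtViX = X.T @ ViX
    beta = np.linalg.solve(XtViX, X.T @ Viy)
    r = y - X @ beta
    quad = float(r @ cho_solve(cf, r))
    sigma2 = quad / (n - 2)
    cov_beta = sigma2 * np.linalg.inv(XtViX)
    se = float(np.sqrt(cov_beta[1, 1]))
    t = float(beta[1] / se)
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    logdetV = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    sigma2_ml = quad / n
    loglik = -0.5 * (n * np.log(2.0 * np.pi * sigma2_ml) + logdetV + n)
    return PGLSFit(n=n, intercept=float(beta[0]), slope=float(beta[1]),
                   slope_se=se, t_stat=t, p_value=p, sigma2_hat=sigma2,
                   loglik=float(loglik), residuals=r)


def profile_lambda(y: np.ndarray, x: np.ndarray,
                   C: PhyloCovariance | np.ndarray) -> PGLSFit:
    """Maximize the GLS log-likelihood over λ ∈ [0, 1] and return the fit at
    the maximizer.

    Coarse grid (step 0.05) followed by bounded scalar refinement around the
    best grid point; the profile likelihood can be flat or multi-modal near
    the boundaries, so the refined value is kept only when it does not fall
    below the grid optimum.
    """
    M = C.matrix if isinstance(C, PhyloCovariance) else np.asarray(C, dtype=float)

    def ll(lam: float) -> float:
        return gls_fit(y, x, lambda_transform(M, lam)).loglik

    grid = np.arange(0.0, 1.0 + 1e-12, LAMBDA_GRID_STEP)
    grid_ll = np.array([ll(g) for g in grid])
    k = int(np.argmax(grid_ll))
    lo = max(0.0, grid[k] - LAMBDA_GRID_STEP)
    hi = min(1.0, grid[k] + LAMBDA_GRID_STEP)
    res = optimize.minimize_scalar(lambda lam: -ll(lam), bounds=(lo, hi),
                                   method="bounded",
                                   options={"xatol": LAMBDA_TOL})
    lam_hat, best_ll = float(grid[k]), float(grid_ll[k])
    if res.success and -res.fun >= best_ll:
        lam_hat, best_ll = float(np.clip(res.x, 0.0, 1.0)), float(-res.fun)
    fit = gls_fit(y, x, lambda_transform(M, lam_hat))
    return replace(fit, lambda_hat=lam_hat)


def pgls_gene(rtt: pd.DataFrame, phenotype: pd.Series, tree: PhyloTree,
              min_species: int = DEFAULT_MIN_SPECIES,
              fixed_lambda: float | None = None,
              log_transform_phenotype: bool = True) -> PGLSFit:
    """PGLS of one gene's log10 root-to-tip ω on a log10 phenotype.

    ``rtt`` holds that gene's rows of the root-to-tip table (columns
    ``species`` and ``log10_omega_bar``); ``phenotype`` maps species to the
    raw phenotype value (g or cm), log10-transformed here unless
    ``log_transform_phenotype`` is False.  Species with undefined ω or
    missing phenotype are dropped; fewer than ``min_species`` complete cases
    raises :class:`TooFewSpeciesError`.  The phylogenetic covariance is built
    on exactly the species used.
    """
    yv = rtt.set_index("species")["log10_omega_bar"].astype(float)
    ph = phenotype.astype(float)
    if log_transform_phenotype:
        with np.errstate(divide="ignore", invalid="ignore"):
            ph = np.log10(ph)
    common = [s for s in yv.index if s in ph.index
              and np.isfinite(yv[s]) and np.isfinite(ph[s])]
    if len(common) < min_species:
        raise TooFewSpeciesError(
            f"{len(common)} species with complete data; minimum is {min_species}"
        )
    C = vcv_matrix(tree, common)
    y = yv.loc[common].to_numpy()
    x = ph.loc[common].to_numpy()
    if fixed_lambda is not None:
        fit = gls_fit(y, x, lambda_transform(C, fixed_lambda))
        fit = replace(fit, lambda_hat=float(fixed_lambda))
    else:
        fit = profile_lambda(y, x, C)
    return replace(fit, species=list(common))
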
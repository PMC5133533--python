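"""Covariate-only linear mixed model shared by all per-window score tests.

The phenotype model under the null of no rare-variant effect is

    Y = X gamma + delta + eps,
    delta ~ N(0, sigma2_g * 2*Phi),   eps ~ N(0, sigma2_e * I),

with X = [1 Z] the fixed-effect design (intercept plus covariates) and
2*Phi the pedigree relatedness structure.  Variance components are
estimated by REML; the fit is performed once genome-wide and every
window's score test reuses its projection quantities, so the expensive
object is the one-time eigendecomposition of 2*Phi.

With V = sigma2_g * 2*Phi + sigma2_e * I the projection matrix is

    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1,

which annihilates X and gives the score-test residuals P*Y.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = ["NullModelError", "PhenotypeTable", "NullModelFit", "fit_null",
           "score_residuals", "read_phenotypes"]


class NullModelError(RuntimeError):
    pass


@dataclass
class PhenotypeTable:
    """Analyzed individuals with their trait values and covariate design."""

    ids: list[str]
    y: np.ndarray            # trait vector, length n
    covariates: np.ndarray   # n x p covariate block Z (no intercept column)
    covariate_names: list[str]
    n_dropped_missing: int = 0

    @property
    def design(self) -> np.ndarray:
        """Full fixed-effect design X = [1 Z]."""
        return np.column_stack([np.ones(len(self.y)), self.covariates])


def read_phenotypes(path, trait: str, covariates: Sequence[str],
                    id_column: str = "id") -> PhenotypeTable:
    """Read a phenotype/covariate TSV, dropping rows with missing values."""
    df = pd.read_csv(path, sep="\t", dtype={id_column: str})
    needed = [id_column, trait, *covariates]
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise NullModelError(f"phenotype table missing columns: {missing_cols}")
    sub = df[needed]
    complete = sub.dropna()
    n_dropped = len(sub) - len(complete)
    return PhenotypeTable(
        ids=list(complete[id_column]),
        y=complete[trait].to_numpy(float),
        covariates=complete[list(covariates)].to_numpy(float),
        covariate_names=list(covariates),
        n_dropped_missing=n_dropped,
    )


@dataclass
class NullModelFit:
    gamma_hat: np.ndarray
    sigma2_g: float
    sigma2_e: float
    mu_hat: np.ndarray
    converged: bool
    # spectral internals: 2*Phi = U diag(d) U'
    _U: np.ndarray = field(repr=False)
    _d: np.ndarray = field(repr=False)
    _X: np.ndarray = field(repr=False)
    _y: np.ndarray = field(repr=False)
    _reml_loglik: float = 0.0

    def __post_init__(self) -> None:
        # diagonal of V in the eigenbasis, and reusable cross-products
        self._v = self.sigma2_g * self._d + self.sigma2_e
        self._Xt = self._U.T @ self._X
        self._yt = self._U.T @ self._y
        WX = self._Xt / self._v[:, None]
        self._WX = WX
        self._XtVinvX = self._Xt.T @ WX
        self._XtVinvX_inv = np.linalg.inv(self._XtVinvX)
        rt = self._yt - self._Xt @ self.gamma_hat
        self._resid_proj = self._U @ (rt / self._v)

    # -- quantities the association layer consumes ------------------------

    @property
    def n(self) -> int:
        return len(self._y)

    @property
    def resid_df(self) -> int:
        """Residual degrees of freedom n - p of the fixed-effect fit."""
        return len(self._y) - self._X.shape[1]

    @property
    def residuals(self) -> np.ndarray:
        """Raw residuals Y - mu_hat."""
        return self._y - self.mu_hat

    @property
    def resid_proj(self) -> np.ndarray:
        """Projection-weighted residuals P @ Y = V^-1 (Y - X gamma_hat)."""
        return self._resid_proj

    @property
    def P(self) -> np.ndarray:
        """The full n x n projection matrix (materialised on demand)."""
        Vinv = (self._U / self._v) @ self._U.T
        VinvX = Vinv @ self._X
        return Vinv - VinvX @ self._XtVinvX_inv @ VinvX.T

    def rotate(self, G: np.ndarray) -> np.ndarray:
        """Rotate a genotype block into the eigenbasis (cacheable per window)."""
        return self._U.T @ G

    def quadratics(self, G: np.ndarray, Gt: Optional[np.ndarray] = None
                   ) -> tuple[np.ndarray, np.ndarray]:
        """Return (G' P y, G' P G) without forming P.

        ``Gt`` may pass a precomputed ``rotate(G)`` — the rotation is the
        dominant cost and is constant across phenotype replicates.
        """
        if Gt is None:
            Gt = self.rotate(G)
        GPy = G.T @ self._resid_proj
        WG = Gt / self._v[:, None]
        B = self._Xt.T @ WG  # p x m
        GPG = Gt.T @ WG - B.T @ (self._XtVinvX_inv @ B)
        return GPy, GPG


def _profiled_neg_reml(log_lam: float, d: np.ndarray, Xt: np.ndarray,
                       yt: np.ndarray) -> float:
    """Negative REML log-likelihood profiled over sigma2_e, at ratio
    lam = sigma2_g / sigma2_e (log scale input)."""
    lam = np.exp(log_lam)
    n, p = Xt.shape
    v = lam * d + 1.0
    w = 1.0 / v
    WX = Xt * w[:, None]
    XtWX = Xt.T @ WX
    try:
        beta = np.linalg.solve(XtWX, WX.T @ yt)
    except np.linalg.LinAlgError as err:
        raise NullModelError("singular fixed-effect design") from err
    r = yt - Xt @ beta
    rss = float(np.sum(w * r * r))
    sigma2_e = rss / (n - p)
    _sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    ll = -0.5 * (
        (n - p) * np.log(sigma2_e)
        + float(np.sum(np.log(v)))
        + logdet_XtWX
        + (n - p)
    )
    return -ll


def fit_null(y: np.ndarray, X: np.ndarray, covstruct: Optional[np.ndarray] = None,
             eig: Optional[tuple[np.ndarray, np.ndarray]] = None,
             max_log_ratio: float = 12.0) -> NullModelFit:
    """Fit the covariate-only mixed model by REML.

    Parameters
    ----------
    y, X
        Trait vector and fixed-effect design [1 Z].
    covstruct
        The relatedness covariance 2*Phi (PSD).  May be omitted when
        ``eig`` supplies its precomputed eigendecomposition ``(d, U)``,
        which lets simulation loops amortise the one-time cost.
    max_log_ratio
        Upper bound for log(sigma2_g / sigma2_e) in the profiled search.

    The variance ratio lam = sigma2_g/sigma2_e is profiled on the log
    scale with sigma2_e concentrated out analytically; the boundary
    lam = 0 (no polygenic component) is evaluated explicitly and kept
    when it dominates.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if y.shape != (n,):
        raise NullModelError("y and X have incompatible shapes")
    if np.linalg.matrix_rank(X) < p:
        raise NullModelError("fixed-effect design X is rank-deficient")
    if eig is None:
        if covstruct is None:
            raise NullModelError("either covstruct or its eigendecomposition required")
        d, U = np.linalg.eigh(np.asarray(covstruct, dtype=float))
        d = np.clip(d, 0.0, None)
    else:
        d, U = eig
        d = np.clip(np.asarray(d, dtype=float), 0.0, None)

    Xt = U.T @ X
    yt = U.T @ y

    res = optimize.minimize_scalar(
        _profiled_neg_reml,
        bounds=(-20.0, max_log_ratio),
        args=(d, Xt, yt),
        method="bounded",
        options={"xatol": 1e-10},
    )
    candidates = [(float(res.fun), float(np.exp(res.x)))]
    # explicit boundary: no polygenic variance at all
    candidates.append((_profiled_neg_reml(-np.inf if False else -745.0, d, Xt, yt), 0.0))
    best_negll, lam = min(candidates, key=lambda t: t[0])

    v = lam * d + 1.0
    w = 1.0 / v
    WX = Xt * w[:, None]
    XtWX = Xt.T @ WX
    gamma = np.linalg.solve(XtWX, WX.T @ yt)
    r = yt - Xt @ gamma
    sigma2_e = float(np.sum(w * r * r)) / (n - p)
    sigma2_g = lam * sigma2_e
    if sigma2_e <= 0:
        raise NullModelError("estimated residual variance is not positive")

    fit = NullModelFit(
        gamma_hat=gamma,
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        mu_hat=X @ gamma,
        converged=bool(res.success),
        _U=U,
        _d=d,
        _X=X,
        _y=y,
        _reml_loglik=-best_negll,
    )
    return fit


def score_residuals(fit: NullModelFit, y: Optional[np.ndarray] = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Residual vector (Y - mu_hat) and the projection matrix P.

    ``P @ Y`` equals the V^-1-weighted residuals of the GLS fit; the
    association layer consumes both through :class:`NullModelFit`, this
    helper exposes them directly for diagnostics.
    """
    if y is not None and not np.array_equal(y, fit._y):
        raise NullModelError("score_residuals must use the fitted trait vector")
    return fit.residuals, fit.P
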
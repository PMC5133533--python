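"""Per-window rare-variant association tests under the shared null model.

Six score tests run per window, three kernel-type and three burden-type:

* ``SKAT``    — weighted quadratic form with Beta(1,25)-density weights,
* ``uwSKAT``  — the same with equal weights,
* ``regSKAT`` — variance-scale weights from the functional-category
  transform ``w_j^2 = (7 - s_j)^2``,
* ``T5``      — flat burden of rare alleles (all filtered variants get
  weight 1),
* ``MB``      — Madsen-Browning burden with ``w_j = 1/(MAF_j(1-MAF_j))``,
* ``regT5``   — burden weighted by the functional-category transform.

The kernel statistic is ``T = sum_j w_j^2 (sum_i (Y_i - mu_i) G_ij)^2``
where the residuals are the projection-weighted residuals ``P Y`` of the
mixed null fit; its null distribution is the eigenvalue mixture of
``W^{1/2} G' P G W^{1/2}``.  Burden tests collapse to a single score with
a 1-df chi-square reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._quadform import EIGEN_RTOL, quadform_ratio_tail
from .annotate import category_values
from .nullmodel import NullModelFit

__all__ = [
    "GenotypeWindow", "TestResult", "filter_rare", "variance_weights",
    "burden_weights", "skat_statistic", "skat_pvalue", "burden_test",
    "run_window", "bonferroni_threshold", "SKAT_METHODS", "BURDEN_METHODS",
    "ALL_METHODS",
]

SKAT_METHODS = ("SKAT", "uwSKAT", "regSKAT")
BURDEN_METHODS = ("T5", "MB", "regT5")
ALL_METHODS = SKAT_METHODS + BURDEN_METHODS


@dataclass
class GenotypeWindow:
    """Minor-allele count matrix for one window after the rarity filter.

    ``G`` is n x m with entries in [0, 2] (imputed values may be
    fractional), columns folded so the counted allele is minor;
    ``kept`` maps columns back to the window's original variant slots.
    """

    G: np.ndarray
    mafs: np.ndarray
    kept: np.ndarray

    @property
    def m(self) -> int:
        return self.G.shape[1]


@dataclass
class TestResult:
    window_label: str
    method: str
    statistic: float
    p_value: float
    m_used: int
    flag: str = "ok"   # p-value path: ok/exact/imhof/liu/degenerate


def filter_rare(G_raw: np.ndarray, maf_threshold: float = 0.05
                ) -> Optional[GenotypeWindow]:
    """Fold, impute and rarity-filter a raw genotype window.

    Alleles are folded so MAF <= 0.5; missing entries (NaN) are imputed
    to twice the observed MAF; monomorphic columns and columns at or
    above the threshold are dropped (strict ``< threshold``).  Returns
    ``None`` when no column survives — the window is skipped, not an
    error.
    """
    G = np.array(G_raw, dtype=float)
    if G.ndim != 2:
        raise ValueError("genotype window must be 2-D (samples x variants)")
    n, m = G.shape
    obs = ~np.isnan(G)
    n_obs = obs.sum(axis=0)
    if np.any(n_obs == 0):
        keep0 = n_obs > 0
        G, obs, n_obs = G[:, keep0], obs[:, keep0], n_obs[keep0]
        kept0 = np.flatnonzero(keep0)
    else:
        kept0 = np.arange(m)
    af = np.nansum(G, axis=0) / (2.0 * n_obs)
    flip = af > 0.5
    G[:, flip] = 2.0 - G[:, flip]
    af = np.where(flip, 1.0 - af, af)
    # impute missing to the expected count under HWE at the observed MAF
    if (~obs).any():
        fill = np.broadcast_to(2.0 * af, G.shape)
        G = np.where(obs, G, fill)
    keep = (af > 0.0) & (af < maf_threshold)
    if not keep.any():
        return None
    return GenotypeWindow(G=G[:, keep], mafs=af[keep], kept=kept0[keep])


def _reg_transform(cats: np.ndarray) -> np.ndarray:
    return (7.0 - cats) ** 2


def variance_weights(method: str, mafs: np.ndarray,
                     categories=None) -> np.ndarray:
    """Variance-scale weights w_j^2 for the kernel-test family."""
    mafs = np.asarray(mafs, dtype=float)
    if method == "SKAT":
        w = 25.0 * (1.0 - mafs) ** 24  # Beta(1,25) density
        return w * w
    if method == "uwSKAT":
        return np.ones_like(mafs)
    if method == "regSKAT":
        if categories is None:
            raise ValueError("regSKAT requires functional categories")
        return _reg_transform(category_values(categories))
    raise ValueError(f"unknown kernel method {method!r}")


def burden_weights(method: str, mafs: np.ndarray,
                   categories=None) -> np.ndarray:
    """Collapsing weights w_j for the burden-test family."""
    mafs = np.asarray(mafs, dtype=float)
    if method == "T5":
        # the MAF<threshold indicator is realised by the upstream filter
        return np.ones_like(mafs)
    if method == "MB":
        return 1.0 / (mafs * (1.0 - mafs))
    if method == "regT5":
        if categories is None:
            raise ValueError("regT5 requires functional categories")
        return _reg_transform(category_values(categories))
    raise ValueError(f"unknown burden method {method!r}")


def skat_statistic(win: GenotypeWindow, wsq: np.ndarray,
                   resid: np.ndarray) -> float:
    """Kernel statistic sum_j w_j^2 (G_j' resid)^2 at the projected residuals."""
    wsq = np.asarray(wsq, dtype=float)
    if wsq.shape != (win.m,):
        raise ValueError("weights and window variant count disagree")
    U = win.G.T @ resid
    return float(np.sum(wsq * U * U))


def skat_pvalue(statistic: float, win: GenotypeWindow, wsq: np.ndarray,
                fit: NullModelFit, GPG: Optional[np.ndarray] = None
                ) -> tuple[float, str]:
    """Analytic p-value of the kernel statistic.

    Asymptotically the null distribution is ``sum_k lambda_k chi2_1``
    with lambda_k the eigenvalues of ``W^{1/2} G' P G W^{1/2}``.
    Because the projection P carries the REML-estimated residual
    variance, which shares degrees of freedom with the statistic, the
    p-value is computed from the exact finite-sample null of the
    variance-scaled ratio instead of the plug-in mixture (the same
    refinement that distinguishes a t-test from a z-test); the two
    coincide as the residual degrees of freedom grow.  ``GPG`` may pass
    the precomputed quadratic ``G' P G``.
    """
    if GPG is None:
        _, GPG = fit.quadratics(win.G)
    w = np.sqrt(np.asarray(wsq, dtype=float))
    K = (w[:, None] * GPG) * w[None, :]
    lam = np.linalg.eigvalsh(K)
    return quadform_ratio_tail(statistic, lam, fit.resid_df)


def burden_test(win: GenotypeWindow, w: np.ndarray, fit: NullModelFit,
                window_label: str, method: str = "T5",
                quad: Optional[tuple[np.ndarray, np.ndarray]] = None
                ) -> TestResult:
    """1-df score test of the collapsed burden b_i = sum_j w_j G_ij.

    The reference distribution is the exact finite-sample null of the
    ratio statistic (equivalent to the classical t/F test of adding the
    burden to the regression), which converges to the 1-df chi-square
    as the residual degrees of freedom grow.
    """
    w = np.asarray(w, dtype=float)
    if w.shape != (win.m,):
        raise ValueError("weights and window variant count disagree")
    if quad is None:
        quad = fit.quadratics(win.G)
    GPy, GPG = quad
    bPy = float(w @ GPy)
    bPb = float(w @ GPG @ w)
    if bPb <= EIGEN_RTOL * max(1.0, float(np.abs(GPG).max()) * float(np.sum(w * w))):
        return TestResult(window_label, method, 0.0, 1.0, win.m, "degenerate")
    stat = bPy * bPy / bPb
    p, _flag = quadform_ratio_tail(stat, np.ones(1), fit.resid_df)
    return TestResult(window_label, method, stat, max(p, np.finfo(float).tiny),
                      win.m, "ok")


def run_window(win: GenotypeWindow, fit: NullModelFit, categories,
               window_label: str) -> list[TestResult]:
    """All six tests for one window, sharing one set of projection quadratics."""
    cats = category_values(categories)
    if cats.shape != (win.m,):
        raise ValueError("categories and window variant count disagree")
    Gt = fit.rotate(win.G)
    GPy, GPG = fit.quadratics(win.G, Gt=Gt)
    resid = fit.resid_proj
    results: list[TestResult] = []
    for method in SKAT_METHODS:
        wsq = variance_weights(method, win.mafs, cats)
        stat = skat_statistic(win, wsq, resid)
        p, flag = skat_pvalue(stat, win, wsq, fit, GPG=GPG)
        results.append(TestResult(window_label, method, stat,
                                  max(p, np.finfo(float).tiny), win.m, flag))
    for method in BURDEN_METHODS:
        w = burden_weights(method, win.mafs, cats)
        results.append(burden_test(win, w, fit, window_label, method,
                                   quad=(GPy, GPG)))
    return results


def bonferroni_threshold(n_tests: int, fwer: float = 0.05
                         ) -> tuple[float, float]:
    """Per-test significance level controlling the FWER, and its -log10."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    alpha = fwer / n_tests
    return alpha, float(-np.log10(alpha))
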
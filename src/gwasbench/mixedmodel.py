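"""REML mixed-model core shared by the kinship-based association models.

The model is y = X b + u + e with Var(u) = sigma_a^2 K and
Var(e) = sigma_e^2 I.  A single eigendecomposition of K reduces the
restricted likelihood to a 1-D function of the variance ratio
lambda = sigma_a^2 / sigma_e^2, optimized by a coarse log-grid followed by
bounded scalar refinement.  Generalized-least-squares Wald scans reuse the
same eigen-transform: with w_i = lambda * s_i + 1 the rotated model is an
ordinary weighted regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .containers import ParameterError

_LOG10_LAM_RANGE = (-6.0, 6.0)
_GRID_POINTS = 49


class CollinearityError(ParameterError):
    """The fixed-effect design is rank deficient."""


@dataclass
class VarianceComponents:
    sigma_a2: float
    sigma_e2: float
    log_reml: float

    @property
    def ratio(self) -> float:
        """lambda = sigma_a^2 / sigma_e^2."""
        return self.sigma_a2 / self.sigma_e2 if self.sigma_e2 > 0 else np.inf

    @property
    def h2(self) -> float:
        tot = self.sigma_a2 + self.sigma_e2
        return self.sigma_a2 / tot if tot > 0 else 0.0

    def __iter__(self):
        return iter((self.sigma_a2, self.sigma_e2, self.log_reml))


def check_full_rank(X: np.ndarray, names: list[str] | None = None) -> None:
    """Raise :class:`CollinearityError` naming the collinear columns."""
    n, p = X.shape
    if p == 0:
        return
    r = np.linalg.matrix_rank(X)
    if r == p:
        return
    # greedy identification of columns not adding rank
    bad = []
    kept = np.empty((n, 0))
    for j in range(p):
        cand = np.column_stack([kept, X[:, j]])
        if np.linalg.matrix_rank(cand) > kept.shape[1]:
            kept = cand
        else:
            bad.append(names[j] if names else str(j))
    raise CollinearityError(f"fixed-effect design is rank deficient; collinear columns: {bad}")


def eigen_kinship(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of a (stabilized) kinship matrix.

    Small negative eigenvalues from numerical noise or non-PSD group
    summaries are clipped at zero.
    """
    K = (K + K.T) / 2.0
    s, U = np.linalg.eigh(K)
    return np.clip(s, 0.0, None), U


def reml_loglik(
    lam: float, yt: np.ndarray, Xt: np.ndarray, s: np.ndarray, logdet_xtx: float
) -> float:
    """Restricted log-likelihood at variance ratio lambda (profile over
    sigma_e^2), in the eigenrotated basis."""
    n, p = Xt.shape
    w = lam * s + 1.0
    wi = 1.0 / w
    xtwx = Xt.T @ (Xt * wi[:, None])
    xtwy = Xt.T @ (yt * wi)
    try:
        beta = np.linalg.solve(xtwx, xtwy)
    except np.linalg.LinAlgError:
        return -np.inf
    r = yt - Xt @ beta
    q = float(r @ (r * wi))
    if q <= 0:
        return -np.inf
    sign, logdet_w = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return -np.inf
    sigma_e2 = q / (n - p)
    return -0.5 * (
        (n - p) * (np.log(2.0 * np.pi * sigma_e2) + 1.0)
        + np.sum(np.log(w))
        + logdet_w
        - logdet_xtx
    )


def ml_loglik(lam: float, yt: np.ndarray, Xt: np.ndarray, s: np.ndarray) -> float:
    """Full (unrestricted) log-likelihood at ratio lambda, profiled over
    sigma_e^2 at the GLS coefficient estimates."""
    n = len(yt)
    w = lam * s + 1.0
    wi = 1.0 / w
    xtwx = Xt.T @ (Xt * wi[:, None])
    beta = np.linalg.solve(xtwx, Xt.T @ (yt * wi))
    r = yt - Xt @ beta
    sigma_e2 = float(r @ (r * wi)) / n
    return -0.5 * (n * (np.log(2.0 * np.pi * sigma_e2) + 1.0) + np.sum(np.log(w)))


def fit_variance_components(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
    column_names: list[str] | None = None,
) -> VarianceComponents:
    """EMMA-style REML estimate of (sigma_a^2, sigma_e^2).

    ``eig`` may carry a precomputed ``(s, U)`` eigendecomposition of K so
    repeated fits against the same kinship share one decomposition.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n != len(y):
        raise ParameterError("y and X have incompatible shapes")
    check_full_rank(X, column_names)
    s, U = eig if eig is not None else eigen_kinship(K)
    yt = U.T @ y
    Xt = U.T @ X
    sign, logdet_xtx = np.linalg.slogdet(X.T @ X)

    grid = np.linspace(*_LOG10_LAM_RANGE, _GRID_POINTS)
    vals = np.array([reml_loglik(10.0**g, yt, Xt, s, logdet_xtx) for g in grid])
    best = int(np.argmax(vals))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda g: -reml_loglik(10.0**g, yt, Xt, s, logdet_xtx),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    cand = [(vals[best], 10.0 ** grid[best]), (-res.fun, 10.0**res.x)]
    # boundary: no genetic variance
    ll0 = reml_loglik(0.0, yt, Xt, s, logdet_xtx)
    cand.append((ll0, 0.0))
    ll, lam = max(cand, key=lambda t: t[0])

    w = lam * s + 1.0
    wi = 1.0 / w
    xtwx = Xt.T @ (Xt * wi[:, None])
    beta = np.linalg.solve(xtwx, Xt.T @ (yt * wi))
    r = yt - Xt @ beta
    sigma_e2 = float(r @ (r * wi)) / (n - p)
    return VarianceComponents(lam * sigma_e2, sigma_e2, float(ll))


@dataclass
class ScanResult:
    effect: np.ndarray
    se: np.ndarray
    p: np.ndarray
    estimable: np.ndarray


def wald_scan(yw: np.ndarray, Xw: np.ndarray, Gw: np.ndarray) -> ScanResult:
    """Single-marker Wald scan in a whitened basis.

    ``yw``, ``Xw`` (null fixed effects incl. intercept) and ``Gw`` (marker
    columns) must already be rotated/whitened so residuals are i.i.d.  For
    each marker the slope is tested with a t reference on
    n - p - 1 degrees of freedom, with the residual variance re-estimated
    per marker (standard GLS with estimated scale).
    """
    n, p = Xw.shape
    q, _ = np.linalg.qr(Xw)
    gr = Gw - q @ (q.T @ Gw)
    yr = yw - q @ (q.T @ yw)
    g2 = np.einsum("ij,ij->j", gr, gr)
    scale = np.einsum("ij,ij->j", Gw, Gw) + 1e-30
    estimable = g2 > 1e-10 * scale
    df = n - p - 1
    if df < 1:
        raise ParameterError("not enough residual degrees of freedom for the scan")
    g2safe = np.where(estimable, g2, 1.0)
    beta = (gr.T @ yr) / g2safe
    sse = float(yr @ yr) - beta**2 * g2safe
    sse = np.clip(sse, 0.0, None)
    sigma2 = sse / df
    se = np.sqrt(np.where(sigma2 > 0, sigma2, np.nan) / g2safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    # exact fits (sse == 0) are maximally significant, not missing
    pvals = np.where(np.isfinite(tstat), pvals, np.where(sigma2 <= 0, 0.0, np.nan))
    pvals = np.clip(pvals, 1e-300, 1.0)
    beta = np.where(estimable, beta, np.nan)
    se = np.where(estimable, se, np.nan)
    pvals = np.where(estimable, pvals, np.nan)
    return ScanResult(beta, se, pvals, estimable)


def whiten(
    y: np.ndarray, X: np.ndarray, G: np.ndarray, s: np.ndarray, U: np.ndarray, lam: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rotate by U' and rescale rows by 1/sqrt(lambda s + 1)."""
    w = 1.0 / np.sqrt(lam * s + 1.0)
    return (U.T @ y) * w, (U.T @ X) * w[:, None], (U.T @ G) * w[:, None]
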
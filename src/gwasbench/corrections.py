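"""Multiple-comparison procedures and the fixed -log10(p) threshold rule.

Three adjustments are provided: Bonferroni (family-wise error control),
Benjamini-Hochberg step-up (false discovery rate) and Storey q-values
(positive false discovery rate, with a pi0 estimate).  Significance flags
use a cutoff of 0.05 on the adjusted values; the fixed-threshold rule
applies -log10(p) > 3.5 to raw p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .containers import ParameterError


@dataclass
class CorrectedResult:
    raw_p: np.ndarray
    adjusted: np.ndarray  # adjusted p (Bonferroni/BH) or q-value (Storey)
    significant: np.ndarray
    method: str
    alpha: float
    pi0: float | None = None

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())

    def rejection_set(self) -> np.ndarray:
        return np.flatnonzero(self.significant)


def _check_p(pvec) -> np.ndarray:
    p = np.asarray(pvec, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ParameterError("p-value vector must be non-empty and 1-D")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ParameterError("p-values must lie in (0, 1]")
    return p


def adjust_bonferroni(pvec, alpha: float = 0.05) -> CorrectedResult:
    """Bonferroni: adjusted = min(1, m p); significant iff adjusted <= alpha."""
    p = _check_p(pvec)
    _, adj, _, _ = multipletests(p, alpha=alpha, method="bonferroni")
    return CorrectedResult(p, adj, adj <= alpha, "bonferroni", alpha)


def adjust_fdr_bh(pvec, alpha: float = 0.05) -> CorrectedResult:
    """Benjamini-Hochberg step-up FDR; significant iff adjusted <= alpha."""
    p = _check_p(pvec)
    _, adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return CorrectedResult(p, adj, adj <= alpha, "fdr_bh", alpha)


def storey_pi0(p: np.ndarray, lambda_param: float = 0.5) -> float:
    """Single-lambda estimate of the null proportion pi0."""
    if not (0.0 <= lambda_param < 1.0):
        raise ParameterError("lambda_param must lie in [0, 1)")
    m = p.size
    pi0 = np.sum(p > lambda_param) / ((1.0 - lambda_param) * m)
    return float(min(1.0, pi0))


def adjust_pfdr_storey(
    pvec, alpha: float = 0.05, lambda_param: float | None = 0.5
) -> CorrectedResult:
    """Storey positive-FDR q-values.

    ``q_(i) = min_{j>=i} min(1, pi0 m p_(j) / j)`` — a pi0-scaled BH
    step-up.  ``lambda_param=None`` averages pi0 over a lambda grid
    (0.05..0.9) instead of the single-lambda default.
    """
    p = _check_p(pvec)
    m = p.size
    if lambda_param is None:
        grid = np.arange(0.05, 0.95, 0.05)
        pi0 = float(min(1.0, np.mean([storey_pi0(p, l) for l in grid])))
    else:
        pi0 = storey_pi0(p, lambda_param)
    order = np.lexsort((np.arange(m), p))  # stable in (p, index)
    ps = p[order]
    q = np.minimum(1.0, pi0 * m * ps / np.arange(1, m + 1))
    q = np.minimum.accumulate(q[::-1])[::-1]
    qvals = np.empty(m)
    qvals[order] = q
    return CorrectedResult(p, qvals, qvals <= alpha, "pfdr_storey", alpha, pi0=pi0)


def fixed_threshold_pvalue(logp_cut: float = 3.5) -> float:
    """The raw p-value cutoff paired with a -log10(p) threshold."""
    return float(10.0 ** (-logp_cut))


def fixed_threshold_select(pvec, logp_cut: float = 3.5) -> np.ndarray:
    """Indices of markers with -log10(p) strictly greater than ``logp_cut``."""
    p = np.asarray(pvec, dtype=float)
    if p.size == 0:
        return np.empty(0, dtype=int)
    if np.any(p[np.isfinite(p)] <= 0) or np.any(p[np.isfinite(p)] > 1):
        raise ParameterError("p-values must lie in (0, 1]")
    with np.errstate(divide="ignore"):
        neglog = -np.log10(p)
    return np.flatnonzero(np.isfinite(p) & (neglog > logp_cut))


CORRECTIONS = {
    "bonferroni": adjust_bonferroni,
    "fdr_bh": adjust_fdr_bh,
    "pfdr_storey": adjust_pfdr_storey,
}


def annotate_frame(frame, p_column: str = "P", alpha: float = 0.05, logp_cut: float = 3.5):
    """Append adjusted p-values and significance flags to a results table.

    Adds ``P_bonf``, ``P_bh``, ``Q_storey``, ``sig_bonf``, ``sig_fdr``,
    ``sig_pfdr`` and ``sig_fixed35``.  Markers with missing (inestimable)
    p-values get NaN adjustments and False flags.
    """
    out = frame.copy()
    p = np.asarray(out[p_column], dtype=float)
    finite = np.isfinite(p)
    cols = {
        "P_bonf": adjust_bonferroni, "P_bh": adjust_fdr_bh, "Q_storey": adjust_pfdr_storey,
    }
    flags = {"P_bonf": "sig_bonf", "P_bh": "sig_fdr", "Q_storey": "sig_pfdr"}
    for col, fn in cols.items():
        adj = np.full(p.shape, np.nan)
        sig = np.zeros(p.shape, dtype=bool)
        if finite.any():
            res = fn(p[finite], alpha=alpha)
            adj[finite] = res.adjusted
            sig[finite] = res.significant
        out[col] = adj
        out[flags[col]] = sig
    fixed = np.zeros(p.shape, dtype=bool)
    if finite.any():
        fixed[np.flatnonzero(finite)[fixed_threshold_select(p[finite], logp_cut)]] = True
    out["sig_fixed35"] = fixed
    return out
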
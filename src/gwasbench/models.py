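"""Eight association-mapping models over a shared REML mixed-model core.

The suite spans single-locus models of increasing sophistication — one-way
ANOVA, a general linear model with principal-component covariates, the
kinship mixed linear model (MLM), its compressed (CMLM) and enriched
compressed (ECMLM) variants, and SUPER with pseudo-QTN-derived kinship —
plus two multilocus models: the stepwise MLMM and the iterative
fixed/random-effect FarmCPU.

All kinship-based scans follow the population-parameters-previously-
determined strategy: variance components are estimated once on the null
(no-marker) model and reused for every marker test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .containers import MISSING, GenotypeMatrix, HeritabilityInputs, ParameterError, PhenotypeVector
from .mixedmodel import (
    VarianceComponents,
    eigen_kinship,
    fit_variance_components,
    ml_loglik,
    wald_scan,
    whiten,
)
from .structure import (
    KINSHIP_METHODS,
    LINKAGES,
    SUMMARIES,
    CompressionScheme,
    CovariateSet,
    KinshipMatrix,
    compress_kinship,
    compute_kinship,
)

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ("SNP", "Chr", "Pos", "MAF", "Effect", "SE", "P")


@dataclass
class AssocResult:
    """Per-marker association statistics from one model run."""

    frame: pd.DataFrame  # columns: SNP, Chr, Pos, MAF, Effect, SE, P
    model: str
    metadata: dict = field(default_factory=dict)

    @property
    def p(self) -> np.ndarray:
        return self.frame["P"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# shared plumbing


def _as_y(y) -> np.ndarray:
    if isinstance(y, PhenotypeVector):
        return y.line_means()
    return np.asarray(y, dtype=float)


def _as_cov(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.empty((n, 0))
    if isinstance(covariates, CovariateSet):
        c = covariates.scores
    else:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
    if c.shape[0] != n:
        raise ParameterError("covariate rows do not match the number of individuals")
    return c


def _prepare(geno: GenotypeMatrix, y, covariates):
    """Listwise deletion of missing phenotypes; mean-filled float dosages."""
    yv = _as_y(y)
    if len(yv) != geno.n_individuals:
        raise ParameterError("phenotype length does not match the genotype panel")
    keep = np.isfinite(yv)
    c = _as_cov(covariates, geno.n_individuals)
    G = geno.dosages_filled()
    if not keep.all():
        yv, c, G = yv[keep], c[keep], G[keep]
    return yv, c, G, keep


def _kin_values(K, keep: np.ndarray) -> np.ndarray:
    v = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    if keep.all():
        return v
    idx = np.flatnonzero(keep)
    return v[np.ix_(idx, idx)]


def _maf_of(G: np.ndarray) -> np.ndarray:
    f = G.mean(axis=0) / 2.0
    return np.minimum(f, 1.0 - f)


def _result(geno: GenotypeMatrix, model: str, G: np.ndarray, effect, se, p, metadata=None):
    mm = geno.marker_map
    frame = pd.DataFrame(
        {
            "SNP": mm["id"].to_numpy(),
            "Chr": mm["chrom"].to_numpy(),
            "Pos": mm["pos"].to_numpy(),
            "MAF": _maf_of(G),
            "Effect": np.asarray(effect, dtype=float),
            "SE": np.asarray(se, dtype=float),
            "P": np.asarray(p, dtype=float),
        }
    )
    return AssocResult(frame, model, metadata or {})


def _design(n: int, c: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(n), c])


def _vanraden(Gsub: np.ndarray) -> np.ndarray:
    p = Gsub.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ParameterError("selected markers are all monomorphic")
    w = Gsub - 2.0 * p[None, :]
    k = (w @ w.T) / denom
    return (k + k.T) / 2.0


def _r2_matrix(G: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Squared dosage correlation of every marker with each of ``cols``."""
    n = G.shape[0]
    gz = G - G.mean(axis=0)
    sd = gz.std(axis=0)
    sd_safe = np.where(sd > 0, sd, np.inf)
    r = (gz.T @ gz[:, cols]) / (n * np.outer(sd_safe, sd_safe[cols]))
    return r * r


def _scan_with_substitution(yv, X0, G, cofactors: list[int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fixed-effect scan with ``cofactors`` marker columns as covariates.

    Cofactor markers receive a substituted test: each is tested in a model
    whose covariates are the remaining cofactors only.
    """
    Xc = np.column_stack([X0, G[:, cofactors]]) if cofactors else X0
    scan = wald_scan(yv, Xc, G)
    eff, se, p = scan.effect.copy(), scan.se.copy(), scan.p.copy()
    for pos, j in enumerate(cofactors):
        others = [c for c in cofactors if c != j]
        Xj = np.column_stack([X0, G[:, others]]) if others else X0
        sub = wald_scan(yv, Xj, G[:, [j]])
        eff[j], se[j], p[j] = sub.effect[0], sub.se[0], sub.p[0]
    return eff, se, p


# ---------------------------------------------------------------------------
# single-locus models


def run_anova(geno: GenotypeMatrix, y) -> AssocResult:
    """One-way ANOVA across observed genotype classes at each marker.

    The F test has (g - 1, n_obs - g) degrees of freedom for g observed
    dosage classes; markers with a single class are flagged inestimable
    (P = NaN).  No structure correction of any kind.
    """
    yv = _as_y(y)
    if len(yv) != geno.n_individuals:
        raise ParameterError("phenotype length does not match the genotype panel")
    keep = np.isfinite(yv)
    dos = geno.dosages[keep]
    yv = yv[keep]

    obs = dos != MISSING
    n_j = obs.sum(axis=0).astype(float)
    sum_y = yv @ obs
    sum_y2 = (yv**2) @ obs
    mean_j = sum_y / np.maximum(n_j, 1.0)
    sst = sum_y2 - n_j * mean_j**2

    ssb = np.zeros(geno.n_markers)
    classes = np.zeros(geno.n_markers)
    for d in (0, 1, 2):
        mask = dos == d
        n_d = mask.sum(axis=0).astype(float)
        s_d = yv @ mask
        present = n_d > 0
        classes += present
        with np.errstate(invalid="ignore", divide="ignore"):
            dev = np.where(present, s_d / np.maximum(n_d, 1.0) - mean_j, 0.0)
        ssb += n_d * dev**2

    ssw = np.clip(sst - ssb, 0.0, None)
    df1 = classes - 1.0
    df2 = n_j - classes
    estimable = (df1 >= 1) & (df2 >= 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (ssb / np.maximum(df1, 1.0)) / np.where(ssw > 0, ssw / np.maximum(df2, 1.0), np.nan)
    p = np.full(geno.n_markers, np.nan)
    ok = estimable & np.isfinite(f)
    p[ok] = stats.f.sf(f[ok], df1[ok], df2[ok])
    # degenerate F: distinguish perfect within-class fit with real
    # between-class signal from an (all but) constant phenotype
    ssb_real = ssb > 1e-12 * np.maximum(sst, 1e-12)
    exact = estimable & ~np.isfinite(f) & ssb_real
    p[exact] = 1e-300
    zero = estimable & ~np.isfinite(f) & ~ssb_real
    p[zero] = 1.0
    p[estimable] = np.clip(p[estimable], 1e-300, 1.0)

    G = geno.dosages_filled()[keep]
    nan = np.full(geno.n_markers, np.nan)
    return _result(geno, "ANOVA", G, nan, nan, p, {"n_used": int(keep.sum())})


def run_glm(geno: GenotypeMatrix, y, covariates=None) -> AssocResult:
    """Least-squares scan of y on intercept + covariates + additive dosage,
    with a 1-df t test on the marker coefficient."""
    yv, c, G, keep = _prepare(geno, y, covariates)
    X0 = _design(len(yv), c)
    scan = wald_scan(yv, X0, G)
    meta = {"n_used": len(yv), "n_covariates": c.shape[1]}
    return _result(geno, "GLM", G, scan.effect, scan.se, scan.p, meta)


def run_mlm(
    geno: GenotypeMatrix,
    y,
    covariates=None,
    K: KinshipMatrix | np.ndarray | None = None,
    var_components: VarianceComponents | None = None,
) -> AssocResult:
    """Kinship mixed linear model scan (PCs + K).

    Variance components come from one null-model REML fit and are reused
    for every marker (P3D); each marker then gets a GLS Wald test.
    """
    if K is None:
        raise ParameterError("run_mlm requires a kinship matrix")
    yv, c, G, keep = _prepare(geno, y, covariates)
    Kv = _kin_values(K, keep)
    X0 = _design(len(yv), c)
    s, U = eigen_kinship(Kv)
    vc = var_components or fit_variance_components(yv, X0, Kv, eig=(s, U))
    yw, Xw, Gw = whiten(yv, X0, G, s, U, vc.ratio)
    scan = wald_scan(yw, Xw, Gw)
    meta = {
        "sigma_a2": vc.sigma_a2,
        "sigma_e2": vc.sigma_e2,
        "log_reml": vc.log_reml,
        "h2": vc.h2,
        "n_used": len(yv),
    }
    return _result(geno, "MLM", G, scan.effect, scan.se, scan.p, meta)


def _default_group_grid(n: int) -> np.ndarray:
    return np.unique(np.round(np.linspace(1, n, 8)).astype(int))


def _best_compression(
    yv, X0, K: KinshipMatrix, group_grid, linkage: str, summary: str
) -> tuple[CompressionScheme, VarianceComponents, list[tuple[int, float]]]:
    trace = []
    best = None
    for g in group_grid:
        scheme = compress_kinship(K, int(g), linkage, summary)
        keff = scheme.effective_kinship()
        vc = fit_variance_components(yv, X0, keff)
        trace.append((int(g), vc.log_reml))
        if best is None or vc.log_reml > best[1].log_reml:
            best = (scheme, vc)
    return best[0], best[1], trace


def run_cmlm(
    geno: GenotypeMatrix,
    y,
    covariates=None,
    K: KinshipMatrix | None = None,
    group_grid=None,
    linkage: str = "average",
    summary: str = "mean",
) -> AssocResult:
    """Compressed MLM: cluster individuals, fit group genetic values.

    The group count is chosen from ``group_grid`` by maximizing the
    null-model restricted likelihood; the marker scan then runs under the
    selected compressed kinship.
    """
    if K is None:
        raise ParameterError("run_cmlm requires a kinship matrix")
    yv, c, G, keep = _prepare(geno, y, covariates)
    if not keep.all():
        K = KinshipMatrix(_kin_values(K, keep), [t for t, k in zip(K.taxa, keep) if k], K.method)
    group_grid = _default_group_grid(len(yv)) if group_grid is None else np.asarray(list(group_grid))
    if group_grid.size == 0:
        raise ParameterError("group_grid must be non-empty")
    if group_grid.min() < 1 or group_grid.max() > len(yv):
        raise ParameterError("group_grid entries must lie in [1, n]")
    X0 = _design(len(yv), c)
    scheme, vc, trace = _best_compression(yv, X0, K, group_grid, linkage, summary)
    keff = scheme.effective_kinship()
    s, U = eigen_kinship(keff)
    yw, Xw, Gw = whiten(yv, X0, G, s, U, vc.ratio)
    scan = wald_scan(yw, Xw, Gw)
    meta = {
        "n_groups": scheme.n_groups,
        "linkage": linkage,
        "summary": summary,
        "group_reml": trace,
        "sigma_a2": vc.sigma_a2,
        "sigma_e2": vc.sigma_e2,
        "log_reml": vc.log_reml,
        "assignment": scheme.assignment,
    }
    return _result(geno, "CMLM", G, scan.effect, scan.se, scan.p, meta)


def run_ecmlm(
    geno: GenotypeMatrix,
    y,
    covariates=None,
    kinship_methods=KINSHIP_METHODS,
    linkages=LINKAGES,
    summaries=SUMMARIES,
    group_grid=None,
) -> AssocResult:
    """Enriched CMLM: enumerate kinship method x linkage x summary, keep the
    combination whose best compressed null model has the highest restricted
    likelihood, and scan under it."""
    if not (kinship_methods and linkages and summaries):
        raise ParameterError("enumeration sets must be non-empty")
    yv, c, G, keep = _prepare(geno, y, covariates)
    sub = geno if keep.all() else geno.select_individuals(np.flatnonzero(keep))
    group_grid = _default_group_grid(len(yv)) if group_grid is None else np.asarray(list(group_grid))
    X0 = _design(len(yv), c)

    from .structure import cluster_assignment, group_summaries

    kinships = {m: compute_kinship(sub, m) for m in kinship_methods}
    best = None
    for method, linkage in itertools.product(kinship_methods, linkages):
        Kv = kinships[method].values
        for g in group_grid:
            assignment = cluster_assignment(Kv, int(g), linkage)
            kgs = group_summaries(Kv, assignment, tuple(summaries))
            for summary, kg in kgs.items():
                scheme = CompressionScheme(assignment, kg, linkage, summary)
                vc = fit_variance_components(yv, X0, scheme.effective_kinship())
                if best is None or vc.log_reml > best["vc"].log_reml:
                    best = {"method": method, "linkage": linkage, "summary": summary,
                            "scheme": scheme, "vc": vc}
    scheme, vc = best["scheme"], best["vc"]
    s, U = eigen_kinship(scheme.effective_kinship())
    yw, Xw, Gw = whiten(yv, X0, G, s, U, vc.ratio)
    scan = wald_scan(yw, Xw, Gw)
    meta = {
        "kinship_method": best["method"],
        "linkage": best["linkage"],
        "summary": best["summary"],
        "n_groups": scheme.n_groups,
        "sigma_a2": vc.sigma_a2,
        "sigma_e2": vc.sigma_e2,
        "log_reml": vc.log_reml,
    }
    return _result(geno, "ECMLM", G, scan.effect, scan.se, scan.p, meta)


# ---------------------------------------------------------------------------
# pseudo-QTN machinery shared by SUPER and FarmCPU


def _chrom_codes(geno: GenotypeMatrix) -> np.ndarray:
    _, codes = np.unique(geno.marker_map["chrom"].to_numpy(), return_inverse=True)
    return codes


def _default_bin_sizes(geno: GenotypeMatrix) -> list[int]:
    """Three bin sizes spanning local to chromosome scale, scaled to the
    marker map (10x, 100x and 1000x the median marker spacing)."""
    pos = geno.marker_map["pos"].to_numpy()
    codes = _chrom_codes(geno)
    gaps = []
    for cc in np.unique(codes):
        p = pos[codes == cc]
        if p.size > 1:
            gaps.append(np.diff(p))
    spacing = float(np.median(np.concatenate(gaps))) if gaps else 1e4
    return [max(1, int(round(spacing * f))) for f in (10, 100, 1000)]


def _bin_best(pvals: np.ndarray, codes: np.ndarray, pos: np.ndarray, bin_size: int,
              candidates: np.ndarray) -> np.ndarray:
    """Per bin, the candidate marker with the smallest p; returned sorted by p."""
    if candidates.size == 0:
        return candidates
    key = codes[candidates].astype(np.int64) * (1 << 42) + pos[candidates] // bin_size
    order = candidates[np.lexsort((candidates, pvals[candidates]))]
    okey = codes[order].astype(np.int64) * (1 << 42) + pos[order] // bin_size
    seen: set[int] = set()
    out = []
    for j, kk in zip(order, okey):
        if kk not in seen:
            seen.add(kk)
            out.append(j)
    return np.asarray(out, dtype=int)


def _default_qtn_counts(max_qtns: int) -> list[int]:
    counts = [t for t in (2, 4, 8, 16, 32) if t <= max_qtns]
    if max_qtns >= 1 and max_qtns not in counts:
        counts.append(max_qtns)
    return sorted(set(counts)) or [1]


def _select_qtns_by_reml(
    yv, X0, G, pvals, codes, pos, bin_sizes, count_grid, candidates,
    prune_r2: float | None = None,
) -> tuple[np.ndarray, VarianceComponents | None, dict]:
    """Optimize (bin size, QTN count) by the restricted likelihood of the
    null mixed model whose kinship is built from the chosen pseudo-QTNs.

    ``prune_r2`` greedily drops candidates in high LD (r^2 >= prune_r2)
    with an already-accepted, more significant candidate.
    """
    best_set, best_vc, info = np.empty(0, dtype=int), None, {}
    for b in bin_sizes:
        ranked = _bin_best(pvals, codes, pos, b, candidates)
        if prune_r2 is not None and ranked.size > 1:
            # greedy prune on pairwise dosage correlation, most significant first
            limit = max(count_grid) * 3
            short = ranked[:limit]
            kept: list[int] = []
            gz = G[:, short] - G[:, short].mean(axis=0)
            sd = gz.std(axis=0)
            sd = np.where(sd > 0, sd, np.inf)
            corr = (gz.T @ gz) / (G.shape[0] * np.outer(sd, sd))
            for a in range(short.size):
                if all(corr[a, b_] ** 2 < prune_r2 for b_ in kept):
                    kept.append(a)
            ranked = short[np.asarray(kept, dtype=int)]
        for t in count_grid:
            if t > ranked.size:
                continue
            subset = ranked[:t]
            try:
                kq = _vanraden(G[:, subset])
                vc = fit_variance_components(yv, X0, kq)
            except (ParameterError, np.linalg.LinAlgError):
                continue
            if best_vc is None or vc.log_reml > best_vc.log_reml:
                best_set, best_vc = subset, vc
                info = {"bin_size": int(b), "n_qtns": int(t), "log_reml": vc.log_reml}
    return best_set, best_vc, info


def run_super(
    geno: GenotypeMatrix,
    y,
    covariates=None,
    bin_grid=None,
    qtn_count_grid=None,
    ld_exclusion_r2: float = 0.7,
    initial: str = "glm",
) -> AssocResult:
    """SUPER: kinship from associated pseudo-QTNs instead of all markers.

    An initial scan supplies p-values; the genome is binned and the most
    significant marker per bin forms the pseudo-QTN candidate set, with
    bin size and QTN count chosen by null REML likelihood.  When a tested
    marker is in LD (r^2 >= ``ld_exclusion_r2``) with a pseudo-QTN, that
    QTN is dropped from the kinship used for its test.
    """
    if not (0.0 < ld_exclusion_r2 <= 1.0):
        raise ParameterError("ld_exclusion_r2 must lie in (0, 1]")
    init = run_glm(geno, y, covariates) if initial == "glm" else None
    if init is None:
        raise ParameterError(f"unknown initial scan {initial!r}")
    yv, c, G, keep = _prepare(geno, y, covariates)
    X0 = _design(len(yv), c)
    codes = _chrom_codes(geno)
    pos = geno.marker_map["pos"].to_numpy()
    pvals = np.where(np.isfinite(init.p), init.p, 1.0)

    bin_sizes = _default_bin_sizes(geno) if bin_grid is None else list(bin_grid)
    max_qtns = min(50, int(np.sqrt(len(yv))))
    counts = _default_qtn_counts(max_qtns) if qtn_count_grid is None else list(qtn_count_grid)
    candidates = np.arange(geno.n_markers)
    qtns, vc, info = _select_qtns_by_reml(yv, X0, G, pvals, codes, pos, bin_sizes, counts, candidates)
    if vc is None:
        logger.warning("run_super: pseudo-QTN selection failed; falling back to GLM")
        out = init
        out.model = "SUPER"
        out.metadata["fallback"] = "glm"
        return out

    r2 = _r2_matrix(G, qtns)  # (m, t)
    excl = r2 >= ld_exclusion_r2
    effect = np.full(geno.n_markers, np.nan)
    se = np.full(geno.n_markers, np.nan)
    p = np.full(geno.n_markers, np.nan)
    n_fallback = 0
    groups: dict[tuple, list[int]] = {}
    for j in range(geno.n_markers):
        groups.setdefault(tuple(np.flatnonzero(excl[j])), []).append(j)
    for excl_idx, markers in groups.items():
        remaining = np.delete(np.arange(len(qtns)), list(excl_idx))
        cols = np.asarray(markers)
        if remaining.size == 0:
            scan = wald_scan(yv, X0, G[:, cols])
            n_fallback += len(markers)
        else:
            try:
                ksub = _vanraden(G[:, qtns[remaining]])
            except ParameterError:
                scan = wald_scan(yv, X0, G[:, cols])
                n_fallback += len(markers)
                effect[cols], se[cols], p[cols] = scan.effect, scan.se, scan.p
                continue
            s, U = eigen_kinship(ksub)
            yw, Xw, Gw = whiten(yv, X0, G[:, cols], s, U, vc.ratio)
            scan = wald_scan(yw, Xw, Gw)
        effect[cols], se[cols], p[cols] = scan.effect, scan.se, scan.p
    if n_fallback:
        logger.info("run_super: %d markers tested under the fixed model (empty QTN kinship)", n_fallback)
    meta = dict(info)
    meta.update({
        "pseudo_qtns": qtns,
        "ld_exclusion_r2": ld_exclusion_r2,
        "n_fixed_fallback": n_fallback,
        "sigma_a2": vc.sigma_a2,
        "sigma_e2": vc.sigma_e2,
    })
    return _result(geno, "SUPER", G, effect, se, p, meta)


# ---------------------------------------------------------------------------
# multilocus models


def subset_criterion(
    yv: np.ndarray,
    X0: np.ndarray,
    G: np.ndarray,
    eig: tuple[np.ndarray, np.ndarray],
    subset,
    n_markers: int,
    criterion: str = "ebic",
) -> float:
    """Model-selection score (smaller is better) for a cofactor subset.

    Extended BIC: -2 logL_ML + k log n + 2 log C(m, k); plain BIC drops
    the combinatorial term.  The ML log-likelihood is evaluated at the
    REML estimate of the variance ratio.
    """
    if criterion not in ("ebic", "bic"):
        raise ParameterError(f"unknown criterion {criterion!r}")
    subset = list(subset)
    X = np.column_stack([X0, G[:, subset]]) if subset else X0
    s, U = eig
    vc = fit_variance_components(yv, X, None, eig=eig)
    lml = ml_loglik(vc.ratio, U.T @ yv, U.T @ X, s)
    n = len(yv)
    k = len(subset)
    score = -2.0 * lml + k * np.log(n)
    if criterion == "ebic":
        log_binom = gammaln(n_markers + 1) - gammaln(k + 1) - gammaln(n_markers - k + 1)
        score += 2.0 * log_binom
    return float(score)


def _mlm_scan_with_cofactors(yv, X0, G, eig, cofactors):
    """GLS scan with cofactor markers as fixed effects; cofactors receive a
    substituted test excluding themselves from the covariates."""
    s, U = eig
    X = np.column_stack([X0, G[:, cofactors]]) if cofactors else X0
    vc = fit_variance_components(yv, X, None, eig=eig)
    yw, Xw, Gw = whiten(yv, X, G, s, U, vc.ratio)
    scan = wald_scan(yw, Xw, Gw)
    eff, se, p = scan.effect.copy(), scan.se.copy(), scan.p.copy()
    for j in cofactors:
        others = [cf for cf in cofactors if cf != j]
        Xj = np.column_stack([X0, G[:, others]]) if others else X0
        vcj = fit_variance_components(yv, Xj, None, eig=eig)
        yw, Xw, Gw = whiten(yv, Xj, G[:, [j]], s, U, vcj.ratio)
        sub = wald_scan(yw, Xw, Gw)
        eff[j], se[j], p[j] = sub.effect[0], sub.se[0], sub.p[0]
    return eff, se, p, vc


def run_mlmm(
    geno: GenotypeMatrix,
    y,
    covariates=None,
    K: KinshipMatrix | None = None,
    max_cofactors: int = 10,
    criterion: str = "ebic",
    h2_floor: float = 0.01,
) -> AssocResult:
    """Stepwise multilocus mixed model.

    Forward inclusion of the most significant marker as a fixed cofactor
    (variance components re-estimated at each step) until ``max_cofactors``
    or the genetic-variance ratio drops below ``h2_floor``; then backward
    elimination; the visited model with the best selection criterion is
    reported, with cofactor p-values substituted from leave-one-out fits.
    """
    if K is None:
        raise ParameterError("run_mlmm requires a kinship matrix")
    if max_cofactors < 0:
        raise ParameterError("max_cofactors must be >= 0")
    if criterion not in ("ebic", "bic"):
        raise ParameterError(f"unknown criterion {criterion!r}")
    yv, c, G, keep = _prepare(geno, y, covariates)
    Kv = _kin_values(K, keep)
    X0 = _design(len(yv), c)
    eig = eigen_kinship(Kv)
    m = geno.n_markers

    visited: list[list[int]] = []

    def record(cof):
        if sorted(cof) not in [sorted(v) for v in visited]:
            visited.append(list(cof))

    cof: list[int] = []
    record(cof)
    # forward
    while len(cof) < max_cofactors:
        eff, se, p, vc = _mlm_scan_with_cofactors(yv, X0, G, eig, cof)
        if vc.h2 < h2_floor and cof:
            break
        open_p = np.where(np.isin(np.arange(m), cof) | ~np.isfinite(p), np.inf, p)
        nxt = int(np.argmin(open_p))
        if not np.isfinite(open_p[nxt]):
            break
        cof.append(nxt)
        record(cof)
        if vc.h2 < h2_floor:
            break
    # backward
    back = list(cof)
    while back:
        _, _, p, _ = _mlm_scan_with_cofactors(yv, X0, G, eig, back)
        worst = max(back, key=lambda j: (np.inf if not np.isfinite(p[j]) else p[j]))
        back = [j for j in back if j != worst]
        record(back)

    scores = [subset_criterion(yv, X0, G, eig, v, m, criterion) for v in visited]
    sel = visited[int(np.argmin(scores))]
    eff, se, p, vc = _mlm_scan_with_cofactors(yv, X0, G, eig, sel)
    meta = {
        "cofactors": np.asarray(sorted(sel), dtype=int),
        "criterion": criterion,
        "criterion_values": list(zip([tuple(sorted(v)) for v in visited], scores)),
        "sigma_a2": vc.sigma_a2,
        "sigma_e2": vc.sigma_e2,
        "h2": vc.h2,
    }
    return _result(geno, "MLMM", G, eff, se, p, meta)


def run_farmcpu(
    geno: GenotypeMatrix,
    y,
    covariates=None,
    bin_sizes_bp=None,
    max_qtns: int | None = None,
    max_iter: int = 10,
    entry_threshold: float | None = None,
    qtn_count_grid=None,
    qtn_prune_r2: float = 0.7,
) -> AssocResult:
    """FarmCPU: alternating fixed-effect and random-effect models.

    FEM scans every marker one at a time with the current pseudo-QTNs as
    fixed covariates; REM refreshes the pseudo-QTN set by multi-bin-size
    binning of the FEM p-values, optimizing bin size and QTN count through
    the REML likelihood of a QTN-derived kinship.  A marker that is itself
    a pseudo-QTN receives a substituted (unified) p-value from a fit that
    excludes it from the covariates.  Candidate pseudo-QTNs in mutual LD
    (r^2 >= ``qtn_prune_r2``) are pruned, keeping the more significant one,
    so correlated covariates cannot cancel each other's tests.  Iteration
    stops when the pseudo-QTN set repeats or ``max_iter`` is reached; if
    no marker reaches ``entry_threshold`` the scan ends with no
    pseudo-QTNs (a plain fixed-effect scan).
    """
    yv, c, G, keep = _prepare(geno, y, covariates)
    X0 = _design(len(yv), c)
    m = geno.n_markers
    codes = _chrom_codes(geno)
    pos = geno.marker_map["pos"].to_numpy()
    if entry_threshold is None:
        entry_threshold = 0.01 / m
    if max_qtns is None:
        max_qtns = min(50, int(np.sqrt(len(yv))))
    bin_sizes = _default_bin_sizes(geno) if bin_sizes_bp is None else list(bin_sizes_bp)
    counts = _default_qtn_counts(max_qtns) if qtn_count_grid is None else list(qtn_count_grid)

    qtns: list[int] = []
    history = {frozenset()}
    converged = False
    rem_info: dict = {}
    eff = se = p = None
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eff, se, p = _scan_with_substitution(yv, X0, G, qtns)
        pv = np.where(np.isfinite(p), p, 1.0)
        # stopping rule: nothing anywhere near significance -> no pseudo-QTNs
        if pv.min() > entry_threshold:
            converged = True
            if qtns:
                qtns = []
                eff, se, p = _scan_with_substitution(yv, X0, G, qtns)
            break
        new_set, vc, info = _select_qtns_by_reml(
            yv, X0, G, pv, codes, pos, bin_sizes, counts, np.arange(m),
            prune_r2=qtn_prune_r2,
        )
        if vc is None:
            # QTN kinship could not be formed; keep the most significant
            # markers directly as covariates
            new_set = np.argsort(pv)[: min(max_qtns, 5)]
            info = {"bin_size": None, "n_qtns": int(new_set.size), "log_reml": None}
        new = sorted(int(j) for j in new_set[:max_qtns])
        rem_info = info
        if new == sorted(qtns):
            converged = True
            break
        if frozenset(new) in history:  # cycle
            qtns = new
            eff, se, p = _scan_with_substitution(yv, X0, G, qtns)
            converged = True
            break
        history.add(frozenset(new))
        qtns = new
    meta = {
        "pseudo_qtns": np.asarray(sorted(qtns), dtype=int),
        "n_iterations": n_iter,
        "converged": converged,
        "entry_threshold": entry_threshold,
        "rem_selection": rem_info,
    }
    if not converged:
        logger.warning("run_farmcpu: pseudo-QTN set still changing at max_iter=%d", max_iter)
    return _result(geno, "FarmCPU", G, eff, se, p, meta)


# ---------------------------------------------------------------------------
# heritability


def estimate_marker_h2(y, covariates, K, taxa=None) -> float:
    """Marker-based narrow-sense heritability sigma_a^2/(sigma_a^2+sigma_e^2)
    from the null-model REML fit against kinship K."""
    yv = _as_y(y)
    keep = np.isfinite(yv)
    c = _as_cov(covariates, len(yv))
    Kv = _kin_values(K, keep)
    X0 = _design(int(keep.sum()), c[keep])
    vc = fit_variance_components(yv[keep], X0, Kv)
    return vc.h2


def broad_sense_h2(inputs: HeritabilityInputs) -> float:
    """Broad-sense heritability H = sigma2_G / (sigma2_G + sigma2_eps / r)."""
    denom = inputs.sigma2_g + inputs.sigma2_e / inputs.n_reps
    if denom <= 0:
        raise ParameterError("both variance components are zero; H is undefined")
    return inputs.sigma2_g / denom


MODEL_RUNNERS = {
    "ANOVA": run_anova,
    "GLM": run_glm,
    "MLM": run_mlm,
    "CMLM": run_cmlm,
    "ECMLM": run_ecmlm,
    "SUPER": run_super,
    "MLMM": run_mlmm,
    "FarmCPU": run_farmcpu,
}
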
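"""Population structure covariates, kinship, compression, and LD decay.

Principal components of the standardized dosage matrix serve as fixed
structure covariates (the "Q matrix" surrogate).  Kinship is available as
identity-by-state allele sharing or as the VanRaden centered cross-product;
compressed kinship groups individuals by hierarchical clustering of the
kinship-derived distance, as used by the compressed mixed linear model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .containers import GenotypeMatrix, ParameterError

KINSHIP_METHODS = ("IBS", "VanRaden")
LINKAGES = ("average", "complete", "single")
SUMMARIES = ("mean", "median", "max")


@dataclass
class CovariateSet:
    """Principal-component scores used as fixed structure covariates."""

    scores: np.ndarray  # (n, n_components)
    variance_explained: np.ndarray  # fraction per component, non-increasing
    taxa: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass
class KinshipMatrix:
    """Symmetric pairwise relatedness with its method tag."""

    values: np.ndarray
    taxa: list[str]
    method: str = "VanRaden"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ParameterError("kinship must be square")
        if len(self.taxa) != self.values.shape[0]:
            raise ParameterError("taxa length does not match kinship size")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class CompressionScheme:
    """Group-compressed kinship for the compressed mixed model."""

    assignment: np.ndarray  # individual -> group index in [0, g)
    group_kinship: np.ndarray  # (g, g)
    linkage: str = "average"
    summary: str = "mean"

    @property
    def n_groups(self) -> int:
        return self.group_kinship.shape[0]

    def incidence(self) -> np.ndarray:
        """n x g incidence matrix Z mapping individuals to groups."""
        n = self.assignment.size
        z = np.zeros((n, self.n_groups))
        z[np.arange(n), self.assignment] = 1.0
        return z

    def effective_kinship(self) -> np.ndarray:
        """Z Kg Z' — the n x n covariance implied by the compression."""
        z = self.incidence()
        return z @ self.group_kinship @ z.T


@dataclass
class LDDecayCurve:
    """Mean r^2 against physical distance, binned."""

    bin_start: np.ndarray
    bin_end: np.ndarray
    mean_r2: np.ndarray
    n_pairs: np.ndarray
    reference_r2: float
    decay_distance: float | None  # start of first bin with mean r^2 < reference

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_start,
                "bin_end": self.bin_end,
                "mean_r2": self.mean_r2,
                "n_pairs": self.n_pairs,
            }
        )


def _standardized(geno: GenotypeMatrix) -> np.ndarray:
    if not geno.is_complete():
        raise ParameterError("genotypes must be imputed (no missing calls)")
    x = geno.dosages.astype(float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} constant marker columns before standardization",
            stacklevel=3,
        )
    return (x[:, keep] - mu[keep]) / sd[keep]


def compute_pcs(geno: GenotypeMatrix, n_components: int = 3) -> CovariateSet:
    """Principal components of the column-standardized dosage matrix.

    Deterministic up to sign; each component's sign is fixed so that its
    largest-magnitude marker loading is positive.
    """
    z = _standardized(geno)
    n, m = z.shape
    if not (0 < n_components < min(n, m)):
        raise ParameterError("n_components must satisfy 0 < c < min(n, m)")
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    for comp in range(n_components):
        j = np.argmax(np.abs(vt[comp]))
        if vt[comp, j] < 0:
            vt[comp] *= -1.0
            u[:, comp] *= -1.0
    scores = u[:, :n_components] * s[:n_components]
    var_expl = (s**2) / np.sum(s**2)
    return CovariateSet(scores, var_expl[:n_components], list(geno.taxa))


def compute_kinship(geno: GenotypeMatrix, method: str = "VanRaden") -> KinshipMatrix:
    """Pairwise relatedness: IBS allele sharing or VanRaden cross-product."""
    if method not in KINSHIP_METHODS:
        raise ParameterError(f"unknown kinship method {method!r}; choose from {KINSHIP_METHODS}")
    if geno.n_markers == 0:
        raise ParameterError("cannot compute kinship with zero markers")
    if not geno.is_complete():
        raise ParameterError("genotypes must be imputed (no missing calls)")
    x = geno.dosages.astype(float)
    n, m = x.shape
    if method == "IBS":
        # mean per-marker allele-sharing fraction 1 - |xi - xj| / 2
        k = np.empty((n, n))
        for i in range(n):
            k[i] = 1.0 - np.abs(x - x[i]).mean(axis=1) / 2.0
        k = (k + k.T) / 2.0
    else:
        p = x.mean(axis=0) / 2.0
        denom = 2.0 * np.sum(p * (1.0 - p))
        if denom <= 0:
            raise ParameterError("all markers monomorphic; VanRaden kinship undefined")
        w = x - 2.0 * p[None, :]
        k = (w @ w.T) / denom
        k = (k + k.T) / 2.0
    return KinshipMatrix(k, list(geno.taxa), method)


def compress_kinship(
    K: KinshipMatrix,
    n_groups: int,
    linkage: str = "average",
    summary: str = "mean",
) -> CompressionScheme:
    """Cluster individuals on kinship-derived distance and summarize kinship
    at the group level.

    Distance is ``1 - K`` rescaled to [0, 1]; the hierarchical tree is cut
    at ``n_groups``; the group kinship entry (a, b) is the chosen summary
    of all member-pair kinships between groups a and b (including the
    diagonal when a == b, so g = n reproduces K exactly).
    """
    if linkage not in LINKAGES:
        raise ParameterError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    if summary not in SUMMARIES:
        raise ParameterError(f"unknown summary {summary!r}; choose from {SUMMARIES}")
    n = K.n
    if not (1 <= n_groups <= n):
        raise ParameterError("n_groups must lie in [1, n]")

    assignment = cluster_assignment(K.values, n_groups, linkage)
    kg = group_summaries(K.values, assignment, (summary,))[summary]
    return CompressionScheme(assignment, kg, linkage, summary)


def cluster_assignment(Kv: np.ndarray, n_groups: int, linkage: str) -> np.ndarray:
    """Hierarchical-clustering group labels on the 1 - K distance."""
    n = Kv.shape[0]
    if n_groups == n:
        return np.arange(n)
    d = 1.0 - Kv
    d = d - d.min()
    if d.max() > 0:
        d = d / d.max()
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    tree = scipy_linkage(condensed, method=linkage)
    labels = fcluster(tree, t=n_groups, criterion="maxclust")
    _, assignment = np.unique(labels, return_inverse=True)
    return assignment


def group_summaries(
    Kv: np.ndarray, assignment: np.ndarray, summaries=("mean",)
) -> dict[str, np.ndarray]:
    """Group-level kinship matrices for one or more summary statistics.

    Each (a, b) entry summarizes all member-pair kinships between groups a
    and b (diagonal included when a == b, so singleton groups reproduce K).
    """
    n = Kv.shape[0]
    g = int(assignment.max()) + 1
    perm = np.argsort(assignment, kind="stable")
    Kp = Kv[np.ix_(perm, perm)]
    sizes = np.bincount(assignment, minlength=g)
    starts = np.concatenate([[0], np.cumsum(sizes)])[:-1]
    out: dict[str, np.ndarray] = {}
    if "mean" in summaries:
        s1 = np.add.reduceat(Kp, starts, axis=0)
        s2 = np.add.reduceat(s1, starts, axis=1)
        out["mean"] = s2 / np.outer(sizes, sizes)
    if "max" in summaries:
        m1 = np.maximum.reduceat(Kp, starts, axis=0)
        out["max"] = np.maximum.reduceat(m1, starts, axis=1)
    if "median" in summaries:
        med = np.empty((g, g))
        ends = starts + sizes
        for a in range(g):
            ra = slice(starts[a], ends[a])
            for b in range(a, g):
                flat = np.sort(Kp[ra, starts[b]:ends[b]], axis=None)
                ln = flat.size
                med[a, b] = med[b, a] = 0.5 * (flat[(ln - 1) // 2] + flat[ln // 2])
        out["median"] = med
    return out


def ld_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared dosage correlation (composite LD) between two markers."""
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return np.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_decay(
    geno: GenotypeMatrix,
    max_dist_bp: int = 1_000_000,
    n_bins: int = 20,
    reference_r2: float = 0.25,
) -> LDDecayCurve:
    """Mean pairwise r^2 binned by physical distance within chromosomes.

    Reports the start of the first distance bin whose mean r^2 drops below
    ``reference_r2`` (None if no bin does).
    """
    if not geno.is_complete():
        raise ParameterError("genotypes must be imputed (no missing calls)")
    x = geno.dosages.astype(float)
    chrom = geno.marker_map["chrom"].to_numpy()
    pos = geno.marker_map["pos"].to_numpy()

    dists: list[np.ndarray] = []
    r2s: list[np.ndarray] = []
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        if idx.size < 2:
            continue
        xc = x[:, idx]
        sd = xc.std(axis=0)
        pc = pos[idx]
        for a in range(idx.size - 1):
            if sd[a] == 0:
                continue
            within = np.flatnonzero(
                (pc[a + 1 :] - pc[a] <= max_dist_bp) & (sd[a + 1 :] > 0)
            )
            if within.size == 0:
                continue
            b = within + a + 1
            xa = xc[:, a] - xc[:, a].mean()
            xb = xc[:, b] - xc[:, b].mean(axis=0)
            r = (xa @ xb) / (len(xa) * sd[a] * sd[b])
            dists.append((pc[b] - pc[a]).astype(float))
            r2s.append(r * r)
    if not dists:
        raise ParameterError("no eligible marker pairs for LD decay")
    dist = np.concatenate(dists)
    r2 = np.concatenate(r2s)

    edges = np.linspace(0, max_dist_bp, n_bins + 1)
    which = np.clip(np.digitize(dist, edges) - 1, 0, n_bins - 1)
    mean_r2 = np.full(n_bins, np.nan)
    n_pairs = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = which == b
        n_pairs[b] = sel.sum()
        if n_pairs[b]:
            mean_r2[b] = r2[sel].mean()
    decay = None
    for b in range(n_bins):
        if n_pairs[b] and mean_r2[b] < reference_r2:
            decay = float(edges[b])
            break
    return LDDecayCurve(edges[:-1], edges[1:], mean_r2, n_pairs, reference_r2, decay)
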
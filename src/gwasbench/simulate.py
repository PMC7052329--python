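"""Synthetic genotype panels and simulated quantitative traits.

The generator emulates the structure of diversity panels used for crop
association mapping: a Balding-Nichols divergence model produces
subpopulation allele frequencies around an ancestral frequency drawn from
a bounded MAF spectrum; within each subpopulation, markers in blocks of
``block_len_bp`` are copied from a small haplotype pool, which creates
block-wise linkage disequilibrium; optional full-sib families add
close-kin relatedness on top of the subpopulation structure.

Traits are simulated as a dosage-weighted sum of effects at Q randomly
chosen causal markers plus Gaussian noise scaled so the broad-sense
heritability H = sigma2_G / (sigma2_G + sigma2_eps / r) hits its target.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import (
    MISSING,
    EmptyPanelError,
    GenotypeMatrix,
    ParameterError,
    PhenotypeVector,
    QCReport,
    TraitArchitecture,
)

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_genotypes(
    n_individuals: int,
    n_markers: int,
    n_chromosomes: int = 10,
    n_subpops: int = 2,
    fst: float = 0.1,
    family_size: int = 5,
    block_len_bp: int = 100_000,
    maf_range: tuple[float, float] = (0.05, 0.5),
    missing_rate: float = 0.0,
    seed=None,
    marker_spacing_bp: int = 10_000,
    haplotype_pool: int = 8,
) -> GenotypeMatrix:
    """Simulate a structured biallelic SNP panel.

    Parameters
    ----------
    n_individuals, n_markers, n_chromosomes
        Panel geometry.  Markers are spread evenly over chromosomes at a
        mean spacing of ``marker_spacing_bp`` (1-based positions).
    n_subpops, fst
        Number of subpopulations and the Balding-Nichols divergence
        between them.  ``fst=0`` collapses to a single panmictic pool.
    family_size
        Individuals per full-sib family within a subpopulation; 1 means
        unrelated individuals.
    block_len_bp
        Length of the haplotype-sharing LD blocks; ``0`` disables block
        structure (every marker independent).
    maf_range
        Ancestral minor-allele-frequency spectrum (uniform draw).
    missing_rate
        i.i.d. probability that a call is set to the missing sentinel.
    haplotype_pool
        Haplotypes per block per subpopulation; smaller pools give
        stronger within-block r^2.
    """
    if n_individuals < 2:
        raise ParameterError("n_individuals must be >= 2")
    if n_markers < 1:
        raise ParameterError("n_markers must be >= 1")
    if n_chromosomes < 1:
        raise ParameterError("n_chromosomes must be >= 1")
    if n_subpops < 1:
        raise ParameterError("n_subpops must be >= 1")
    if not (0.0 <= fst < 1.0):
        raise ParameterError("fst must lie in [0, 1)")
    if family_size < 1:
        raise ParameterError("family_size must be >= 1")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ParameterError("maf_range must be a subset of (0, 0.5]")
    if not (0.0 <= missing_rate < 1.0):
        raise ParameterError("missing_rate must lie in [0, 1)")
    if haplotype_pool < 2:
        raise ParameterError("haplotype_pool must be >= 2")

    rng = _rng(seed)
    n, m = n_individuals, n_markers

    # marker map: even split over chromosomes, jittered spacing
    per_chrom = np.full(n_chromosomes, m // n_chromosomes)
    per_chrom[: m % n_chromosomes] += 1
    chroms, positions = [], []
    for c, mc in enumerate(per_chrom):
        gaps = rng.integers(marker_spacing_bp // 2, marker_spacing_bp * 3 // 2 + 1, size=mc)
        pos = np.cumsum(gaps)
        chroms.append(np.full(mc, c))
        positions.append(pos)
    chrom_idx = np.concatenate(chroms) if chroms else np.empty(0, dtype=int)
    pos = np.concatenate(positions) if positions else np.empty(0, dtype=int)
    chrom_labels = np.array([f"Chr{c + 1:02d}" for c in chrom_idx])

    # ancestral frequencies and allele letters
    p0 = rng.uniform(lo, hi, size=m)
    allele_pairs = np.array([rng.choice(4, size=2, replace=False) for _ in range(m)])
    a1 = _BASES[allele_pairs[:, 0]]  # coded allele during generation
    a2 = _BASES[allele_pairs[:, 1]]

    # subpopulation frequencies (Balding-Nichols)
    if fst > 0.0 and n_subpops > 1:
        shape1 = p0 * (1.0 - fst) / fst
        shape2 = (1.0 - p0) * (1.0 - fst) / fst
        pk = np.stack([rng.beta(shape1, shape2) for _ in range(n_subpops)])
    else:
        pk = np.tile(p0, (n_subpops, 1))
    pk = np.clip(pk, 1e-6, 1.0 - 1e-6)

    # individuals -> subpopulations -> families
    subpop = np.repeat(np.arange(n_subpops), int(np.ceil(n / n_subpops)))[:n]
    families = np.empty(n, dtype=int)
    fam_id = 0
    for s in range(n_subpops):
        members = np.flatnonzero(subpop == s)
        for start in range(0, len(members), family_size):
            families[members[start : start + family_size]] = fam_id
            fam_id += 1

    # LD blocks: contiguous runs of pos // block_len_bp within a chromosome
    if block_len_bp > 0:
        block_key = chrom_idx * (1 << 40) + pos // block_len_bp
    else:
        block_key = np.arange(m)
    _, block_of = np.unique(block_key, return_inverse=True)
    n_blocks = block_of.max() + 1 if m else 0

    dos = np.zeros((n, m), dtype=np.int8)
    for b in range(n_blocks):
        cols = np.flatnonzero(block_of == b)
        for s in range(n_subpops):
            members = np.flatnonzero(subpop == s)
            if members.size == 0:
                continue
            # single-marker blocks carry no LD, so haplotypes are drawn
            # directly from the subpopulation frequency (no pool bottleneck);
            # multi-marker blocks copy from a small pool, which is the LD device
            pool_n = haplotype_pool if cols.size > 1 else 2 * members.size + 4
            pool = (rng.random((pool_n, cols.size)) < pk[s, cols]).astype(np.int8)
            if family_size > 1:
                h1 = np.empty(members.size, dtype=int)
                h2 = np.empty(members.size, dtype=int)
                for f in np.unique(families[members]):
                    sibs = np.flatnonzero(families[members] == f)
                    par = rng.integers(0, pool_n, size=4)  # two parents x two haplotypes
                    h1[sibs] = par[rng.integers(0, 2, size=sibs.size)]
                    h2[sibs] = par[2 + rng.integers(0, 2, size=sibs.size)]
            else:
                h1 = rng.integers(0, pool_n, size=members.size)
                h2 = rng.integers(0, pool_n, size=members.size)
            dos[np.ix_(members, cols)] = pool[h1] + pool[h2]

    # missingness before allele-orientation so minor allele reflects observed calls
    if missing_rate > 0.0:
        mask = rng.random((n, m)) < missing_rate
        dos[mask] = MISSING

    # orient dosage to count the minor allele; ties broken lexicographically
    obs = dos != MISSING
    with np.errstate(invalid="ignore"):
        f = np.where(obs, dos, 0).sum(axis=0) / np.maximum(2.0 * obs.sum(axis=0), 1.0)
    flip = (f > 0.5) | ((f == 0.5) & (a1 > a2))
    for j in np.flatnonzero(flip):
        col = dos[:, j]
        col[col != MISSING] = 2 - col[col != MISSING]
    minor = np.where(flip, a2, a1)
    major = np.where(flip, a1, a2)

    width = max(4, len(str(m)))
    marker_map = pd.DataFrame(
        {
            "chrom": chrom_labels,
            "pos": pos.astype(np.int64),
            "id": [f"M{j + 1:0{width}d}" for j in range(m)],
            "minor": minor,
            "major": major,
        }
    )
    taxa = [f"tax{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(dos, taxa, marker_map, groups=subpop, families=families)


def simulate_trait(
    geno: GenotypeMatrix,
    n_qtl: int,
    h2_target: float,
    effect_dist: str = "normal",
    n_reps: int = 1,
    seed=None,
    name: str | None = None,
) -> tuple[PhenotypeVector, TraitArchitecture]:
    """Simulate a quantitative trait with a target broad-sense heritability.

    Q causal markers are sampled without replacement; the genetic value is
    the dosage-weighted sum of their effects.  The per-observation noise
    variance is ``r * var(g) * (1 - H) / H`` so that the line means over r
    replicates realize heritability H under the broad-sense formula.
    """
    if n_qtl < 1:
        raise ParameterError("n_qtl must be >= 1")
    if n_qtl > geno.n_markers:
        raise ParameterError("n_qtl exceeds the number of markers")
    if not (0.0 < h2_target <= 1.0):
        raise ParameterError("h2_target must lie in (0, 1]")
    if n_reps < 1:
        raise ParameterError("n_reps must be >= 1")

    rng = _rng(seed)
    causal = np.sort(rng.choice(geno.n_markers, size=n_qtl, replace=False))
    if effect_dist == "normal":
        effects = rng.standard_normal(n_qtl)
    elif effect_dist == "geometric":
        effects = 0.9 ** np.arange(n_qtl) * rng.choice([-1.0, 1.0], size=n_qtl)
    else:
        raise ParameterError(f"unknown effect_dist {effect_dist!r}")

    g = geno.dosages_filled()[:, causal] @ effects
    var_g = float(np.var(g, ddof=1))
    if var_g <= 0.0:
        raise ParameterError("genetic variance is zero (all sampled QTLs monomorphic)")

    if h2_target >= 1.0:
        sigma2_obs = 0.0
    else:
        sigma2_obs = n_reps * var_g * (1.0 - h2_target) / h2_target

    n = geno.n_individuals
    if n_reps == 1:
        values = g + rng.normal(0.0, np.sqrt(sigma2_obs), size=n)
    else:
        values = g[:, None] + rng.normal(0.0, np.sqrt(sigma2_obs), size=(n, n_reps))

    arch = TraitArchitecture(causal, effects, h2_target, n_reps=n_reps,
                             seed=None if isinstance(seed, np.random.Generator) else seed)
    phen = PhenotypeVector(values, list(geno.taxa),
                           name=name or f"H{int(round(h2_target * 100))}_Q{n_qtl}")
    return phen, arch


def realized_heritability(
    phen: PhenotypeVector, geno: GenotypeMatrix, arch: TraitArchitecture
) -> float:
    """Realized var(g)/var(y) on line means for a simulated trait."""
    g = arch.genetic_values(geno)
    y = phen.line_means()
    return float(np.var(g, ddof=1) / np.var(y, ddof=1))


def simulate_structured_null(
    geno: GenotypeMatrix,
    kinship_h2: float = 0.5,
    subpop_effect: float = 0.5,
    seed=None,
) -> PhenotypeVector:
    """Phenotype with structure/relatedness signal but no individual QTL.

    Draws a polygenic background u ~ N(0, sigma_a^2 K) (VanRaden kinship,
    ``kinship_h2`` of the non-shift variance) plus a subpopulation mean
    shift of ``subpop_effect`` phenotypic standard deviations, plus i.i.d.
    noise.  Association scans against such a phenotype probe confounding:
    every marker is null, yet markers correlated with structure inflate
    naive tests.
    """
    if not (0.0 <= kinship_h2 < 1.0):
        raise ParameterError("kinship_h2 must lie in [0, 1)")
    rng = _rng(seed)
    n = geno.n_individuals
    from .structure import compute_kinship

    K = compute_kinship(geno, "VanRaden").values
    s, U = np.linalg.eigh((K + K.T) / 2.0)
    s = np.clip(s, 0.0, None)
    u = U @ (np.sqrt(s * kinship_h2) * rng.standard_normal(n))
    e = rng.normal(0.0, np.sqrt(1.0 - kinship_h2), size=n)
    y = u + e
    if subpop_effect != 0.0 and geno.groups is not None:
        shift = subpop_effect * np.std(y, ddof=1)
        y = y + shift * (geno.groups - np.mean(geno.groups))
    return PhenotypeVector(y, list(geno.taxa), name="structured_null")


def qc_filter(
    geno: GenotypeMatrix, maf_min: float = 0.05, miss_max: float = 0.10
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the standard marker quality-control rules.

    Removes, in order: monomorphic markers, markers with MAF <= ``maf_min``
    (boundary removed), and markers with missing fraction strictly greater
    than ``miss_max``.  MAF is computed on non-missing calls only; the
    three removal categories are disjoint in that order.
    """
    if not (0.0 <= maf_min <= 0.5):
        raise ParameterError("maf_min must lie in [0, 0.5]")
    if not (0.0 <= miss_max <= 1.0):
        raise ParameterError("miss_max must lie in [0, 1]")

    dos = geno.dosages
    obs = dos != MISSING
    n_obs = obs.sum(axis=0)
    # monomorphic: at most one distinct observed dosage value
    mono = np.empty(geno.n_markers, dtype=bool)
    for j in range(geno.n_markers):
        vals = np.unique(dos[obs[:, j], j])
        mono[j] = vals.size <= 1
    maf = geno.maf()
    maf = np.where(n_obs > 0, maf, 0.0)
    low_maf = (~mono) & (maf <= maf_min)
    high_miss = (~mono) & (~low_maf) & (geno.missing_fraction() > miss_max)
    keep = ~(mono | low_maf | high_miss)

    report = QCReport(
        n_input=geno.n_markers,
        n_monomorphic=int(mono.sum()),
        n_low_maf=int(low_maf.sum()),
        n_high_missing=int(high_miss.sum()),
        n_retained=int(keep.sum()),
    )
    if report.n_retained == 0:
        raise EmptyPanelError("quality control removed every marker")
    return geno.select_markers(np.flatnonzero(keep)), report


def impute_knn(geno: GenotypeMatrix, k: int = 5, window_markers: int = 20) -> GenotypeMatrix:
    """LD-kNN imputation of missing genotype calls.

    For each missing call, the k nearest individuals (1 - IBS distance over
    the non-missing markers in a ``window_markers``-wide window on the same
    chromosome) that are observed at the target marker vote with
    inverse-distance weights; the weighted mean dosage is rounded to the
    nearest valid dosage.  Observed calls are never modified.  An
    individual with no comparable window markers falls back to the marker
    mode (logged).
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    if window_markers < 1:
        raise ParameterError("window_markers must be >= 1")
    out = geno.copy()
    dos = out.dosages
    if not (dos == MISSING).any():
        return out

    chrom = geno.marker_map["chrom"].to_numpy()
    half = max(1, window_markers // 2)
    n_fallback = 0
    d_float = dos.astype(float)
    miss = dos == MISSING
    for j in np.flatnonzero(miss.any(axis=0)):
        lo = max(0, j - half)
        hi = min(geno.n_markers, j + half + 1)
        win = np.arange(lo, hi)
        win = win[(chrom[win] == chrom[j]) & (win != j)]
        donors = np.flatnonzero(~miss[:, j])
        targets = np.flatnonzero(miss[:, j])
        obs_vals = dos[donors, j].astype(float)
        if donors.size == 0:
            dos[targets, j] = 0
            n_fallback += targets.size
            continue
        mode = np.bincount(dos[donors, j], minlength=3).argmax()
        for i in targets:
            # pairwise shared-marker IBS distance to every donor
            if win.size:
                xi = d_float[i, win]
                xd = d_float[np.ix_(donors, win)]
                ok = (~miss[i, win])[None, :] & (~miss[np.ix_(donors, win)])
                diff = np.where(ok, np.abs(xd - xi[None, :]) / 2.0, 0.0)
                cnt = ok.sum(axis=1)
                with np.errstate(invalid="ignore"):
                    dist = np.where(cnt > 0, diff.sum(axis=1) / np.maximum(cnt, 1), np.inf)
            else:
                dist = np.full(donors.size, np.inf)
            finite = np.isfinite(dist)
            if not finite.any():
                dos[i, j] = mode
                n_fallback += 1
                continue
            order = np.lexsort((donors, dist))  # distance, then index for determinism
            order = order[finite[order]][:k]
            w = 1.0 / (dist[order] + 1e-6)
            val = np.round(np.sum(w * obs_vals[order]) / np.sum(w))
            dos[i, j] = int(np.clip(val, 0, 2))
    if n_fallback:
        logger.warning("impute_knn: %d calls fell back to the marker mode", n_fallback)
    return out
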
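"""Q-Q diagnostics, QTL-recovery scoring and benchmark orchestration.

The benchmark reproduces the structure of a model-comparison table:
for each simulated trait scenario it runs the requested association
models, applies each selection rule (fixed -log10 p threshold and the
multiple-comparison adjustments) and scores the significant markers
against the simulated truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, ParameterError, TraitArchitecture
from .corrections import CORRECTIONS, fixed_threshold_select
from .models import MODEL_RUNNERS, AssocResult, _r2_matrix

logger = logging.getLogger(__name__)


@dataclass
class QQData:
    """Observed vs expected -log10 p with a pointwise concentration band."""

    expected: np.ndarray  # rank 1 (most significant) first
    observed: np.ndarray
    band_lower: np.ndarray
    band_upper: np.ndarray
    band_level: float
    inflation: float  # median observed chi2 / median expected chi2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "expected": self.expected,
                "observed": self.observed,
                "band_lower": self.band_lower,
                "band_upper": self.band_upper,
            }
        )


def inflation_factor(pvec) -> float:
    """Median-based genomic inflation: median chi2 quantile of the observed
    p-values over the null median (0.4549)."""
    p = np.asarray(pvec, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ParameterError("no finite p-values")
    return float(np.median(stats.chi2.isf(p, df=1)) / stats.chi2.ppf(0.5, df=1))


def qq_points(pvec, band_level: float = 0.95) -> QQData:
    """Q-Q data for a p-value vector.

    Expected quantiles follow the (i - 0.5)/m plotting convention; the
    pointwise band comes from Beta(i, m - i + 1) order-statistic quantiles
    at (1 +/- band_level)/2.
    """
    p = np.asarray(pvec, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ParameterError("empty p-value vector")
    if np.any(p <= 0) or np.any(p > 1):
        raise ParameterError("p-values must lie in (0, 1]")
    m = p.size
    ranks = np.arange(1, m + 1)
    observed = -np.log10(np.sort(p))
    expected = -np.log10((ranks - 0.5) / m)
    lo_q = (1.0 - band_level) / 2.0
    hi_q = (1.0 + band_level) / 2.0
    band_lower = -np.log10(stats.beta.ppf(hi_q, ranks, m - ranks + 1))
    band_upper = -np.log10(stats.beta.ppf(lo_q, ranks, m - ranks + 1))
    return QQData(expected, observed, band_lower, band_upper, band_level, inflation_factor(p))


@dataclass
class DetectionReport:
    """QTL-recovery score for one set of significant markers."""

    detected: np.ndarray  # per-QTL flag
    tp: int
    fp: int
    fn: int
    match_rule: str
    assignments: dict  # selected marker index -> QTL position in architecture (or None)

    @property
    def n_qtl(self) -> int:
        return self.detected.size


def score_detection(
    selected,
    architecture: TraitArchitecture,
    geno: GenotypeMatrix,
    match_rule: str = "exact",
    r2_threshold: float = 0.5,
    window_bp: int = 1_000_000,
) -> DetectionReport:
    """Score significant markers against the simulated truth.

    ``exact``: a QTL is detected iff its causal marker is selected.
    ``ld``: a QTL is detected iff any selected marker on the same
    chromosome within ``window_bp`` has r^2 >= ``r2_threshold`` with the
    causal marker.  Each QTL is counted at most once; each selected marker
    is assigned to at most one QTL; unassigned selections count as false
    positives.
    """
    if match_rule not in ("exact", "ld"):
        raise ParameterError(f"unknown match rule {match_rule!r}")
    selected = np.unique(np.asarray(list(selected), dtype=int))
    causal = architecture.causal_indices
    q = causal.size
    detected = np.zeros(q, dtype=bool)
    assignments: dict[int, int | None] = {}

    if match_rule == "exact":
        lookup = {int(cj): qi for qi, cj in enumerate(causal)}
        for j in selected:
            qi = lookup.get(int(j))
            assignments[int(j)] = qi
            if qi is not None:
                detected[qi] = True
    else:
        chrom = geno.marker_map["chrom"].to_numpy()
        pos = geno.marker_map["pos"].to_numpy()
        G = geno.dosages_filled()
        r2 = _r2_matrix(G, causal) if selected.size else np.empty((0, q))
        for j in selected:
            best_qi, best_r2 = None, -1.0
            for qi, cj in enumerate(causal):
                if chrom[j] != chrom[cj] or abs(int(pos[j]) - int(pos[cj])) > window_bp:
                    continue
                if r2[j, qi] >= r2_threshold and r2[j, qi] > best_r2:
                    best_qi, best_r2 = qi, r2[j, qi]
            assignments[int(j)] = best_qi
            if best_qi is not None:
                detected[best_qi] = True
    tp = int(detected.sum())
    fp = sum(1 for v in assignments.values() if v is None)
    return DetectionReport(detected, tp, fp, q - tp, match_rule, assignments)


# ---------------------------------------------------------------------------
# benchmark orchestration


@dataclass
class BenchmarkTable:
    """Significant-marker counts and QTL recovery per model x selection rule."""

    cells: pd.DataFrame  # long format: scenario, model, rule, n_significant, tp, fp, fn, error
    qq: dict = field(default_factory=dict)  # (scenario, model) -> QQData
    provenance: dict = field(default_factory=dict)

    def counts_table(self, scenario: str | None = None) -> pd.DataFrame:
        """Wide table (models x rules) of significant-marker counts."""
        df = self.cells
        if scenario is not None:
            df = df[df["scenario"] == scenario]
        return df.pivot_table(
            index="model", columns="rule", values="n_significant", aggfunc="first", sort=False
        )

    def digest(self) -> str:
        payload = self.cells.drop(columns=["error"]).to_csv(index=False)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def select_significant(pvec: np.ndarray, rule: str, logp_cut: float = 3.5, alpha: float = 0.05):
    """Apply one selection rule to a p-value vector that may contain NaN
    (inestimable markers are never significant).  Returns (indices, extra)."""
    p = np.asarray(pvec, dtype=float)
    finite = np.isfinite(p)
    idx_map = np.flatnonzero(finite)
    if rule == "fixed35":
        sel = fixed_threshold_select(p[finite], logp_cut)
        return idx_map[sel], {}
    if rule not in CORRECTIONS:
        raise ParameterError(f"unknown selection rule {rule!r}")
    if idx_map.size == 0:
        return np.empty(0, dtype=int), {}
    corr = CORRECTIONS[rule](p[finite], alpha=alpha)
    extra = {"pi0": corr.pi0} if corr.pi0 is not None else {}
    return idx_map[corr.rejection_set()], extra


def run_benchmark(config, geno: GenotypeMatrix | None = None) -> BenchmarkTable:
    """Full factorial benchmark: scenarios x models x selection rules.

    ``config`` is a :class:`gwasbench.config.RunConfig`.  A pre-built
    genotype panel may be passed to skip simulation.  Model failures are
    recorded in the corresponding cells and the run continues.
    """
    from .config import RunConfig  # local import to keep module layering acyclic
    from .simulate import impute_knn, qc_filter, simulate_trait
    from .structure import compute_kinship, compute_pcs

    if not isinstance(config, RunConfig):
        raise ParameterError("config must be a RunConfig")

    if geno is None:
        geno = config.build_genotypes()
    if not geno.is_complete():
        geno, _ = qc_filter(geno, config.qc_maf_min, config.qc_miss_max)
        geno = impute_knn(geno)

    covs = compute_pcs(geno, config.n_pcs) if config.n_pcs > 0 else None
    need_k = any(m in ("MLM", "CMLM", "MLMM") for m in config.models)
    K = compute_kinship(geno, "VanRaden") if need_k else None

    rows = []
    qq: dict = {}
    for si, scen in enumerate(config.scenarios):
        seed = scen.seed if scen.seed is not None else config.stage_seed(1000 + si)
        phen, arch = simulate_trait(
            geno, scen.n_qtl, scen.h2, effect_dist=config.effect_dist,
            n_reps=scen.n_reps, seed=seed, name=scen.name,
        )
        sname = phen.name
        for model in config.models:
            opts = dict(config.model_options.get(model, {}))
            try:
                runner = MODEL_RUNNERS[model]
                if model == "ANOVA":
                    res: AssocResult = runner(geno, phen)
                elif model in ("GLM", "SUPER", "FarmCPU", "ECMLM"):
                    res = runner(geno, phen, covariates=covs, **opts)
                else:  # MLM, CMLM, MLMM
                    res = runner(geno, phen, covariates=covs, K=K, **opts)
            except Exception as exc:  # recorded per cell, run continues
                logger.error("model %s failed on %s: %s", model, sname, exc)
                for rule in ["fixed35", *config.corrections]:
                    rows.append(
                        {"scenario": sname, "model": model, "rule": rule,
                         "n_significant": -1, "tp": -1, "fp": -1, "fn": -1,
                         "error": repr(exc)}
                    )
                continue
            qq[(sname, model)] = qq_points(res.p[np.isfinite(res.p)])
            for rule in ["fixed35", *config.corrections]:
                sel, _ = select_significant(res.p, rule, config.logp_cut, config.alpha)
                rep = score_detection(
                    sel, arch, geno, config.match_rule,
                    r2_threshold=config.ld_match_r2, window_bp=config.ld_match_window_bp,
                )
                rows.append(
                    {"scenario": sname, "model": model, "rule": rule,
                     "n_significant": int(sel.size), "tp": rep.tp, "fp": rep.fp,
                     "fn": rep.fn, "error": ""}
                )
    cells = pd.DataFrame(rows)
    prov = {
        "master_seed": config.master_seed,
        "config_digest": config.digest(),
        "n_individuals": geno.n_individuals,
        "n_markers": geno.n_markers,
    }
    return BenchmarkTable(cells, qq, prov)


# ---------------------------------------------------------------------------
# optional plotting (matplotlib imported lazily)


def plot_qq(qq: QQData, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    order = np.argsort(qq.expected)
    ax.fill_between(qq.expected[order], qq.band_lower[order], qq.band_upper[order],
                    color="0.85", label=f"{qq.band_level:.0%} band")
    ax.plot(qq.expected, qq.observed, "o", ms=2, color="C0")
    lim = max(qq.expected.max(), qq.observed.max()) * 1.05
    ax.plot([0, lim], [0, lim], "k--", lw=1)
    ax.set_xlabel("expected -log10 p")
    ax.set_ylabel("observed -log10 p")
    ax.set_title(f"inflation {qq.inflation:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_manhattan(result: AssocResult, path: str, logp_cut: float = 3.5) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = result.frame
    fig, ax = plt.subplots(figsize=(8, 3))
    offset = 0
    ticks, labels = [], []
    for c, sub in df.groupby("Chr", sort=False):
        x = sub["Pos"].to_numpy() + offset
        with np.errstate(divide="ignore"):
            ax.scatter(x, -np.log10(sub["P"]), s=4)
        ticks.append(offset + sub["Pos"].max() / 2)
        labels.append(str(c))
        offset += sub["Pos"].max()
    ax.axhline(logp_cut, color="red", lw=1, ls="--")
    ax.set_xticks(ticks, labels, rotation=90, fontsize=6)
    ax.set_ylabel("-log10 p")
    ax.set_title(result.model)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
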
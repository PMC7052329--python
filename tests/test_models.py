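"""The eight association models: reductions, oracles and contracts."""

import itertools

import numpy as np
import pytest
from scipy import stats

from gwasbench import (
    HeritabilityInputs,
    ParameterError,
    broad_sense_h2,
    compress_kinship,
    compute_kinship,
    estimate_marker_h2,
    fit_variance_components,
    run_anova,
    run_cmlm,
    run_ecmlm,
    run_farmcpu,
    run_glm,
    run_mlm,
    run_mlmm,
    run_super,
    simulate_genotypes,
)
from gwasbench.mixedmodel import VarianceComponents, eigen_kinship
from gwasbench.models import _vanraden, subset_criterion
from conftest import make_genotypes


def finite(p):
    return p[np.isfinite(p)]


class TestANOVA:
    def test_constant_phenotype(self, structured_panel):
        y = np.full(structured_panel.n_individuals, 3.14)
        res = run_anova(structured_panel, y)
        assert np.all(finite(res.p) == 1.0)

    def test_matches_scipy_f_oneway(self):
        dos = np.array([[0], [0], [2], [2]], dtype=np.int8)
        y = np.array([1.0, 2.0, 3.0, 4.0])
        res = run_anova(make_genotypes(dos), y)
        f, p = stats.f_oneway(y[:2], y[2:])
        assert res.p[0] == pytest.approx(p, rel=1e-10)

    def test_three_class_matches_scipy(self):
        rng = np.random.default_rng(12)
        dos = rng.integers(0, 3, size=(40, 5)).astype(np.int8)
        y = rng.standard_normal(40)
        res = run_anova(make_genotypes(dos), y)
        for j in range(5):
            groups = [y[dos[:, j] == d] for d in (0, 1, 2) if np.any(dos[:, j] == d)]
            _, p = stats.f_oneway(*groups)
            assert res.p[j] == pytest.approx(p, rel=1e-9)

    def test_null_p_uniform(self):
        g = simulate_genotypes(150, 5000, n_subpops=1, fst=0.0, family_size=1,
                               block_len_bp=0, seed=71)
        y = np.random.default_rng(72).standard_normal(150)
        res = run_anova(g, y)
        ks = stats.kstest(finite(res.p), "uniform")
        assert ks.pvalue > 0.01

    def test_single_class_marker_flagged(self):
        dos = np.array([[1, 0], [1, 2], [1, 1], [1, 0]], dtype=np.int8)
        res = run_anova(make_genotypes(dos), np.arange(4.0))
        assert np.isnan(res.p[0]) and np.isfinite(res.p[1])


class TestGLM:
    def test_reduces_to_anova_with_two_classes(self):
        rng = np.random.default_rng(2)
        dos = rng.choice([0, 2], size=(50, 10)).astype(np.int8)
        y = rng.standard_normal(50)
        g = make_genotypes(dos)
        pa = run_anova(g, y).p
        pg = run_glm(g, y).p
        ok = np.isfinite(pa) & np.isfinite(pg)
        assert np.allclose(pa[ok], pg[ok], rtol=1e-8)

    def test_collinear_marker_flagged_not_crash(self, structured_panel):
        y = np.random.default_rng(3).standard_normal(structured_panel.n_individuals)
        cov = structured_panel.dosages_filled()[:, [7]]
        res = run_glm(structured_panel, y, covariates=cov)
        assert np.isnan(res.p[7])
        assert np.isfinite(res.p).sum() > 0

    def test_matches_statsmodels_ols(self, structured_panel, structured_pcs):
        import statsmodels.api as sm

        y = np.random.default_rng(4).standard_normal(structured_panel.n_individuals)
        res = run_glm(structured_panel, y, structured_pcs)
        G = structured_panel.dosages_filled()
        poly = np.flatnonzero(structured_panel.maf() > 0.05)
        for j in poly[[0, 30, 100]]:
            X = sm.add_constant(np.column_stack([structured_pcs.scores, G[:, j]]))
            fit = sm.OLS(y, X).fit()
            assert res.p[j] == pytest.approx(fit.pvalues[-1], rel=1e-8)
            assert res.frame["Effect"].iloc[j] == pytest.approx(fit.params[-1], rel=1e-8)


class TestMLM:
    def test_variance_collapse_equals_glm(self, structured_panel, structured_pcs,
                                          structured_kinship, trait60):
        phen, _ = trait60
        vc0 = VarianceComponents(0.0, 1.0, 0.0)
        pm = run_mlm(structured_panel, phen, structured_pcs, structured_kinship,
                     var_components=vc0).p
        pg = run_glm(structured_panel, phen, structured_pcs).p
        ok = np.isfinite(pm) & np.isfinite(pg)
        assert np.allclose(pm[ok], pg[ok], atol=1e-8)

    def test_matches_explicit_gls_oracle(self):
        """Wald p equals a dense generalized-least-squares fit on a small
        panel with known variance components (1e-6 relative)."""
        rng = np.random.default_rng(6)
        dos = rng.integers(0, 3, size=(8, 6)).astype(np.int8)
        g = make_genotypes(dos)
        K = compute_kinship(g, "VanRaden")
        y = rng.standard_normal(8)
        sa, se = 2.0, 1.0
        res = run_mlm(g, y, None, K, var_components=VarianceComponents(sa, se, 0.0))
        V = sa * K.values + se * np.eye(8)
        Vi = np.linalg.inv(V)
        G = g.dosages_filled()
        for j in range(6):
            X = np.column_stack([np.ones(8), G[:, j]])
            XtVi = X.T @ Vi
            beta = np.linalg.solve(XtVi @ X, XtVi @ y)
            r = y - X @ beta
            scale = float(r @ Vi @ r) / (8 - 2)
            cov = scale * np.linalg.inv(XtVi @ X)
            t = beta[1] / np.sqrt(cov[1, 1])
            p = 2 * stats.t.sf(abs(t), 8 - 2)
            if np.isfinite(res.p[j]):
                assert res.p[j] == pytest.approx(p, rel=1e-6)
                assert res.frame["Effect"].iloc[j] == pytest.approx(beta[1], rel=1e-6)

    def test_marker_order_preserved(self, structured_panel, structured_pcs,
                                    structured_kinship, trait60):
        phen, _ = trait60
        res = run_mlm(structured_panel, phen, structured_pcs, structured_kinship)
        assert res.frame["SNP"].tolist() == structured_panel.marker_map["id"].tolist()
        assert np.all(finite(res.p) > 0) and np.all(finite(res.p) <= 1)


class TestCMLM:
    def test_no_compression_equals_mlm(self, structured_panel, structured_pcs,
                                       structured_kinship, trait60):
        phen, _ = trait60
        n = structured_panel.n_individuals
        pc = run_cmlm(structured_panel, phen, structured_pcs, structured_kinship,
                      group_grid=[n]).p
        pm = run_mlm(structured_panel, phen, structured_pcs, structured_kinship).p
        ok = np.isfinite(pc) & np.isfinite(pm)
        assert np.allclose(pc[ok], pm[ok], atol=1e-6)

    def test_selection_matches_exhaustive_grid(self, structured_panel, structured_pcs,
                                               structured_kinship, trait60):
        phen, _ = trait60
        grid = [1, 15, 40, 80, 120]
        res = run_cmlm(structured_panel, phen, structured_pcs, structured_kinship,
                       group_grid=grid)
        # oracle: evaluate every group count independently
        y = phen.line_means()
        X0 = np.column_stack([np.ones(len(y)), structured_pcs.scores])
        best_g, best_ll = None, -np.inf
        for g in grid:
            scheme = compress_kinship(structured_kinship, g)
            vc = fit_variance_components(y, X0, scheme.effective_kinship())
            if vc.log_reml > best_ll:
                best_g, best_ll = g, vc.log_reml
        assert res.metadata["n_groups"] == best_g
        assert res.metadata["log_reml"] == pytest.approx(best_ll, abs=1e-4)

    def test_two_subpop_groups_align(self):
        g = simulate_genotypes(100, 500, n_subpops=2, fst=0.3, family_size=1,
                               block_len_bp=0, seed=19)
        K = compute_kinship(g, "VanRaden")
        scheme = compress_kinship(K, 2)
        agree = np.mean(scheme.assignment == g.groups)
        assert max(agree, 1 - agree) > 0.9

    def test_empty_grid_error(self, structured_panel, structured_pcs,
                              structured_kinship, trait60):
        phen, _ = trait60
        with pytest.raises(ParameterError):
            run_cmlm(structured_panel, phen, structured_pcs, structured_kinship,
                     group_grid=[])


class TestECMLM:
    def test_singleton_search_equals_cmlm(self, structured_panel, structured_pcs,
                                          trait60):
        phen, _ = trait60
        K = compute_kinship(structured_panel, "VanRaden")
        grid = [10, 60, 120]
        pe = run_ecmlm(structured_panel, phen, structured_pcs,
                       kinship_methods=("VanRaden",), linkages=("average",),
                       summaries=("mean",), group_grid=grid)
        pc = run_cmlm(structured_panel, phen, structured_pcs, K, group_grid=grid)
        ok = np.isfinite(pe.p) & np.isfinite(pc.p)
        assert np.allclose(pe.p[ok], pc.p[ok], atol=1e-8)

    def test_selection_matches_exhaustive_combination_scan(self, structured_panel,
                                                           structured_pcs, trait60):
        phen, _ = trait60
        methods, links, sums = ("IBS", "VanRaden"), ("average", "complete"), ("mean", "max")
        grid = [10, 60, 120]
        res = run_ecmlm(structured_panel, phen, structured_pcs, methods, links, sums,
                        group_grid=grid)
        y = phen.line_means()
        X0 = np.column_stack([np.ones(len(y)), structured_pcs.scores])
        best = (None, -np.inf)
        for me, li, su in itertools.product(methods, links, sums):
            K = compute_kinship(structured_panel, me)
            for g in grid:
                scheme = compress_kinship(K, g, li, su)
                vc = fit_variance_components(y, X0, scheme.effective_kinship())
                if vc.log_reml > best[1]:
                    best = ((me, li, su), vc.log_reml)
        chosen = (res.metadata["kinship_method"], res.metadata["linkage"],
                  res.metadata["summary"])
        assert chosen == best[0]
        assert res.metadata["log_reml"] == pytest.approx(best[1], abs=1e-4)

    def test_metadata_names_selected_triple(self, structured_panel, structured_pcs,
                                            trait60):
        phen, _ = trait60
        res = run_ecmlm(structured_panel, phen, structured_pcs, group_grid=[30, 120])
        assert res.metadata["kinship_method"] in ("IBS", "VanRaden")
        assert res.metadata["linkage"] in ("average", "complete", "single")
        assert res.metadata["summary"] in ("mean", "median", "max")

    def test_empty_enumeration_error(self, structured_panel, trait60):
        phen, _ = trait60
        with pytest.raises(ParameterError):
            run_ecmlm(structured_panel, phen, None, kinship_methods=())


class TestSUPER:
    def test_own_qtn_excluded_from_kinship(self, structured_panel, structured_pcs,
                                           trait60):
        """A pseudo-QTN's own test uses a kinship that provably differs from
        the full pseudo-QTN kinship."""
        phen, _ = trait60
        res = run_super(structured_panel, phen, structured_pcs)
        qtns = res.metadata["pseudo_qtns"]
        assert len(qtns) >= 2
        # recompute the test for one QTN with the *full* QTN kinship
        y = phen.line_means()
        X0 = np.column_stack([np.ones(len(y)), structured_pcs.scores])
        G = structured_panel.dosages_filled()
        kq = _vanraden(G[:, qtns])
        lam = res.metadata["sigma_a2"] / res.metadata["sigma_e2"]
        s, U = eigen_kinship(kq)
        from gwasbench.mixedmodel import wald_scan, whiten

        j = int(qtns[0])
        yw, Xw, Gw = whiten(y, X0, G[:, [j]], s, U, lam)
        p_full = wald_scan(yw, Xw, Gw).p[0]
        assert np.isfinite(res.p[j])
        assert res.p[j] != pytest.approx(p_full, rel=1e-6)

    def test_selection_matches_exhaustive_grid(self, structured_panel, structured_pcs,
                                               trait60):
        phen, _ = trait60
        bins = [50_000, 500_000]
        counts = [2, 4, 8]
        res = run_super(structured_panel, phen, structured_pcs, bin_grid=bins,
                        qtn_count_grid=counts)
        y = phen.line_means()
        X0 = np.column_stack([np.ones(len(y)), structured_pcs.scores])
        G = structured_panel.dosages_filled()
        p0 = run_glm(structured_panel, phen, structured_pcs).p
        p0 = np.where(np.isfinite(p0), p0, 1.0)
        chrom = structured_panel.marker_map["chrom"].to_numpy()
        pos = structured_panel.marker_map["pos"].to_numpy()
        best = (None, -np.inf)
        for b in bins:
            # rank bins by their best marker p
            order = np.lexsort((np.arange(len(p0)), p0))
            seen, ranked = set(), []
            for j in order:
                key = (chrom[j], pos[j] // b)
                if key not in seen:
                    seen.add(key)
                    ranked.append(j)
            for t in counts:
                if t > len(ranked):
                    continue
                sel = np.asarray(ranked[:t])
                try:
                    vc = fit_variance_components(y, X0, _vanraden(G[:, sel]))
                except ParameterError:
                    continue
                if vc.log_reml > best[1]:
                    best = ((b, t), vc.log_reml)
        assert (res.metadata["bin_size"], res.metadata["n_qtns"]) == best[0]
        assert res.metadata["log_reml"] == pytest.approx(best[1], abs=1e-4)


class TestMLMM:
    def test_zero_cofactors_equals_mlm(self, structured_panel, structured_pcs,
                                       structured_kinship, trait60):
        phen, _ = trait60
        pm = run_mlmm(structured_panel, phen, structured_pcs, structured_kinship,
                      max_cofactors=0).p
        p0 = run_mlm(structured_panel, phen, structured_pcs, structured_kinship).p
        ok = np.isfinite(pm) & np.isfinite(p0)
        assert np.allclose(pm[ok], p0[ok], atol=1e-8)

    def test_first_step_selects_dominant_qtl(self):
        g = simulate_genotypes(150, 200, n_chromosomes=2, seed=61)
        G = g.dosages_filled()
        rng = np.random.default_rng(62)
        j = 117
        gv = G[:, j]
        y = gv + rng.normal(0, np.sqrt(np.var(gv, ddof=1) * 0.6 / 0.4), 150)
        K = compute_kinship(g, "VanRaden")
        res = run_mlmm(g, y, None, K, max_cofactors=3)
        cof = res.metadata["cofactors"]
        assert len(cof) >= 1
        first = int(cof[0]) if len(cof) == 1 else int(
            min(cof, key=lambda c: abs(c - j))
        )
        r = np.corrcoef(G[:, first], gv)[0, 1] ** 2
        assert r > 0.99

    def test_matches_exhaustive_best_subset(self):
        """Stepwise selection agrees with exhaustive best-subset search
        under the same extended-BIC criterion (m = 15, up to 3 cofactors)."""
        rng = np.random.default_rng(63)
        g = simulate_genotypes(80, 15, n_chromosomes=1, n_subpops=1, fst=0.0,
                               family_size=1, block_len_bp=0, seed=63)
        G = g.dosages_filled()
        y = 1.5 * G[:, 3] - 1.2 * G[:, 11] + rng.normal(0, 1.0, 80)
        K = compute_kinship(g, "VanRaden")
        res = run_mlmm(g, y, None, K, max_cofactors=3)
        yv = np.asarray(y, float)
        X0 = np.ones((80, 1))
        eig = eigen_kinship(K.values)
        best = (None, np.inf)
        for k in range(4):
            for sub in itertools.combinations(range(15), k):
                score = subset_criterion(yv, X0, G, eig, sub, 15, "ebic")
                if score < best[1]:
                    best = (set(sub), score)
        assert set(int(c) for c in res.metadata["cofactors"]) == best[0]

    def test_unknown_criterion(self, structured_panel, structured_kinship, trait60):
        phen, _ = trait60
        with pytest.raises(ParameterError):
            run_mlmm(structured_panel, phen, None, structured_kinship,
                     criterion="aicc")


class TestFarmCPU:
    def test_null_trait_equals_glm(self, structured_panel, structured_pcs):
        """With no marker near significance the scan never recruits
        pseudo-QTNs and reduces to the fixed-effect (GLM) scan."""
        y = np.random.default_rng(81).standard_normal(structured_panel.n_individuals)
        pf = run_farmcpu(structured_panel, y, structured_pcs)
        pg = run_glm(structured_panel, y, structured_pcs)
        assert pf.metadata["pseudo_qtns"].size == 0
        ok = np.isfinite(pf.p) & np.isfinite(pg.p)
        assert np.allclose(pf.p[ok], pg.p[ok], atol=1e-8)

    def test_unified_qtn_pvalues_match_refit(self, structured_panel, structured_pcs):
        """Each pseudo-QTN's reported p equals a from-scratch least-squares
        refit that tests it with the other pseudo-QTNs as covariates."""
        phen, _ = __import__("gwasbench").simulate_trait(structured_panel, 5, 0.8, seed=83)
        res = run_farmcpu(structured_panel, phen, structured_pcs)
        qtns = [int(q) for q in res.metadata["pseudo_qtns"]]
        assert qtns, "expected at least one pseudo-QTN on a strong trait"
        y = phen.line_means()
        G = structured_panel.dosages_filled()
        for j in qtns:
            others = [q for q in qtns if q != j]
            X = np.column_stack([np.ones(len(y)), structured_pcs.scores,
                                 G[:, others], G[:, j]])
            beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            df = len(y) - X.shape[1]
            sigma2 = float(r @ r) / df
            XtXi = np.linalg.inv(X.T @ X)
            t = beta[-1] / np.sqrt(sigma2 * XtXi[-1, -1])
            p = 2 * stats.t.sf(abs(t), df)
            assert res.p[j] == pytest.approx(p, rel=1e-6)

    def test_single_hit_in_ld_block(self):
        from gwasbench.models import _r2_matrix
        from gwasbench import fixed_threshold_select

        g = simulate_genotypes(200, 500, n_chromosomes=2, n_subpops=1, fst=0.0,
                               family_size=1, block_len_bp=120_000,
                               haplotype_pool=4, seed=4)
        G = g.dosages_filled()
        best_j, proxies = 0, np.array([0])
        for j in range(0, g.n_markers, 7):
            pr = np.flatnonzero(_r2_matrix(G, np.array([j]))[:, 0] >= 0.5)
            if pr.size > proxies.size:
                best_j, proxies = j, pr
        assert proxies.size >= 3
        rng = np.random.default_rng(500)
        gv = G[:, best_j]
        y = gv + rng.normal(0, np.sqrt(np.var(gv, ddof=1) * 0.6 / 0.4), 200)
        pf = run_farmcpu(g, y, None).p
        sel = set(fixed_threshold_select(np.where(np.isfinite(pf), pf, 1.0)))
        assert len(sel & {int(x) for x in proxies}) == 1


class TestHeritability:
    def test_broad_sense_formula(self):
        assert broad_sense_h2(HeritabilityInputs(2.0, 2.0, 2)) == pytest.approx(2 / 3)
        assert broad_sense_h2(HeritabilityInputs(0.0, 1.0, 1)) == 0.0
        assert broad_sense_h2(HeritabilityInputs(1.0, 1.0, 10**9)) == pytest.approx(1.0, abs=1e-6)
        with pytest.raises(ParameterError):
            broad_sense_h2(HeritabilityInputs(0.0, 0.0, 1))

    def test_marker_h2_is_component_ratio(self, structured_panel, structured_pcs,
                                          structured_kinship, trait60):
        phen, _ = trait60
        y = phen.line_means()
        h2 = estimate_marker_h2(y, structured_pcs.scores, structured_kinship)
        X0 = np.column_stack([np.ones(len(y)), structured_pcs.scores])
        vc = fit_variance_components(y, X0, structured_kinship.values)
        assert h2 == pytest.approx(vc.h2)

    def test_marker_h2_recovery_and_null(self):
        g = simulate_genotypes(200, 300, seed=91)
        K = compute_kinship(g, "VanRaden")
        eig = eigen_kinship(K.values)
        s, U = eig
        rng = np.random.default_rng(92)
        ests, nulls = [], []
        for _ in range(100):
            u = U @ (np.sqrt(s * 0.7) * rng.standard_normal(200))
            y = u + rng.normal(0, np.sqrt(0.3), 200)
            ests.append(estimate_marker_h2(y, None, K))
            nulls.append(estimate_marker_h2(rng.standard_normal(200), None, K))
        assert abs(np.mean(ests) - 0.7) < 0.05
        assert np.mean(np.asarray(nulls) < 0.1) >= 0.95
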
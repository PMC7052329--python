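"""Synthetic genotype/trait generator, QC rules and kNN imputation."""

import numpy as np
import pytest

from gwasbench import (
    MISSING,
    EmptyPanelError,
    ParameterError,
    impute_knn,
    qc_filter,
    realized_heritability,
    simulate_genotypes,
    simulate_trait,
)
from conftest import make_genotypes


class TestSimulateGenotypes:
    def test_domain_and_determinism(self):
        g1 = simulate_genotypes(4, 3, n_chromosomes=1, n_subpops=1, fst=0.0,
                                family_size=1, missing_rate=0.0, seed=42)
        g2 = simulate_genotypes(4, 3, n_chromosomes=1, n_subpops=1, fst=0.0,
                                family_size=1, missing_rate=0.0, seed=42)
        assert set(np.unique(g1.dosages)) <= {0, 1, 2}
        assert np.array_equal(g1.dosages, g2.dosages)
        assert g1.marker_map.equals(g2.marker_map)

    def test_different_seeds_differ(self):
        a = simulate_genotypes(30, 100, seed=1)
        b = simulate_genotypes(30, 100, seed=2)
        assert not np.array_equal(a.dosages, b.dosages)

    def test_fst_recovery(self):
        """Hudson-type Fst from realized subpopulation allele frequencies
        recovers the Balding-Nichols divergence parameter."""
        target = 0.4
        g = simulate_genotypes(400, 1000, n_subpops=2, fst=target, family_size=1,
                               block_len_bp=0, maf_range=(0.1, 0.5), seed=9)
        d = g.dosages.astype(float)
        num, den = [], []
        for s, t in [(0, 1)]:
            a = d[g.groups == s]
            b = d[g.groups == t]
            p1, p2 = a.mean(0) / 2, b.mean(0) / 2
            n1, n2 = len(a), len(b)
            num.append((p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1))
            den.append(p1 * (1 - p2) + p2 * (1 - p1))
        fst_hat = np.concatenate(num).mean() / np.concatenate(den).mean()
        assert abs(fst_hat - target) < 0.05

    def test_missing_rate_binomial(self):
        rate, n, m = 0.05, 100, 2000
        g = simulate_genotypes(n, m, missing_rate=rate, seed=3)
        frac = (g.dosages == MISSING).mean()
        assert abs(frac - rate) <= 3 * np.sqrt(rate * (1 - rate) / (n * m))

    def test_positions_sorted_and_ids_unique(self, structured_panel):
        structured_panel.validate()  # raises on any invariant violation

    @pytest.mark.parametrize("bad", [
        dict(n_individuals=1), dict(fst=1.0), dict(fst=-0.1),
        dict(maf_range=(0.0, 0.5)), dict(maf_range=(0.1, 0.6)),
        dict(missing_rate=1.0), dict(family_size=0),
    ])
    def test_parameter_errors(self, bad):
        kwargs = dict(n_individuals=10, n_markers=20, seed=0)
        kwargs.update(bad)
        with pytest.raises(ParameterError):
            simulate_genotypes(**kwargs)


class TestSimulateTrait:
    def test_noise_free_limit(self, structured_panel):
        phen, arch = simulate_trait(structured_panel, 5, 1.0, seed=1)
        g = arch.genetic_values(structured_panel)
        assert np.allclose(phen.values, g)

    def test_qtl_count_contract(self, structured_panel):
        _, arch = simulate_trait(structured_panel, 20, 0.5, seed=2)
        assert arch.n_qtl == 20
        assert len(np.unique(arch.causal_indices)) == 20

    def test_determinism(self, structured_panel):
        p1, a1 = simulate_trait(structured_panel, 8, 0.4, seed=7)
        p2, a2 = simulate_trait(structured_panel, 8, 0.4, seed=7)
        assert np.array_equal(p1.values, p2.values)
        assert np.array_equal(a1.causal_indices, a2.causal_indices)
        assert np.array_equal(a1.effects, a2.effects)

    def test_rejects_degenerate_inputs(self, structured_panel):
        with pytest.raises(ParameterError):
            simulate_trait(structured_panel, 0, 0.5)
        with pytest.raises(ParameterError):
            simulate_trait(structured_panel, 5, 0.0)
        with pytest.raises(ParameterError):
            simulate_trait(structured_panel, structured_panel.n_markers + 1, 0.5)

    def test_heritability_calibration(self):
        """Mean realized var(g)/var(y) tracks the target within +-0.05."""
        g = simulate_genotypes(200, 500, seed=17)
        vals = []
        for r in range(100):
            phen, arch = simulate_trait(g, 10, 0.6, seed=5000 + r)
            vals.append(realized_heritability(phen, g, arch))
        assert abs(np.mean(vals) - 0.6) < 0.05

    def test_replicated_observations(self, structured_panel):
        phen, arch = simulate_trait(structured_panel, 5, 0.5, n_reps=3, seed=4)
        assert phen.values.shape == (structured_panel.n_individuals, 3)
        assert phen.line_means().shape == (structured_panel.n_individuals,)


class TestQCFilter:
    def test_rules_on_hand_panel(self):
        # 10 individuals; columns: monomorphic, MAF exactly 0.05 (one het of
        # 20 alleles, boundary removed), MAF 0.10 (retained), high missing
        dos = np.zeros((10, 4), dtype=np.int8)
        dos[:, 1] = [1] + [0] * 9          # MAF 1/20 = 0.05
        dos[:, 2] = [1, 1] + [0] * 8       # MAF 2/20 = 0.10
        dos[:, 3] = [MISSING, MISSING, 1, 1, 1, 0, 0, 0, 0, 0]  # 20% missing
        g = make_genotypes(dos)
        out, rep = qc_filter(g, maf_min=0.05, miss_max=0.10)
        assert rep.n_monomorphic == 1
        assert rep.n_low_maf == 1
        assert rep.n_high_missing == 1
        assert rep.n_retained == 1
        assert out.marker_map["id"].tolist() == ["S003"]

    def test_six_individual_maf_boundary(self):
        # one heterozygote among six individuals: MAF = 1/12 > 0.05, retained
        dos = np.zeros((6, 2), dtype=np.int8)
        dos[:, 0] = [1, 0, 0, 0, 0, 0]
        dos[:, 1] = [1, 1, 0, 2, 0, 0]
        g = make_genotypes(dos)
        out, rep = qc_filter(g)
        assert rep.n_low_maf == 0 and rep.n_retained == 2

    def test_clean_panel_identity(self, structured_panel):
        clean, _ = qc_filter(structured_panel)
        out, rep = qc_filter(clean)
        assert rep.n_monomorphic == rep.n_low_maf == rep.n_high_missing == 0
        assert np.array_equal(out.dosages, clean.dosages)

    def test_idempotence(self):
        g = simulate_genotypes(60, 300, missing_rate=0.05, maf_range=(0.02, 0.5), seed=8)
        once, _ = qc_filter(g)
        twice, rep2 = qc_filter(once)
        assert np.array_equal(once.dosages, twice.dosages)
        assert rep2.n_retained == once.n_markers

    def test_all_removed_raises(self):
        dos = np.zeros((5, 3), dtype=np.int8)
        with pytest.raises(EmptyPanelError):
            qc_filter(make_genotypes(dos))


class TestImputeKNN:
    def test_no_missing_identity(self, structured_panel):
        out = impute_knn(structured_panel)
        assert np.array_equal(out.dosages, structured_panel.dosages)

    def test_unanimous_neighbors(self):
        # individual 0 missing at the last marker; its 3 nearest neighbors
        # (identical elsewhere) all carry dosage 2 there
        base = np.array([1, 0, 2, 1, 0, 2, 1, 0], dtype=np.int8)
        far = np.array([0, 2, 0, 0, 2, 0, 0, 2], dtype=np.int8)
        dos = np.vstack(
            [np.append(base, MISSING)]
            + [np.append(base, 2)] * 3
            + [np.append(far, 0)] * 4
        )
        g = make_genotypes(dos)
        out = impute_knn(g, k=3, window_markers=20)
        assert out.dosages[0, -1] == 2
        assert out.is_complete()

    def test_observed_calls_never_modified(self):
        g = simulate_genotypes(40, 100, missing_rate=0.1, seed=13)
        obs = g.dosages != MISSING
        out = impute_knn(g)
        assert np.array_equal(out.dosages[obs], g.dosages[obs])
        assert out.is_complete()

    def test_matches_exhaustive_neighbor_oracle(self):
        """One missing call in a 10 x 20 toy equals a brute-force
        nearest-neighbor search over all individuals."""
        rng = np.random.default_rng(99)
        dos = rng.integers(0, 3, size=(10, 20)).astype(np.int8)
        dos[4, 7] = MISSING
        g = make_genotypes(dos.copy())
        out = impute_knn(g, k=5, window_markers=40)  # window spans all markers

        # oracle: 1 - IBS over every other marker, 5 nearest, inverse-distance vote
        dists = []
        for i in range(10):
            if i == 4:
                continue
            others = [j for j in range(20) if j != 7]
            d = np.mean(np.abs(dos[4, others] - dos[i, others]) / 2.0)
            dists.append((d, i))
        dists.sort()
        top = dists[:5]
        w = np.array([1.0 / (d + 1e-6) for d, _ in top])
        vals = np.array([dos[i, 7] for _, i in top], dtype=float)
        expected = int(np.clip(np.round(np.sum(w * vals) / np.sum(w)), 0, 2))
        assert out.dosages[4, 7] == expected
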
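from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from stockload.genotype_io import MISSING
from stockload.ordination import (
    broken_stick, dapc, forward_select, hellinger_stocking,
    impute_by_population, partial_rda, pca_broken_stick, pcoa,
    permutation_anova, rda, vif,
)

from conftest import make_genotypes, two_pop_map


class TestPcoa:
    def test_planar_points_recover_distances(self, rng):
        pts = rng.normal(size=(5, 2))
        d = squareform(pdist(pts))
        res = pcoa(d)
        pos = res.eigenvalues > 1e-9
        assert pos.sum() == 2
        rec = squareform(pdist(res.scores))
        assert np.sqrt(((rec - d) ** 2).mean()) < 1e-8

    def test_zero_matrix(self):
        res = pcoa(np.zeros((4, 4)))
        assert res.scores.shape[1] == 0
        assert not res.retained.any()

    def test_matches_pca_on_euclidean_distances(self, rng):
        x = rng.normal(size=(10, 4))
        d = squareform(pdist(x))
        res = pcoa(d)
        xc = x - x.mean(axis=0)
        u, s, _ = np.linalg.svd(xc, full_matrices=False)
        pca_scores = u * s
        for j in range(4):
            r = np.corrcoef(res.scores[:, j], pca_scores[:, j])[0, 1]
            assert abs(abs(r) - 1) < 1e-8

    def test_cross_checked_against_skbio(self, rng):
        from skbio.stats.ordination import pcoa as skbio_pcoa
        x = rng.normal(size=(8, 3))
        d = squareform(pdist(x))
        ours = pcoa(d)
        theirs = skbio_pcoa(d, method="eigh")
        pos = np.asarray(theirs.eigvals) > 1e-9
        assert np.allclose(np.sort(ours.eigenvalues[ours.eigenvalues > 1e-9]),
                           np.sort(np.asarray(theirs.eigvals)[pos]), rtol=1e-8)

    def test_asymmetric_rejected(self):
        d = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError):
            pcoa(d)


class TestHellinger:
    def setup_method(self):
        self.lakes = pd.DataFrame(
            {"lake_code": ["A", "B", "C"], "area_ha": [1.0, 1.0, 1.0]}
        ).set_index("lake_code")

    def test_single_source_row(self):
        sm = pd.DataFrame([[4.0, 0.0]], index=["A"], columns=["s1", "s2"])
        out = hellinger_stocking(sm, self.lakes)
        assert out.loc["A"].tolist() == [1.0, 0.0]

    def test_hand_computed_row(self):
        sm = pd.DataFrame([[1.0, 1.0, 2.0]], index=["B"], columns=list("xyz"))
        out = hellinger_stocking(sm, self.lakes)
        assert np.allclose(out.loc["B"], [0.5, 0.5, np.sqrt(0.5)])

    def test_zero_row_stays_zero(self):
        sm = pd.DataFrame([[0.0, 0.0], [2.0, 2.0]], index=["A", "C"],
                          columns=["s1", "s2"])
        out = hellinger_stocking(sm, self.lakes)
        assert out.loc["A"].tolist() == [0.0, 0.0]
        assert not out.isna().any().any()

    def test_area_normalization_matters(self):
        lakes = pd.DataFrame({"lake_code": ["A", "B"], "area_ha": [1.0, 100.0]}
                             ).set_index("lake_code")
        sm = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]], index=["A", "B"],
                          columns=["s1", "s2"])
        out = hellinger_stocking(sm, lakes)
        # Hellinger is row-relative, so equal compositions coincide even at
        # different densities; the transform must stay finite and bounded
        assert np.allclose(out.loc["A"], out.loc["B"])


class TestBrokenStick:
    def test_p3_values(self):
        assert np.allclose(broken_stick(3), [0.6111, 0.2778, 0.1111], atol=5e-5)

    def test_sums_to_one_exact_rationals(self):
        for p in range(1, 11):
            expect = [sum(Fraction(1, i) for i in range(k, p + 1)) / p
                      for k in range(1, p + 1)]
            assert sum(expect) == 1
            assert np.allclose(broken_stick(p), [float(e) for e in expect])

    def test_p1_retention(self):
        res = pca_broken_stick(np.array([[1.0], [2.0], [4.0]]))
        assert res.broken_stick.tolist() == [1.0]
        assert res.retained.tolist() == [True]

    def test_planted_two_factor_structure(self):
        """With two strong latent factors plus noise, exactly two axes beat
        the broken stick across seeded replicates."""
        load = np.zeros((2, 8))
        load[0, :4] = 0.5
        load[1, 4:] = 0.5          # orthonormal loading rows
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            f = rng.normal(size=(60, 2))
            x = f @ (load * np.array([[6.0], [4.0]])) + 0.3 * rng.normal(size=(60, 8))
            res = pca_broken_stick(x)
            hits += int(res.retained.sum() == 2)
        assert hits == 20

    def test_constant_matrix_retains_nothing(self):
        res = pca_broken_stick(np.ones((5, 3)))
        assert not res.retained.any()


class TestRda:
    def test_perfect_fit(self, rng):
        x = rng.normal(size=(20, 1))
        assert rda(x, x).r2 == pytest.approx(1.0)

    def test_univariate_equals_ols(self, rng):
        x = rng.normal(size=(40, 3))
        y = x @ np.array([1.0, -2.0, 0.5]) + rng.normal(size=40)
        res = rda(y, x)
        # independent OLS R^2
        xc = np.hstack([np.ones((40, 1)), x])
        beta, *_ = np.linalg.lstsq(xc, y, rcond=None)
        resid = y - xc @ beta
        r2 = 1 - resid.var() / y.var()
        assert abs(res.r2 - r2) < 1e-10
        # Ezekiel adjustment
        assert res.adj_r2 == pytest.approx(1 - (1 - r2) * 39 / (40 - 3 - 1))

    def test_orthogonal_predictors_explain_nothing(self):
        y = np.array([1.0, -1, 1, -1, 1, -1])
        x = np.array([1.0, 1, -1, -1, 1, -1])[:, None]  # orthogonal to y
        x = x - x.mean()
        y = y - y.mean()
        x -= (x[:, 0] @ y) / (y @ y) * y[:, None]
        assert rda(y, x).r2 < 1e-10

    def test_collinear_columns_dropped(self, rng):
        x = rng.normal(size=(15, 2))
        xx = np.hstack([x, x[:, :1] * 2.0])
        res = rda(rng.normal(size=15), xx)
        assert res.dropped_columns == [2]
        assert res.rank == 2


class TestPartialRda:
    def test_empty_conditioning_reduces_to_rda(self, rng):
        y = rng.normal(size=(20, 2))
        x = rng.normal(size=(20, 2))
        a = partial_rda(y, x, None)
        b = rda(y, x)
        assert a.r2 == pytest.approx(b.r2)

    def test_variance_partitioning_identity(self, rng):
        """For orthogonalized blocks, semipartial fractions add up."""
        n = 50
        x = rng.normal(size=(n, 2))
        z = rng.normal(size=(n, 2))
        x -= x.mean(axis=0); z -= z.mean(axis=0)
        z -= x @ np.linalg.lstsq(x, z, rcond=None)[0]   # orthogonalize
        y = rng.normal(size=(n, 3))
        joint = rda(y, np.hstack([x, z])).r2
        sep = rda(y, z).r2 + partial_rda(y, x, z).r2
        assert abs(joint - sep) < 1e-8

    def test_x_equals_z_gives_zero(self, rng):
        x = rng.normal(size=(15, 2))
        res = partial_rda(rng.normal(size=(15, 2)), x, x)
        assert res.r2 == 0.0


class TestPermutationAnova:
    def test_perfect_relation_minimum_p(self, rng):
        x = rng.normal(size=(25, 1))
        F, p = permutation_anova(x, x, n_perm=199, seed=0)
        assert p == pytest.approx(1 / 200)

    def test_invariant_to_joint_row_permutation(self, rng):
        y = rng.normal(size=(20, 2))
        x = rng.normal(size=(20, 2))
        perm = rng.permutation(20)
        F1, p1 = permutation_anova(y, x, n_perm=199, seed=3)
        F2, p2 = permutation_anova(y[perm], x[perm], n_perm=199, seed=3)
        assert F1 == pytest.approx(F2)
        assert p1 == pytest.approx(p2)

    def test_p_converges_with_permutation_count(self):
        rng = np.random.default_rng(77)
        y = rng.normal(size=(30, 1))
        x = 0.35 * y + rng.normal(size=(30, 1))
        _, p1 = permutation_anova(y, x, n_perm=999, seed=1)
        _, p2 = permutation_anova(y, x, n_perm=9999, seed=2)
        assert abs(p1 - p2) < 0.01


class TestForwardSelect:
    def test_recovers_planted_predictor(self):
        hits = 0
        for seed in range(25):
            rng = np.random.default_rng(seed)
            n = 50
            signal = rng.normal(size=(n, 1))
            y = signal + rng.normal(size=(n, 1))     # R^2 ~ 0.5
            cands = {"signal": signal}
            for j in range(5):
                cands[f"noise{j}"] = rng.normal(size=(n, 1))
            sel, _ = forward_select(y, cands, alpha=0.05, n_perm=199, seed=seed)
            hits += int(sel == ["signal"])
        assert hits >= 23    # >= 90% of replicates

    def test_all_noise_rarely_selects(self):
        selections = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            y = rng.normal(size=(40, 1))
            cands = {f"n{j}": rng.normal(size=(40, 1)) for j in range(4)}
            sel, _ = forward_select(y, cands, alpha=0.05, n_perm=199, seed=seed)
            selections += len(sel)
        # per-step family-wise selection rate is bounded near alpha * n_cands
        assert selections <= 10

    def test_alpha_one_selects_until_rank_exhausted(self, rng):
        y = rng.normal(size=(20, 1))
        cands = {f"c{j}": rng.normal(size=(20, 1)) for j in range(3)}
        sel, _ = forward_select(y, cands, alpha=1.0, n_perm=99, seed=0)
        assert sorted(sel) == ["c0", "c1", "c2"]


class TestVif:
    def test_orthogonal_columns(self):
        n = 16
        x = np.zeros((n, 2))
        x[:8, 0] = 1; x[8:, 0] = -1
        x[::2, 1] = 1; x[1::2, 1] = -1
        assert np.allclose(vif(x), [1.0, 1.0])

    def test_exact_correlation_09(self):
        n = 100
        a = np.sin(np.linspace(0, 7, n)); a = (a - a.mean()) / np.linalg.norm(a - a.mean())
        b = np.cos(np.linspace(0, 5, n)); b = b - b.mean()
        b -= (b @ a) * a; b /= np.linalg.norm(b)
        x = np.column_stack([a, 0.9 * a + np.sqrt(1 - 0.81) * b])
        got = vif(x)
        assert np.allclose(got, 1 / (1 - 0.81), atol=1e-8)
        assert got[0] == pytest.approx(5.263, abs=1e-3)

    def test_duplicate_column_infinite(self, rng):
        a = rng.normal(size=20)
        assert np.isinf(vif(np.column_stack([a, a]))).all()


class TestImpute:
    def test_no_missing_identity(self, rng):
        g = make_genotypes(rng.integers(0, 3, size=(6, 5)).astype(np.int8))
        pm = two_pop_map(g, 3)
        assert np.array_equal(impute_by_population(g, pm).dosage, g.dosage)

    def test_modal_fill_with_tie_to_lower(self):
        d = np.array([[0], [0], [2], [MISSING]], dtype=np.int8)
        g = make_genotypes(d)
        pm = pd.Series(["A"] * 4, index=g.individual_ids)
        assert impute_by_population(g, pm).dosage[3, 0] == 0
        d2 = np.array([[0], [2], [MISSING]], dtype=np.int8)   # tie 0 vs 2
        g2 = make_genotypes(d2)
        pm2 = pd.Series(["A"] * 3, index=g2.individual_ids)
        assert impute_by_population(g2, pm2).dosage[2, 0] == 0

    def test_restores_majority_class(self, rng):
        d = np.repeat(rng.integers(0, 3, size=(1, 30)), 12, axis=0).astype(np.int8)
        g = make_genotypes(d.copy())
        mask = rng.random(d.shape) < 0.1
        g.dosage[mask] = MISSING
        pm = two_pop_map(g, 6)
        imp = impute_by_population(g, pm)
        assert np.array_equal(imp.dosage, d)


class TestDapc:
    def test_two_separated_groups(self):
        rng = np.random.default_rng(12)
        n, m = 40, 60
        pa, pb = rng.uniform(0.05, 0.95, m), rng.uniform(0.05, 0.95, m)
        d = np.vstack([rng.binomial(2, pa, size=(n // 2, m)),
                       rng.binomial(2, pb, size=(n // 2, m))]).astype(np.int8)
        g = make_genotypes(d)
        res = dapc(g, k_max=6, seed=0)
        assert res.k == 2
        labels = res.q.values.argmax(axis=1)
        first = labels[: n // 2]
        acc = max((first == 0).mean(), (first == 1).mean())
        assert acc > 0.95

    def test_q_rows_sum_to_one(self, small_dataset):
        from stockload.ordination import impute_by_population
        g = impute_by_population(small_dataset.genotypes, small_dataset.popmap)
        sub = g.take_individuals(np.arange(60))
        res = dapc(sub, k_max=4, seed=1)
        assert np.allclose(res.q.sum(axis=1), 1.0)

    def test_k1_degenerate(self):
        g = make_genotypes(np.zeros((8, 10), dtype=np.int8) + np.eye(8, 10, dtype=np.int8))
        res = dapc(g, k_max=1, seed=0)
        assert res.k == 1
        assert np.allclose(res.q.values, 1.0)
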
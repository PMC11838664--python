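import numpy as np
import pytest

from gtaccc.ldsc import (
    GeneticCovStruct,
    LDScoreTable,
    compute_ld_scores,
    fit_ldsc_bivariate,
    fit_ldsc_univariate,
    liability_convert,
    liability_factor,
    multivariate_ldsc,
    smooth_to_psd,
    standardize_S,
    standardize_S_matrices,
    unvech,
    vech,
    vech_indices,
)
from gtaccc.simulate import (
    GenoPanel,
    simulate_genotypes,
    simulate_sumstats_direct,
    synthetic_ld_scores,
)


class TestVech:
    def test_order_row_major_lower(self):
        assert vech_indices(3) == [(0, 0), (1, 0), (1, 1), (2, 0), (2, 1), (2, 2)]

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((4, 4))
        a = a + a.T
        np.testing.assert_allclose(unvech(vech(a), 4), a)


class TestLDScores:
    def test_window_zero_self_only(self, small_panel):
        ld = compute_ld_scores(small_panel, window=0, adjusted=False)
        np.testing.assert_allclose(ld.ld, 1.0)

    def test_duplicated_variant_pair(self):
        # two perfectly correlated variants: each unadjusted score = 2
        rng = np.random.default_rng(71)
        col = rng.integers(0, 3, size=500).astype(np.int8)
        dosage = np.column_stack([col, col])
        panel = GenoPanel(
            dosage=dosage, maf=np.array([0.5, 0.5]), block=np.zeros(2, dtype=int),
            r=np.array([0.0, 0.0]), snp=np.array(["rs1", "rs2"]),
            chrom=np.ones(2, dtype=int), pos=np.array([1, 2]),
        )
        ld = compute_ld_scores(panel, window=1, adjusted=False)
        np.testing.assert_allclose(ld.ld, 2.0, atol=1e-5)   # float32 correlations

    def test_adjusted_unbiased_for_independent_variants(self):
        panel = simulate_genotypes(400, 200, 200, r=0.0, maf_range=(0.2, 0.5), seed=72)
        adj = compute_ld_scores(panel, window=20, adjusted=True)
        unadj = compute_ld_scores(panel, window=20, adjusted=False)
        assert adj.ld.mean() == pytest.approx(1.0, abs=0.02)
        assert unadj.ld.mean() > adj.ld.mean()      # upward bias without correction

    def test_round_trip_io(self, small_panel, tmp_path):
        ld = compute_ld_scores(small_panel, window=5)
        path = ld.write(tmp_path / "ld.tsv")
        back = LDScoreTable.read(path)
        np.testing.assert_allclose(back.ld, ld.ld)
        assert back.M == ld.M


class TestUnivariate:
    def test_recovery(self):
        M = 2000
        ld_vals = synthetic_ld_scores(M, mean=3, spread=2, seed=81)
        (s,) = simulate_sumstats_direct(ld_vals, M, [{"h2": 0.3, "N": 50_000}], seed=82)
        ld = LDScoreTable(snp=s.df["SNP"].to_numpy(), ld=ld_vals, M=M)
        fit = fit_ldsc_univariate(s, ld, n_blocks=200)
        assert abs(fit.h2 - 0.3) < 2 * fit.h2_se
        assert abs(fit.intercept - 1.0) < 2 * fit.intercept_se

    def test_null_h2(self):
        M = 2000
        ld_vals = synthetic_ld_scores(M, mean=3, spread=2, seed=83)
        (s,) = simulate_sumstats_direct(ld_vals, M, [{"h2": 0.0, "N": 50_000}], seed=84)
        ld = LDScoreTable(snp=s.df["SNP"].to_numpy(), ld=ld_vals, M=M)
        fit = fit_ldsc_univariate(s, ld, n_blocks=200)
        assert abs(fit.h2) < 2 * fit.h2_se

    def test_confounding_in_intercept(self):
        M = 2000
        ld_vals = synthetic_ld_scores(M, mean=3, spread=2, seed=85)
        (s,) = simulate_sumstats_direct(
            ld_vals, M, [{"h2": 0.0, "N": 50_000, "intercept": 1.2}], seed=86
        )
        ld = LDScoreTable(snp=s.df["SNP"].to_numpy(), ld=ld_vals, M=M)
        fit = fit_ldsc_univariate(s, ld, n_blocks=200)
        assert abs(fit.intercept - 1.2) < 2 * fit.intercept_se
        assert abs(fit.h2) < 2 * fit.h2_se

    def test_constant_ld_unidentified(self, direct_pair):
        traits, ld = direct_pair
        flat = LDScoreTable(snp=ld.snp, ld=np.full_like(ld.ld, 2.0), M=ld.M)
        with pytest.raises(ValueError, match="constant"):
            fit_ldsc_univariate(traits[0], flat, n_blocks=100)

    def test_too_few_variants(self, direct_pair):
        traits, ld = direct_pair
        import gtaccc.sumstats as ss

        small = ss.SumStats(trait_id="x", df=traits[0].df.head(100))
        with pytest.raises(ValueError, match="200"):
            fit_ldsc_univariate(small, ld, n_blocks=10)


class TestBivariate:
    def test_self_consistency(self, direct_pair):
        traits, ld = direct_pair
        uni = fit_ldsc_univariate(traits[0], ld, n_blocks=200)
        biv = fit_ldsc_bivariate(traits[0], traits[0], ld, n_blocks=200, align=False)
        assert biv.gencov == pytest.approx(uni.h2, rel=1e-3)
        assert biv.intercept == pytest.approx(uni.intercept, rel=1e-2)

    def test_rg_recovery(self, direct_pair):
        traits, ld = direct_pair
        biv = fit_ldsc_bivariate(traits[0], traits[1], ld, n_blocks=200)
        u1 = fit_ldsc_univariate(traits[0], ld, n_blocks=200)
        u2 = fit_ldsc_univariate(traits[1], ld, n_blocks=200)
        rg = biv.gencov / np.sqrt(u1.h2 * u2.h2)
        assert abs(rg - 0.5) < 2.5 * biv.gencov_se / np.sqrt(u1.h2 * u2.h2)

    def test_overlap_in_intercept_not_slope(self):
        M = 2000
        ld_vals = synthetic_ld_scores(M, mean=3, spread=2, seed=87)
        traits = simulate_sumstats_direct(
            ld_vals, M,
            [{"h2": 0.2, "N": 30_000}, {"h2": 0.2, "N": 30_000}],
            overlap={"N_s": 30_000, "pheno_corr": 0.5},
            seed=88,
        )
        ld = LDScoreTable(snp=traits[0].df["SNP"].to_numpy(), ld=ld_vals, M=M)
        biv = fit_ldsc_bivariate(traits[0], traits[1], ld, n_blocks=200)
        assert abs(biv.gencov) < 2 * biv.gencov_se
        assert abs(biv.intercept - 0.5) < 2 * biv.intercept_se


class TestMultivariate:
    def test_k1_reduces_to_univariate(self, direct_pair):
        traits, ld = direct_pair
        uni = fit_ldsc_univariate(traits[0], ld, n_blocks=200)
        struct = multivariate_ldsc([traits[0]], ld, n_blocks=200)
        assert struct.S[0, 0] == pytest.approx(uni.h2, rel=1e-9)
        assert struct.intercepts[0, 0] == pytest.approx(uni.intercept, rel=1e-9)
        assert np.sqrt(struct.V_S[0, 0]) == pytest.approx(uni.h2_se, rel=1e-9)

    def test_duplicated_trait_degenerate_v(self, direct_pair):
        traits, ld = direct_pair
        dup = traits[0].copy()
        dup.trait_id = "dup"
        struct = multivariate_ldsc([traits[0], dup], ld, n_blocks=100)
        # vech order: (0,0), (1,0), (1,1); all three cells estimate the same
        # quantity so their estimation errors correlate perfectly
        corr = struct.V_S / np.sqrt(np.outer(np.diag(struct.V_S), np.diag(struct.V_S)))
        assert corr.min() > 0.999

    def test_rg_matrix_recovery(self, trio_struct):
        struct, rgm = trio_struct
        pairs = vech_indices(3)
        for c, (i, j) in enumerate(pairs):
            if i == j:
                continue
            se = np.sqrt(struct.V_R[c, c])
            assert abs(struct.R[i, j] - rgm[i, j]) < 2.5 * se

    def test_disjoint_sample_cross_covariance_near_zero(self, trio_struct):
        struct, _ = trio_struct
        # errors of element (1,0) and (2,2) share no trait; their V entry is
        # small relative to the diagonal scale
        pairs = vech_indices(3)
        i_10 = pairs.index((1, 0))
        i_22 = pairs.index((2, 2))
        scale = np.sqrt(struct.V_S[i_10, i_10] * struct.V_S[i_22, i_22])
        assert abs(struct.V_S[i_10, i_22]) < 0.5 * scale

    def test_write_read_round_trip(self, trio_struct, tmp_path):
        struct, _ = trio_struct
        outdir = struct.write(tmp_path / "struct")
        back = GeneticCovStruct.read(outdir)
        np.testing.assert_allclose(back.S, struct.S, atol=1e-12)
        np.testing.assert_allclose(back.V_S, struct.V_S, atol=1e-12)
        np.testing.assert_allclose(back.R, struct.R, atol=1e-12)
        assert back.trait_ids == struct.trait_ids


class TestLiability:
    def test_balanced_factor_is_half_pi(self):
        assert liability_factor(0.5, 0.5) == pytest.approx(np.pi / 2, abs=1e-9)

    def test_zero_h2_stays_zero(self):
        struct = GeneticCovStruct(
            trait_ids=["a"], S=np.array([[0.0]]), V_S=np.array([[1e-4]]),
            intercepts=np.array([[1.0]]),
        )
        out = liability_convert(struct, [0.3], [0.1])
        assert out.S[0, 0] == 0.0

    def test_mixed_continuous_binary_scaling(self):
        S = np.array([[0.5, 0.2], [0.2, 0.3]])
        V = np.eye(3) * 1e-4
        struct = GeneticCovStruct(
            trait_ids=["cont", "bin"], S=S, V_S=V, intercepts=np.eye(2)
        )
        out = liability_convert(struct, [None, 0.5], [None, 0.2])
        c = liability_factor(0.5, 0.2)
        assert out.S[0, 0] == pytest.approx(0.5)
        assert out.S[0, 1] == pytest.approx(0.2 * np.sqrt(c))
        assert out.S[1, 1] == pytest.approx(0.3 * c)
        # V scales with the product of the element scale factors
        assert out.V_S[1, 1] == pytest.approx(1e-4 * c)
        assert out.V_S[2, 2] == pytest.approx(1e-4 * c * c)

    def test_rg_invariant_under_conversion(self, trio_struct):
        struct, _ = trio_struct
        out = liability_convert(struct, [0.4, 0.3, None], [0.2, 0.1, None])
        R_out, _ = standardize_S_matrices(out.S, out.V_S)
        np.testing.assert_allclose(R_out, struct.R, atol=1e-10)

    def test_errors(self):
        with pytest.raises(ValueError):
            liability_factor(0.0, 0.5)


class TestStandardize:
    def test_correlation_input_identity(self):
        R = np.array([[1.0, 0.4], [0.4, 1.0]])
        out, _ = standardize_S_matrices(R, np.eye(3) * 1e-4)
        np.testing.assert_allclose(out, R)

    def test_arithmetic(self):
        S = np.array([[4.0, 3.0], [3.0, 9.0]])
        R, _ = standardize_S_matrices(S, np.eye(3) * 1e-4)
        assert R[0, 1] == pytest.approx(0.5)

    def test_non_positive_diagonal_errors(self):
        S = np.array([[0.0, 0.1], [0.1, 0.5]])
        with pytest.raises(ValueError, match="diagonal"):
            standardize_S_matrices(S, np.eye(3) * 1e-4)

    def test_delta_vs_jackknife_agreement(self, direct_pair):
        """Two independent routes to V_R agree within 15% on the informative
        elements (the off-diagonal; diagonal rows of R are identically 1)."""
        traits, ld = direct_pair
        delta = multivariate_ldsc(traits, ld, n_blocks=200, r_method="delta")
        direct = multivariate_ldsc(traits, ld, n_blocks=200, r_method="jackknife")
        off = vech_indices(2).index((1, 0))
        a = delta.V_R[off, off]
        b = direct.V_R[off, off]
        assert abs(a - b) / b < 0.15

    def test_standardize_helper(self, trio_struct):
        struct, _ = trio_struct
        out = standardize_S(struct)
        np.testing.assert_allclose(np.diag(out.R), 1.0, atol=1e-12)
        np.testing.assert_allclose(out.R, struct.R, atol=1e-12)


class TestSmoothToPSD:
    def test_psd_unchanged(self):
        V = np.array([[2.0, 0.5], [0.5, 1.0]])
        out, change = smooth_to_psd(V)
        np.testing.assert_allclose(out, V)
        assert change == 0.0

    def test_eigen_clipping(self):
        # symmetric 2x2 with eigenvalues (1, -0.01)
        vecs = np.array([[np.cos(0.3), -np.sin(0.3)], [np.sin(0.3), np.cos(0.3)]])
        V = (vecs * np.array([1.0, -0.01])) @ vecs.T
        out, change = smooth_to_psd(V)
        assert np.linalg.eigvalsh(out).min() >= 0
        assert change <= 0.0100001

    def test_zero_matrix(self):
        out, change = smooth_to_psd(np.zeros((3, 3)))
        np.testing.assert_allclose(out, 0.0)
        assert change == 0.0

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            smooth_to_psd(np.array([[1.0, 2.0], [0.0, 1.0]]))
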
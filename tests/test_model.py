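import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ordagree as oa
from ordagree.model import association_covariate, build_design
from ordagree.partitions import AdjacentPairPartition, parse_partition

LOG3 = np.log(3.0)


class TestAssociationCovariate:
    @pytest.mark.parametrize(
        "i, j, group, expected",
        [
            (1, 5, {1, 2, 3, 4}, 8.0),  # UA: (j-i)^2/2
            (3, 3, {1, 2, 3, 4}, 0.0),  # diagonal carries no penalty
            (1, 2, {1}, 0.5),
            (2, 4, {1}, 0.0),  # pair 1 not crossed between 2 and 4
            (1, 3, {1, 2}, 2.0),
        ],
    )
    def test_values(self, i, j, group, expected):
        assert association_covariate(i, j, group, I=5) == expected

    @given(st.integers(1, 6), st.integers(1, 6), st.sets(st.integers(1, 5)))
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_nonnegativity(self, i, j, group):
        x = association_covariate(i, j, group)
        assert x == association_covariate(j, i, group)
        assert x >= 0
        if i == j:
            assert x == 0

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            association_covariate(0, 3, {1}, I=5)


class TestDesign:
    @pytest.mark.parametrize(
        "spec, ncols",
        [("uniform", 10), ("full", 13), ("independence", 9), ("12|2345", 11)],
    )
    def test_shapes_and_rank(self, spec, ncols):
        X, names = build_design(5, spec)
        assert X.shape == (25, ncols)
        assert len(names) == ncols
        assert np.linalg.matrix_rank(X) == ncols

    def test_ua_odds_ratio_structure(self):
        # log tau_ij implied by the design equals beta (i-j)^2 under UA
        X, _ = build_design(5, "uniform")
        c = X[:, -1].reshape(5, 5)  # the beta column holds -x_g(i, j)
        for i in range(5):
            for j in range(5):
                log_tau = c[i, i] + c[j, j] - c[i, j] - c[j, i]  # coefficient of beta
                assert log_tau == pytest.approx((i - j) ** 2)


class TestFit:
    def test_2x2_independence_hand_arithmetic(self):
        fit = oa.fit_loglinear(np.array([[10, 0], [0, 10]]), "independence")
        assert fit.converged_
        assert fit.fitted_means_ == pytest.approx(np.full((2, 2), 5.0))
        assert fit.g_squared_ == pytest.approx(40 * np.log(2))

    def test_df_arithmetic(self, random_tables):
        # I^2 - (2I - 1) main parameters - one per association group
        t5 = random_tables(5, 1)[0]
        assert oa.fit_loglinear(t5, "uniform").df_resid_ == 25 - 9 - 1
        assert oa.fit_loglinear(t5, "full").df_resid_ == 25 - 9 - 4
        t3 = random_tables(3, 1)[0]
        assert oa.fit_loglinear(t3, "full").df_resid_ == 9 - 5 - 2

    def test_margin_reproduction(self, random_tables):
        for t in random_tables(5, 3):
            for spec in ["independence", "uniform", "full", "123|345"]:
                fit = oa.fit_loglinear(t, spec)
                assert fit.converged_
                m = fit.fitted_means_
                np.testing.assert_allclose(m.sum(1), t.sum(1), rtol=1e-6)
                np.testing.assert_allclose(m.sum(0), t.sum(0), rtol=1e-6)
                assert np.all(m > 0)
                assert m.sum() == pytest.approx(t.sum())

    def test_parameter_recovery_on_expected_counts(self):
        # Noiseless expected counts from a solved NUA surface recover the betas
        gen = (0.3, LOG3, 0.7, LOG3)
        design = oa.solve_design(100000, gen, "homogeneous")
        counts = np.round(design.expected_counts).astype(int)
        fit = oa.fit_loglinear(counts, "full")
        np.testing.assert_allclose(fit.beta_pairs_, gen, atol=1e-3)

    def test_merged_groups_reproduce_uniform_fit(self, random_tables):
        t = random_tables(5, 1)[0]
        ua = oa.fit_loglinear(t, "uniform")
        merged = oa.fit_loglinear(t, AdjacentPairPartition.from_groups(5, [{1, 2, 3, 4}]))
        assert merged.g_squared_ == ua.g_squared_
        np.testing.assert_array_equal(merged.fitted_means_, ua.fitted_means_)

    def test_empty_row_reports_nonconvergence(self):
        t = np.array([[5, 1, 0], [1, 6, 1], [0, 0, 0]])
        fit = oa.fit_loglinear(t, "uniform")
        assert not fit.converged_
        assert "empty" in fit.message_

    def test_nesting_monotonicity_of_g2(self, random_tables):
        # Refining the partition never increases the deviance
        chains = [["independence", "uniform", "123|345", "full"],
                  ["independence", "uniform", "12|2345", "full"]]
        for t in random_tables(5, 3):
            for chain in chains:
                g2 = [oa.fit_loglinear(t, s).g_squared_ for s in chain]
                assert all(a >= b - 1e-8 for a, b in zip(g2, g2[1:]))

    def test_statsmodels_poisson_oracle(self, random_tables):
        # Independent generic GLM fit of the same design matrix
        import statsmodels.api as sm

        for I in (4, 5):
            for t in random_tables(I, 2):
                for spec in ["uniform", "full"]:
                    X, _ = build_design(I, spec)
                    ref = sm.GLM(t.ravel(), X, family=sm.families.Poisson()).fit()
                    fit = oa.fit_loglinear(t, spec)
                    np.testing.assert_allclose(
                        fit.fitted_means_.ravel(), ref.fittedvalues, rtol=1e-6
                    )
                    assert fit.g_squared_ == pytest.approx(ref.deviance, rel=1e-6)

    def test_effects_recentred_to_sum_zero(self, random_tables):
        fit = oa.fit_loglinear(random_tables(5, 1)[0], "uniform")
        assert fit.row_effects_.sum() == pytest.approx(0, abs=1e-9)
        assert fit.col_effects_.sum() == pytest.approx(0, abs=1e-9)
        # re-centred parameters still reproduce the fitted means
        eta = (
            fit.mu_
            + fit.row_effects_[:, None]
            + fit.col_effects_[None, :]
            - np.array([[sum(b * association_covariate(i, j, g)
                            for b, g in zip(fit.betas_, fit.partition_.groups))
                         for j in range(1, 6)] for i in range(1, 6)])
        )
        np.testing.assert_allclose(np.exp(eta), fit.fitted_means_, rtol=1e-8)


class TestLRTest:
    @pytest.mark.parametrize(
        "alt, expected_df",
        [("full", 3), ("12|2345", 1), ("123|345", 1), ("1-2,4-5|2-3,3-4", 1)],
    )
    def test_delta_df(self, random_tables, alt, expected_df):
        t = random_tables(5, 1)[0]
        lrt = oa.lr_test(oa.fit_loglinear(t, "uniform"), oa.fit_loglinear(t, alt))
        assert lrt.delta_df == expected_df
        assert lrt.delta_g2 >= 0
        assert 0 <= lrt.p_value <= 1

    def test_same_partition_gives_p_one(self, random_tables):
        t = random_tables(5, 1)[0]
        lrt = oa.lr_test(oa.fit_loglinear(t, "uniform"), oa.fit_loglinear(t, "uniform"))
        assert lrt.delta_g2 == pytest.approx(0, abs=1e-10)
        assert lrt.p_value == 1.0

    def test_chi2_quantile_crosscheck(self):
        from scipy import stats

        assert stats.chi2.sf(3.841, 1) == pytest.approx(0.05, abs=5e-4)

    def test_non_nested_rejected(self, random_tables):
        t = random_tables(5, 1)[0]
        with pytest.raises(ValueError, match="nested"):
            oa.lr_test(oa.fit_loglinear(t, "123|345"), oa.fit_loglinear(t, "1-2,4-5|2-3,3-4"))

    def test_different_tables_rejected(self, random_tables):
        t1, t2 = random_tables(5, 2)
        with pytest.raises(ValueError, match="different tables"):
            oa.lr_test(oa.fit_loglinear(t1, "uniform"), oa.fit_loglinear(t2, "full"))
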
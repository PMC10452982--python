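import math

import numpy as np
import pytest

from stochident.identify import (EmptyMatrixError, build_concatenated,
                                 collinearity_index, delta_msqr,
                                 determinant_measure, normalize_columns,
                                 select_identifiable_subsets, svd_spectrum)
from stochident.network import ModelConfigError


def _wrap(sens, grid):
    return type("S", (), {"values": sens, "grid": grid})()


class TestBuildConcatenated:
    def test_cancellation_gives_ones(self):
        # S_ik = E[X_i]/c_k  =>  s = 1 everywhere
        grid = np.linspace(0, 1, 4)
        means = np.random.default_rng(0).uniform(1, 5, size=(4, 2))
        c = np.array([2.0, 3.0, 4.0])
        sens = means[:, :, None] / c[None, None, :]
        concat = build_concatenated(_wrap(sens, grid), means, c)
        np.testing.assert_allclose(concat.matrix, 1.0)
        assert concat.n_rows == 6  # t = 0 block dropped

    def test_zero_mean_rows_masked_not_nan(self):
        grid = np.linspace(0, 1, 3)
        means = np.array([[0.0, 0.0], [5.0, 0.0], [5.0, 1.0]])
        sens = np.ones((3, 2, 2))
        concat = build_concatenated(_wrap(sens, grid), means, np.array([1.0, 1.0]))
        assert concat.n_rows == 3          # (t1, X1), (t2, X1), (t2, X2)
        assert len(concat.mask_log) == 1   # (t1, X2) masked
        assert np.all(np.isfinite(concat.matrix))

    def test_all_masked_raises(self):
        grid = np.linspace(0, 1, 3)
        means = np.zeros((3, 1))
        sens = np.ones((3, 1, 1))
        with pytest.raises(EmptyMatrixError):
            build_concatenated(_wrap(sens, grid), means, np.array([1.0]))

    def test_pure_death_closed_form(self):
        # s(t) = c * (-x0 t e^{-ct}) / (x0 e^{-ct}) = -c t
        grid = np.linspace(0, 3, 7)
        c = np.array([2.0])
        means = 20.0 * np.exp(-2.0 * grid)[:, None]
        sens = (-20.0 * grid * np.exp(-2.0 * grid))[:, None, None]
        concat = build_concatenated(_wrap(sens, grid), means, c)
        np.testing.assert_allclose(concat.matrix[:, 0], -2.0 * grid[1:],
                                   rtol=1e-12)

    def test_observed_subset(self):
        grid = np.linspace(0, 1, 3)
        means = np.ones((3, 2))
        sens = np.ones((3, 2, 2))
        concat = build_concatenated(_wrap(sens, grid), means,
                                    np.array([1.0, 1.0]), observed=[1])
        assert all(i == 1 for _, i in concat.row_index)


class TestDelta:
    def test_unit_column(self):
        assert delta_msqr(np.ones((17, 1)))[0] == pytest.approx(1.0)

    def test_hand_value(self):
        assert delta_msqr(np.array([[3.0], [4.0]]))[0] == \
            pytest.approx(math.sqrt(12.5))

    def test_not_scale_invariant(self):
        m = np.random.default_rng(1).normal(size=(10, 2))
        d1 = delta_msqr(m)
        m2 = m.copy()
        m2[:, 0] *= 7.0
        d2 = delta_msqr(m2)
        assert d2[0] == pytest.approx(7 * d1[0])
        assert d2[1] == pytest.approx(d1[1])


class TestNormalize:
    def test_unit_columns(self):
        m = np.random.default_rng(2).normal(size=(20, 4))
        St = normalize_columns(m)
        np.testing.assert_allclose(np.linalg.norm(St.matrix, axis=0), 1.0,
                                   rtol=1e-12)
        assert not St.zero_columns

    def test_zero_column_flagged_and_ci_undefined(self):
        m = np.random.default_rng(3).normal(size=(20, 3))
        m[:, 1] = 0.0
        St = normalize_columns(m)
        assert St.zero_columns == {1}
        assert collinearity_index(St, (0, 1)) is None
        assert collinearity_index(St, (0, 2)) is not None


class TestCollinearityIndex:
    def test_orthonormal_columns(self):
        q, _ = np.linalg.qr(np.random.default_rng(4).normal(size=(30, 3)))
        assert collinearity_index(normalize_columns(q), (0, 1, 2)) == \
            pytest.approx(1.0)

    def test_two_column_closed_form(self):
        # unit columns with inner product rho: lambda_min = 1 - |rho|
        rho = 0.75
        u = np.zeros(10)
        v = np.zeros(10)
        u[0] = 1.0
        v[0] = rho
        v[1] = math.sqrt(1 - rho ** 2)
        ci = collinearity_index(normalize_columns(np.column_stack([u, v])),
                                (0, 1))
        assert ci == pytest.approx(2.0)

    def test_exactly_collinear_is_infinite(self):
        u = np.random.default_rng(5).normal(size=12)
        ci = collinearity_index(normalize_columns(np.column_stack([u, 2 * u])),
                                (0, 1))
        assert math.isinf(ci)

    def test_monotone_under_subset_growth(self):
        # CI can only grow when a parameter is added (eigenvalue interlacing)
        rng = np.random.default_rng(6)
        for _ in range(100):
            St = normalize_columns(rng.normal(size=(12, 5)))
            ci3 = collinearity_index(St, (0, 1, 2))
            ci4 = collinearity_index(St, (0, 1, 2, 3))
            ci5 = collinearity_index(St, (0, 1, 2, 3, 4))
            assert ci3 <= ci4 + 1e-9 <= ci5 + 2e-9

    def test_matches_brute_force_minimisation(self):
        # CI = 1 / min over unit z of ||S~_K z||, sampled over random z
        rng = np.random.default_rng(7)
        St = normalize_columns(rng.normal(size=(15, 2)))
        ci = collinearity_index(St, (0, 1))
        z = rng.normal(size=(2, 20_000))
        z /= np.linalg.norm(z, axis=0)
        brute = 1.0 / np.linalg.norm(St.matrix @ z, axis=0).min()
        assert brute <= ci * (1 + 1e-9)
        assert ci <= brute * 1.02

    def test_scale_invariance(self):
        rng = np.random.default_rng(8)
        m = rng.normal(size=(20, 3))
        ci1 = collinearity_index(normalize_columns(m), (0, 1, 2))
        m2 = m * np.array([3.0, 0.1, 42.0])
        ci2 = collinearity_index(normalize_columns(m2), (0, 1, 2))
        assert ci1 == pytest.approx(ci2, rel=1e-10)

    def test_input_validation(self):
        St = normalize_columns(np.eye(3))
        with pytest.raises(ModelConfigError):
            collinearity_index(St, (0,))
        with pytest.raises(ModelConfigError):
            collinearity_index(St, (0, 0))


class TestSVD:
    def test_orthonormal_rank(self):
        q, _ = np.linalg.qr(np.random.default_rng(9).normal(size=(12, 3)))
        sv, rank = svd_spectrum(q)
        assert rank == 3
        np.testing.assert_allclose(sv, 1.0, rtol=1e-12)

    def test_duplicate_column_keeps_rank(self):
        m = np.random.default_rng(10).normal(size=(12, 3))
        _, r1 = svd_spectrum(m)
        _, r2 = svd_spectrum(np.column_stack([m, m[:, 0]]))
        assert r1 == r2 == 3

    def test_descending(self):
        sv, _ = svd_spectrum(np.random.default_rng(11).normal(size=(20, 6)))
        assert np.all(np.diff(sv) <= 0)


class TestDeterminantMeasure:
    def test_orthonormal_is_one(self):
        q, _ = np.linalg.qr(np.random.default_rng(12).normal(size=(9, 3)))
        assert determinant_measure(q) == pytest.approx(1.0)

    def test_identical_columns_zero(self):
        u = np.random.default_rng(13).normal(size=9)
        assert determinant_measure(np.column_stack([u, u])) == 0.0

    def test_hand_value(self):
        u = np.zeros(6)
        v = np.zeros(6)
        u[0] = 1.0
        v[0] = 0.6
        v[1] = 0.8
        rho = determinant_measure(np.column_stack([u, v]))
        assert rho == pytest.approx(0.64 ** 0.25)


class TestSelection:
    def test_orthogonal_pair_identifiable(self):
        m = np.zeros((10, 2))
        m[0, 0] = 3.0
        m[1, 1] = 4.0
        report = select_identifiable_subsets(normalize_columns(m),
                                             delta_msqr(m))
        assert len(report.subsets) == 1
        s = report.subsets[0]
        assert s.indices == (0, 1) and s.identifiable
        assert s.ci == pytest.approx(1.0)

    def test_weak_parameter_blocks_identifiability_not_tabulation(self):
        rng = np.random.default_rng(14)
        m = rng.normal(size=(30, 3))
        m[:, 2] *= 1e-3                     # important scale but tiny delta
        delta = delta_msqr(m)
        assert delta[2] < 0.2 < min(delta[0], delta[1])
        report = select_identifiable_subsets(normalize_columns(m), delta)
        assert len(report.subsets) == 4     # 3 pairs + 1 triple, all tabulated
        for s in report.subsets:
            if 2 in s.indices:
                assert not s.identifiable
                assert s.ci is not None     # CI still reported

    def test_empty_ranking_warns(self):
        m = 1e-4 * np.random.default_rng(15).normal(size=(10, 3))
        report = select_identifiable_subsets(normalize_columns(m),
                                             delta_msqr(m))
        assert report.warnings and not report.subsets

    def test_budget_guard(self):
        rng = np.random.default_rng(16)
        m = rng.normal(size=(5, 40))
        with pytest.raises(ModelConfigError, match="budget"):
            select_identifiable_subsets(normalize_columns(m),
                                        np.ones(40))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(17)
        m = rng.normal(size=(25, 4))
        perm = [2, 0, 3, 1]
        r1 = select_identifiable_subsets(normalize_columns(m), delta_msqr(m))
        r2 = select_identifiable_subsets(normalize_columns(m[:, perm]),
                                         delta_msqr(m[:, perm]))
        np.testing.assert_allclose(np.sort(r1.delta), np.sort(r2.delta))
        ci1 = {tuple(sorted(perm[j] for j in s.indices)): s.ci
               for s in r2.subsets}
        for s in r1.subsets:
            assert s.ci == pytest.approx(ci1[s.indices], rel=1e-10)

    def test_flagged_column_subsets_marked_undefined(self):
        m = np.random.default_rng(18).normal(size=(10, 3))
        m[:, 0] = 0.0
        report = select_identifiable_subsets(normalize_columns(m),
                                             np.array([0.5, 0.5, 0.5]))
        for s in report.subsets:
            if 0 in s.indices:
                assert s.ci is None and not s.identifiable
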
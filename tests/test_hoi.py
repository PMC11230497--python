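import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import ndtri

from braingap.hoi import (
    DegenerateChannelError,
    OmegaMatrix,
    RegionTimeSeries,
    copula_transform,
    gaussian_entropy,
    normalize_omega,
    o_information,
    o_information_pair,
    omega_matrix,
)
from conftest import make_ts

HALF_LOG_2PIE = 0.5 * np.log(2 * np.pi * np.e)


def brute_force_omega(X):
    """Independent oracle: recompute every entropy term from first principles.

    Entropy of a subset S of copula rows = 0.5 ln((2 pi e)^|S| det cov(S)),
    determinants via numpy slogdet on the explicit submatrix; no shared
    bookkeeping with the implementation under test.
    """
    G = copula_transform(X)
    n = G.shape[0]

    def H(rows):
        sub = np.cov(G[rows]) if len(rows) > 1 else np.var(G[rows[0]], ddof=1)
        if len(rows) == 1:
            return HALF_LOG_2PIE + 0.5 * np.log(sub)
        _, logdet = np.linalg.slogdet(sub)
        return len(rows) * HALF_LOG_2PIE + 0.5 * logdet

    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        rest = [k for k in range(n) if k not in (i, j)]
        val = (
            H(list(range(n))) - H([i, j]) - H([i] + rest) - H([j] + rest)
            + H([i]) + H([j]) + H(rest)
        )
        out[i, j] = out[j, i] = val
    return out


class TestCopulaTransform:
    def test_three_point_row_hits_normal_quartiles(self):
        got = copula_transform(np.array([[10.0, 20.0, 30.0]]))
        expected = ndtri([0.25, 0.5, 0.75])
        np.testing.assert_allclose(got[0], expected, atol=1e-12)
        np.testing.assert_allclose(got[0], [-0.67448975, 0.0, 0.67448975], atol=1e-6)

    def test_invariant_under_monotone_map(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((4, 50))
        np.testing.assert_array_equal(
            copula_transform(np.exp(X)), copula_transform(X)
        )

    def test_constant_row_raises_with_region_name(self):
        X = np.array([[1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0]])
        with pytest.raises(DegenerateChannelError, match="bad_region"):
            copula_transform(X, region_labels=["ok", "bad_region"])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_property_monotone_invariance_whole_matrix(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((3, 40))
        Y = X.copy()
        Y[1] = Y[1] ** 3  # strictly increasing on R
        np.testing.assert_allclose(copula_transform(X), copula_transform(Y))


class TestGaussianEntropy:
    def test_univariate_standard_normal_closed_form(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(200000)
        x = (x - x.mean()) / x.std(ddof=1)
        est = gaussian_entropy(x[None, :])
        assert est.block_size == 1
        assert est.value == pytest.approx(HALF_LOG_2PIE, abs=1e-6)

    def test_two_independent_normals_additive(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((2, 5000))
        est = gaussian_entropy(X)
        assert est.value == pytest.approx(2 * HALF_LOG_2PIE, abs=0.05)

    def test_bivariate_rho_half(self):
        # population value: 2*0.5 ln(2 pi e) + 0.5 ln(det [[1,.5],[.5,1]])
        expected = 2 * HALF_LOG_2PIE + 0.5 * np.log(0.75)
        assert expected == pytest.approx(2.69404, abs=1e-4)
        rng = np.random.default_rng(3)
        z = rng.standard_normal((2, 40000))
        X = np.vstack([z[0], 0.5 * z[0] + np.sqrt(0.75) * z[1]])
        assert gaussian_entropy(X).value == pytest.approx(expected, abs=0.02)

    def test_singular_covariance_warns_not_crashes(self):
        x = np.linspace(0, 1, 50)
        X = np.vstack([x, x])  # duplicated channel
        with pytest.warns(UserWarning, match="singular"):
            est = gaussian_entropy(X)
        assert np.isfinite(est.value)


class TestOInformationPair:
    def test_independent_triple_near_zero(self):
        rng = np.random.default_rng(4)
        ts = make_ts(rng.standard_normal((3, 20000)))
        assert o_information_pair(ts, 0, 1) == pytest.approx(0.0, abs=0.02)

    def test_common_driver_redundancy(self):
        # x ~ N(0,1), y=(x+e1)/sqrt2, z=(x+e2)/sqrt2 ->
        # corr(x,y)=corr(x,z)=1/sqrt2, corr(y,z)=1/2; Omega = 0.5 ln(4/3)
        expected = 0.5 * np.log(4.0 / 3.0)
        assert expected == pytest.approx(0.1438, abs=1e-4)
        rng = np.random.default_rng(5)
        x = rng.standard_normal(20000)
        ts = make_ts(np.vstack([
            x,
            (x + rng.standard_normal(20000)) / np.sqrt(2),
            (x + rng.standard_normal(20000)) / np.sqrt(2),
        ]))
        assert o_information_pair(ts, 1, 2) == pytest.approx(expected, abs=0.03)

    def test_noisy_sum_synergy(self):
        # z=(x+y+e)/sqrt3 -> det Sigma = 1/3; Omega = 0.5 ln(3/4)
        expected = 0.5 * np.log(3.0 / 4.0)
        assert expected == pytest.approx(-0.1438, abs=1e-4)
        rng = np.random.default_rng(6)
        x = rng.standard_normal(20000)
        y = rng.standard_normal(20000)
        z = (x + y + rng.standard_normal(20000)) / np.sqrt(3)
        ts = make_ts(np.vstack([x, y, z]))
        assert o_information_pair(ts, 0, 1) == pytest.approx(expected, abs=0.03)

    def test_symmetry_and_index_checks(self):
        rng = np.random.default_rng(7)
        ts = make_ts(rng.standard_normal((4, 100)))
        assert o_information_pair(ts, 0, 2) == pytest.approx(
            o_information_pair(ts, 2, 0), abs=1e-12
        )
        with pytest.raises(ValueError):
            o_information_pair(ts, 1, 1)
        with pytest.raises(IndexError):
            o_information_pair(ts, 0, 9)


class TestOmegaMatrix:
    def test_independent_system_near_zero(self):
        rng = np.random.default_rng(8)
        m = omega_matrix(make_ts(rng.standard_normal((4, 20000))))
        off = m.omega[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 0.03)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        for n_reg in (4, 5, 6):
            L = rng.normal(0, 0.4, (n_reg, n_reg))
            np.fill_diagonal(L, 1.0)
            X = L @ rng.standard_normal((n_reg, 500))
            got = omega_matrix(make_ts(X)).omega
            np.testing.assert_allclose(got, brute_force_omega(X), atol=1e-8)

    def test_general_n_formula_matches_triple_expansion(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(500)
        X = np.vstack([x, x + rng.standard_normal(500),
                       x + rng.standard_normal(500)])
        ts = make_ts(X)
        assert o_information(X) == pytest.approx(
            o_information_pair(ts, 0, 1), abs=1e-10
        )

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((5, 300)) + 0.5 * rng.standard_normal((1, 300))
        m = omega_matrix(make_ts(X)).omega
        perm = np.array([2, 0, 4, 1, 3])
        m_perm = omega_matrix(make_ts(X[perm])).omega
        np.testing.assert_allclose(m_perm, m[np.ix_(perm, perm)], atol=1e-10)

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(12)
        m = omega_matrix(make_ts(rng.standard_normal((5, 200)))).omega
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        np.testing.assert_array_equal(np.diag(m), 0.0)

    def test_block_structure_from_synthetic_cohort(self, small_config, small_cohort):
        from braingap.synthetic import simulate_subject_timeseries, _block_assignment
        rec = next(r for r in small_cohort if r.diagnosis == "HC")
        ts = simulate_subject_timeseries(rec, small_config, seed=42)
        m = omega_matrix(ts).omega
        blocks = _block_assignment(small_config.n_regions, small_config.n_blocks)
        within = (blocks[:, None] == blocks[None, :]) & ~np.eye(len(blocks), dtype=bool)
        cross = ~(blocks[:, None] == blocks[None, :])
        assert m[within].mean() > m[cross].mean()


class TestNormalizeOmega:
    def test_all_zero_passes_through(self):
        m = OmegaMatrix(np.zeros((4, 4)), [f"r{i}" for i in range(4)])
        nm = normalize_omega(m)
        assert nm.normalized
        assert nm.normalization_constant == 0.0
        np.testing.assert_array_equal(nm.omega, 0.0)

    def test_max_abs_is_exactly_one_and_signs_kept(self):
        rng = np.random.default_rng(13)
        raw = omega_matrix(make_ts(rng.standard_normal((5, 300))))
        nm = normalize_omega(raw)
        off = nm.omega[~np.eye(5, dtype=bool)]
        assert np.max(np.abs(off)) == pytest.approx(1.0, abs=1e-15)
        np.testing.assert_array_equal(np.sign(nm.omega), np.sign(raw.omega))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_property_bound_holds(self, seed):
        rng = np.random.default_rng(seed)
        L = rng.normal(0, 0.3, (5, 5))
        np.fill_diagonal(L, 1.0)
        nm = normalize_omega(omega_matrix(make_ts(L @ rng.standard_normal((5, 200)))))
        assert np.max(np.abs(nm.omega)) <= 1.0 + 1e-12


def test_rest_block_is_joint_not_bag_of_marginals():
    # with a correlated rest block, treating it jointly vs marginally differs;
    # the implementation must use the joint (N-2)-dimensional entropy
    rng = np.random.default_rng(14)
    shared = rng.standard_normal(5000)
    X = np.vstack([
        rng.standard_normal(5000),
        rng.standard_normal(5000),
        shared + 0.3 * rng.standard_normal(5000),
        shared + 0.3 * rng.standard_normal(5000),
    ])
    got = o_information_pair(make_ts(X), 0, 1)
    assert got == pytest.approx(brute_force_omega(X)[0, 1], abs=1e-8)


def test_timeseries_validation():
    with pytest.raises(ValueError):
        RegionTimeSeries(np.ones((2, 10)), ["a", "b"])  # < 3 regions
    with pytest.raises(ValueError):
        RegionTimeSeries(np.full((3, 10), np.nan), ["a", "b", "c"])
    with pytest.warns(UserWarning):
        RegionTimeSeries(np.random.default_rng(0).normal(size=(5, 4)),
                         [f"r{i}" for i in range(5)])
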
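"""Polychoric estimation against closed forms, brute force and bootstrap."""

import numpy as np
import pytest
from scipy.stats import norm

from ordsem._bvn import bvn_cdf, bvn_pdf
from ordsem.polychoric import (
    EmptyCategoryError,
    PolychoricSummary,
    asymptotic_cov,
    bivariate_cell_probs,
    polychoric_matrix,
    polychoric_pair,
    univariate_thresholds,
)
from ordsem.polychoric import _pair_loglik


def _simulate_pair(rng, rho, cuts_i, cuts_j, n):
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    return np.column_stack(
        [np.searchsorted(cuts_i, z[:, 0]), np.searchsorted(cuts_j, z[:, 1])]
    )


def _table(data, ki, kj):
    return np.bincount(data[:, 0] * kj + data[:, 1], minlength=ki * kj).reshape(ki, kj)


class TestBVN:
    def test_quadrant_closed_form(self):
        for rho in (0.5, -0.5, 0.9):
            got = float(bvn_cdf(0.0, 0.0, rho))
            assert got == pytest.approx(0.25 + np.arcsin(rho) / (2 * np.pi), abs=1e-10)

    def test_independence_product(self, rng):
        h, k = rng.uniform(-2, 2, 10), rng.uniform(-2, 2, 10)
        assert np.allclose(bvn_cdf(h, k, 0.0), norm.cdf(h) * norm.cdf(k), atol=1e-14)

    def test_against_numerical_integration(self, rng):
        # Phi2(h,k;r) = int_-inf^h phi(x) Phi((k-rx)/sqrt(1-r^2)) dx
        from scipy.integrate import quad

        for rho in (0.3, -0.8, 0.96):
            for _ in range(3):
                h, k = rng.uniform(-2, 2), rng.uniform(-2, 2)
                om = np.sqrt(1 - rho**2)
                ref, _ = quad(
                    lambda x: norm.pdf(x) * norm.cdf((k - rho * x) / om), -10, h
                )
                assert float(bvn_cdf(h, k, rho)) == pytest.approx(ref, abs=1e-9)

    def test_pdf_matches_density(self):
        rho = 0.4
        val = float(bvn_pdf(0.3, -0.2, rho))
        om = 1 - rho**2
        z = (0.09 + 2 * rho * 0.3 * 0.2 + 0.04) / om
        assert val == pytest.approx(np.exp(-z / 2) / (2 * np.pi * np.sqrt(om)), abs=1e-14)


class TestThresholds:
    def test_normal_quantiles(self):
        thr = univariate_thresholds(np.array([200, 500, 300]))
        assert thr == pytest.approx([norm.ppf(0.2), norm.ppf(0.7)], abs=1e-10)
        assert thr == pytest.approx([-0.8416, 0.5244], abs=1e-4)

    def test_median_split(self):
        assert univariate_thresholds(np.array([500, 500])) == pytest.approx([0.0])

    def test_empty_category_error(self):
        with pytest.raises(EmptyCategoryError):
            univariate_thresholds(np.array([100, 0, 900]))


class TestCellProbs:
    def test_independence_outer_product(self):
        ti, tj = np.array([-0.5, 0.8]), np.array([0.2])
        probs = bivariate_cell_probs(0.0, ti, tj)
        pi = np.diff(np.concatenate(([0], norm.cdf(ti), [1])))
        pj = np.diff(np.concatenate(([0], norm.cdf(tj), [1])))
        assert np.allclose(probs, np.outer(pi, pj), atol=1e-12)

    def test_quadrant_probability(self):
        probs = bivariate_cell_probs(0.5, np.array([0.0]), np.array([0.0]))
        assert probs[1, 1] == pytest.approx(0.25 + np.arcsin(0.5) / (2 * np.pi), abs=1e-6)
        assert probs[1, 1] == pytest.approx(1 / 3, abs=1e-6)

    def test_sum_to_one_and_margins(self, rng):
        for _ in range(10):
            rho = rng.uniform(-0.95, 0.95)
            ti = np.sort(rng.uniform(-2, 2, 3))
            tj = np.sort(rng.uniform(-2, 2, 2))
            probs = bivariate_cell_probs(rho, ti, tj)
            assert probs.sum() == pytest.approx(1.0, abs=1e-10)
            assert np.allclose(
                probs.sum(axis=1),
                np.diff(np.concatenate(([0], norm.cdf(ti), [1]))),
                atol=1e-10,
            )

    def test_boundary_rho_raises(self):
        with pytest.raises(ValueError):
            bivariate_cell_probs(1.0, np.array([0.0]), np.array([0.0]))


class TestPolychoricPair:
    def test_independence_table(self):
        ti, tj = np.array([-0.5, 0.5]), np.array([0.0])
        pi = np.diff(np.concatenate(([0], norm.cdf(ti), [1])))
        pj = np.diff(np.concatenate(([0], norm.cdf(tj), [1])))
        table = np.outer(pi, pj) * 10000
        assert polychoric_pair(table, ti, tj) == pytest.approx(0.0, abs=1e-3)

    def test_quadrant_inversion(self):
        table = np.array([[333.0, 167.0], [167.0, 333.0]])
        thr = np.array([0.0])
        rho = polychoric_pair(table, thr, thr)
        assert rho == pytest.approx(0.5, abs=0.01)
        # brute-force grid search over the same likelihood
        grid = np.linspace(-0.99, 0.99, 1981)
        lls = [_pair_loglik(r, table, thr, thr) for r in grid]
        assert rho == pytest.approx(grid[int(np.argmax(lls))], abs=1e-2)

    def test_matches_brute_force_grid(self, rng):
        """ML maximizer equals an independent grid/refine oracle to 1e-4."""
        for _ in range(20):
            rho = rng.uniform(-0.85, 0.85)
            cuts_i = np.sort(rng.uniform(-1.5, 1.5, rng.integers(1, 3)))
            cuts_j = np.sort(rng.uniform(-1.5, 1.5, rng.integers(1, 3)))
            data = _simulate_pair(rng, rho, cuts_i, cuts_j, 400)
            ki, kj = len(cuts_i) + 1, len(cuts_j) + 1
            table = _table(data, ki, kj)
            if np.any(table.sum(0) == 0) or np.any(table.sum(1) == 0):
                continue
            ti = univariate_thresholds(table.sum(axis=1))
            tj = univariate_thresholds(table.sum(axis=0))
            ml = polychoric_pair(table, ti, tj)
            grid = np.linspace(-0.995, 0.995, 1991)
            coarse = grid[
                int(np.argmax([_pair_loglik(r, table, ti, tj) for r in grid]))
            ]
            fine = np.linspace(coarse - 2e-3, coarse + 2e-3, 801)
            best = fine[
                int(np.argmax([_pair_loglik(r, table, ti, tj) for r in fine]))
            ]
            assert ml == pytest.approx(best, abs=1e-4)

    def test_category_reversal_negates_rho(self, rng):
        data = _simulate_pair(rng, 0.55, np.array([-0.4, 0.6]), np.array([0.1]), 2000)
        table = _table(data, 3, 2)
        ti = univariate_thresholds(table.sum(axis=1))
        tj = univariate_thresholds(table.sum(axis=0))
        rho = polychoric_pair(table, ti, tj)
        table_rev = table[::-1, :]  # reverse one item's categories
        ti_rev = -ti[::-1]
        rho_rev = polychoric_pair(table_rev, ti_rev, tj)
        assert rho_rev == pytest.approx(-rho, abs=1e-6)

    def test_consistency_large_n(self, rng):
        data = _simulate_pair(rng, 0.7, np.array([-0.5, 0.5]), np.array([-0.2, 0.9]), 50_000)
        table = _table(data, 3, 3)
        ti = univariate_thresholds(table.sum(axis=1))
        tj = univariate_thresholds(table.sum(axis=0))
        assert polychoric_pair(table, ti, tj) == pytest.approx(0.7, abs=0.01)

    def test_shrinking_error(self, rng):
        errs = []
        for n in (1000, 10_000, 100_000):
            est = []
            for _ in range(3):
                data = _simulate_pair(rng, 0.5, np.array([-0.5, 0.5]), np.array([0.0]), n)
                table = _table(data, 3, 2)
                ti = univariate_thresholds(table.sum(axis=1))
                tj = univariate_thresholds(table.sum(axis=0))
                est.append(polychoric_pair(table, ti, tj))
            errs.append(np.sqrt(np.mean((np.array(est) - 0.5) ** 2)))
        assert errs[2] < errs[0]

    def test_zero_margin_raises(self):
        with pytest.raises(EmptyCategoryError):
            polychoric_pair(np.array([[10, 0], [20, 0]]), np.array([0.0]), np.array([0.0]))


class TestPolychoricMatrix:
    def test_one_factor_implied_correlations(self, rng):
        # y*_j = a_j eta + eps; implied rho_ij = a_i a_j / sqrt((a_i^2+1)(a_j^2+1))
        a = np.array([0.9, 1.3, 0.7])
        cuts = [np.array([-0.6, 0.7]), np.array([-0.2]), np.array([-1.0, 0.1, 1.2])]
        n = 30_000
        eta = rng.standard_normal(n)
        data = np.column_stack(
            [
                np.searchsorted(c, aj * eta + rng.standard_normal(n))
                for aj, c in zip(a, cuts)
            ]
        )
        sm = polychoric_matrix(data, np.array([3, 2, 4]))
        for i in range(3):
            for j in range(i + 1, 3):
                implied = a[i] * a[j] / np.sqrt((a[i] ** 2 + 1) * (a[j] ** 2 + 1))
                assert sm.corr[i, j] == pytest.approx(implied, abs=0.02)

    def test_matches_pairwise_reference(self, rng):
        data = _simulate_pair(rng, 0.4, np.array([-0.5, 0.5]), np.array([0.0, 1.0]), 3000)
        sm = polychoric_matrix(data, np.array([3, 3]))
        table = _table(data, 3, 3)
        ref = polychoric_pair(table, sm.thresholds[0], sm.thresholds[1])
        assert sm.corr[0, 1] == pytest.approx(ref, abs=1e-6)

    def test_duplicate_column_clipped(self, rng):
        col = (rng.standard_normal(2000) > 0).astype(int)
        data = np.column_stack([col, col])
        sm = polychoric_matrix(data, np.array([2, 2]))
        assert sm.corr[0, 1] == pytest.approx(0.999, abs=1e-9)

    def test_serialization_round_trip(self, rng, tmp_path):
        data = _simulate_pair(rng, 0.3, np.array([0.0]), np.array([0.5]), 1000)
        sm = polychoric_matrix(data, np.array([2, 2]))
        asymptotic_cov(data, sm)
        path = str(tmp_path / "summary.json")
        sm.to_json(path)
        back = PolychoricSummary.from_json(path)
        assert np.allclose(back.stat_vector, sm.stat_vector)
        assert np.allclose(back.gamma, sm.gamma)


class TestAsymptoticCov:
    def test_threshold_delta_method(self, rng):
        n = 4000
        data = np.column_stack(
            [
                (rng.standard_normal(n) > 0.3).astype(int),
                (rng.standard_normal(n) > 0.0).astype(int),
            ]
        )
        sm = polychoric_matrix(data, np.array([2, 2]))
        g = asymptotic_cov(data, sm)
        p = (data[:, 0] == 0).mean()
        tau = sm.thresholds[0][0]
        assert g[0, 0] == pytest.approx(p * (1 - p) / norm.pdf(tau) ** 2, rel=1e-10)

    def test_bootstrap_agreement(self, rng):
        """Diagonal within 15% of a 1000-resample bootstrap at n=2000.

        (1000 resamples keep the oracle's own relative noise near 4.5%, so
        the 15% band tests the estimator, not the bootstrap.)
        """
        n = 2000
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=n)
        cuts = np.array([-0.5, 0.8])
        data = np.column_stack(
            [np.searchsorted(cuts, z[:, 0]), np.searchsorted(cuts, z[:, 1])]
        )
        sm = polychoric_matrix(data, np.array([3, 3]))
        g = asymptotic_cov(data, sm)
        boot = []
        for _ in range(1000):
            idx = rng.integers(0, n, n)
            boot.append(polychoric_matrix(data[idx], np.array([3, 3])).stat_vector)
        bv = np.array(boot).var(axis=0, ddof=1) * n
        assert np.all(np.abs(np.diag(g) - bv) / bv < 0.15)

    def test_symmetric_psd(self, rng):
        data = _simulate_pair(rng, 0.4, np.array([-0.3, 0.8]), np.array([0.0]), 1500)
        sm = polychoric_matrix(data, np.array([3, 2]))
        g = asymptotic_cov(data, sm)
        assert np.allclose(g, g.T)
        assert np.min(np.linalg.eigvalsh(g)) > -1e-10

    def test_independent_items_near_zero_cross(self, rng):
        n = 20_000
        data = np.column_stack(
            [
                np.searchsorted(np.array([-0.5, 0.5]), rng.standard_normal(n)),
                np.searchsorted(np.array([0.0]), rng.standard_normal(n)),
            ]
        )
        sm = polychoric_matrix(data, np.array([3, 2]))
        g = asymptotic_cov(data, sm)
        # rho is the last entry; thresholds of both items come first
        assert abs(g[-1, 0]) < 0.1
        assert abs(g[-1, 2]) < 0.1
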
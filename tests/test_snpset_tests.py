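import numpy as np
import pytest
from scipy.stats import chi2

from genesat.snpset_tests import (
    DEFAULT_RHO_GRID,
    NumericalError,
    QuadFormNull,
    _AdaptiveNull,
    adaptive_test,
    gene_scan,
    quadform_sf,
    squared_sum_test,
    sum_test,
)
from genesat.synthetic_data import make_ld

from test_ld_panel import make_gene_set


def random_corr(rng, m):
    base = rng.standard_normal((m + 5, m))
    r = np.corrcoef(base.T)
    return r


class TestQuadformSf:
    @pytest.mark.parametrize(
        "q,weights,expected",
        [
            (3.8415, [1.0], chi2.sf(3.8415, 1)),
            (2.0, [1.0, 1.0], np.exp(-1.0)),
            (4.0, [2.0, 2.0], np.exp(-1.0)),  # scaling: 2*chi2(2) at 4 == chi2(2) at 2
        ],
    )
    def test_closed_forms(self, q, weights, expected):
        assert quadform_sf(q, weights) == pytest.approx(expected, abs=1e-10)

    def test_scale_invariance_general_weights(self):
        lam = [1.7, 0.9, 0.4]
        for c in (0.25, 3.0):
            assert quadform_sf(5.0, lam) == pytest.approx(
                quadform_sf(5.0 * c, [w * c for w in lam]), abs=1e-8
            )

    def test_monte_carlo_oracle_small_m(self, rng):
        """CF inversion agrees with brute-force simulation of the
        weighted chi-square for random instances with m <= 5."""
        n = 500_000
        for m in (2, 3, 5):
            lam = rng.uniform(0.1, 2.0, size=m)
            draws = rng.chisquare(1, size=(n, m)) @ lam
            for frac in (0.5, 1.5, 3.0):
                q = frac * lam.sum()
                p_hat = (draws > q).mean()
                se = np.sqrt(p_hat * (1 - p_hat) / n)
                assert quadform_sf(q, lam) == pytest.approx(p_hat, abs=3 * se)

    def test_deep_tail_falls_back_to_moment_matching(self):
        p, method = quadform_sf(500.0, [1.5, 1.0, 0.5], return_method=True)
        assert method == "moment_match"
        assert 0 < p < 1e-12

    def test_nonpositive_q_gives_one(self):
        assert quadform_sf(0.0, [1.0, 2.0]) == 1.0
        assert quadform_sf(-3.0, [1.0, 2.0]) == 1.0

    def test_negative_weight_beyond_tolerance_raises(self):
        with pytest.raises(ValueError):
            quadform_sf(1.0, [1.0, -0.5])

    def test_small_negative_weights_clipped(self):
        p = quadform_sf(2.0, [1.0, 1.0, -1e-12])
        assert p == pytest.approx(np.exp(-1.0), abs=1e-9)

    def test_quadform_null_records_method(self):
        null = QuadFormNull(weights=np.array([1.5, 0.5]))
        null.sf(2.0)
        assert null.method == "cf_inversion"
        null.sf(300.0)
        assert null.method == "moment_match"


class TestSumTest:
    def test_perfect_cancellation(self):
        B, p = sum_test([1.0, -1.0], np.eye(2))
        assert B == 0.0 and p == 1.0

    def test_known_values(self):
        B, p = sum_test([1.0, 1.0], np.eye(2))
        assert B == 2.0
        assert p == pytest.approx(0.15730, abs=5e-6)
        _, p1 = sum_test([1.5], [[1.0]])
        assert p1 == pytest.approx(0.13361, abs=5e-6)

    def test_ld_enters_the_variance(self):
        r = np.array([[1.0, 0.5], [0.5, 1.0]])
        B, p = sum_test([1.0, 1.0], r)
        assert p == pytest.approx(chi2.sf(4.0 / 3.0, 1), abs=1e-12)

    def test_degenerate_variance_raises(self):
        r = np.array([[1.0, -1.0], [-1.0, 1.0]])
        with pytest.raises(NumericalError):
            sum_test([1.0, 1.0], r)


class TestSquaredSumTest:
    def test_known_values(self):
        Q, p = squared_sum_test([1.0, 1.0], np.eye(2))
        assert Q == 2.0 and p == pytest.approx(np.exp(-1.0), abs=1e-10)
        Q, p = squared_sum_test([2.0], [[1.0]])
        assert Q == 4.0 and p == pytest.approx(0.04550, abs=5e-6)

    def test_zero_vector(self):
        Q, p = squared_sum_test([0.0, 0.0, 0.0], np.eye(3))
        assert Q == 0.0 and p == 1.0

    def test_null_weight_sum_equals_m(self, rng):
        """Trace identity: S2T null weights sum to m for a correlation R."""
        for m in (3, 6, 12):
            r = random_corr(rng, m)
            lam = np.linalg.eigvalsh(r)
            assert lam.sum() == pytest.approx(m, abs=1e-8)


class TestAdaptiveTest:
    def test_m1_all_statistics_coincide(self):
        res = adaptive_test([2.0], [[1.0]])
        expected = chi2.sf(4.0, 1)
        for p in (res.p_st, res.p_s2t, res.T, res.p_at):
            assert p == pytest.approx(expected, abs=1e-12)

    def test_grid_endpoints_are_s2t_and_st(self, ar1_10, rng):
        z = rng.standard_normal(10)
        res = adaptive_test(z, ar1_10)
        assert res.rho_grid[0] == 0.0 and res.rho_grid[-1] == 1.0
        assert res.p_rho[0] == pytest.approx(res.p_s2t, abs=1e-7)
        assert res.p_rho[-1] == pytest.approx(res.p_st, abs=1e-9)

    def test_two_point_grid_antagonistic_z(self):
        """z = (1,-1) on identity LD: S2T p = e^-1, ST p = 1, so T = e^-1;
        the min-p adjustment is checked against the Monte-Carlo oracle."""
        z = np.array([1.0, -1.0])
        r = np.eye(2)
        res = adaptive_test(z, r, rho_grid=(0.0, 1.0))
        assert res.T == pytest.approx(np.exp(-1.0), abs=1e-7)
        mc = adaptive_test(z, r, rho_grid=(0.0, 1.0), method="monte_carlo",
                           mc_draws=200_000, seed=11)
        se = np.sqrt(mc.p_at * (1 - mc.p_at) / 200_000)
        assert res.p_at == pytest.approx(mc.p_at, abs=3 * se)

    def test_weight_conservation_along_grid(self, ar1_10):
        """sum of AT null weights at rho equals trace(A_rho R)
        = (1-rho) m + rho 1'R1."""
        null = _AdaptiveNull(ar1_10, DEFAULT_RHO_GRID)
        m = 10
        s2 = ar1_10.sum()
        for rho, lam in zip(null.rho, null.lam_rho):
            assert lam.sum() == pytest.approx((1 - rho) * m + rho * s2, abs=1e-8)

    def test_minp_sandwich(self, rng):
        """T <= p_AT <= min(1, |grid| * T) on random instances."""
        for m in (2, 4, 8):
            r = random_corr(rng, m)
            for _ in range(5):
                z = rng.standard_normal(m) @ np.linalg.cholesky(r + 1e-10 * np.eye(m)).T
                res = adaptive_test(z, r)
                assert res.T <= res.p_at <= min(1.0, len(res.rho_grid) * res.T) + 1e-12

    def test_snp_permutation_invariance(self, ar1_10, rng):
        z = rng.standard_normal(10)
        res = adaptive_test(z, ar1_10)
        perm = rng.permutation(10)
        res_p = adaptive_test(z[perm], ar1_10[np.ix_(perm, perm)])
        for attr in ("p_st", "p_s2t", "T", "p_at"):
            assert getattr(res_p, attr) == pytest.approx(getattr(res, attr), abs=1e-10)

    def test_integration_matches_monte_carlo(self, ar1_10, rng):
        z = rng.standard_normal(10) + 0.45
        res_int = adaptive_test(z, ar1_10, method="integration")
        res_mc = adaptive_test(z, ar1_10, method="monte_carlo", mc_draws=200_000, seed=5)
        se = np.sqrt(max(res_mc.p_at * (1 - res_mc.p_at), 1e-12) / 200_000)
        assert res_int.p_at == pytest.approx(res_mc.p_at, abs=3 * se)
        assert res_mc.at_method == "monte_carlo"
        assert res_mc.mc_draws == 200_000

    def test_power_monotone_in_shift(self):
        """Empirical AT power is non-decreasing in the mean shift delta
        (AR(1) r = 0.5, m = 10, common shifts 0 / 0.3 / 0.6)."""
        r = make_ld("ar1", 10, r=0.5).r
        null = _AdaptiveNull(r, DEFAULT_RHO_GRID)
        L = np.linalg.cholesky(r)
        rng = np.random.default_rng(77)
        power = []
        noise = rng.standard_normal((300, 10)) @ L.T  # shared noise across deltas
        for delta in (0.0, 0.3, 0.6):
            zs = noise + delta
            rejections = sum(
                adaptive_test(z, r, null=null).p_at < 0.05 for z in zs
            )
            power.append(rejections / len(zs))
        assert power[0] <= power[1] <= power[2]
        assert power[2] > power[0]  # the largest shift is actually detectable


class TestGeneScan:
    def make_sets(self, rng, n=5, m=4):
        sets = []
        for i in range(n):
            r = make_ld("ar1", m, r=0.4).r
            z = rng.standard_normal(m)
            gs = make_gene_set(z, r)
            gs.gene_id = f"G{i}"
            sets.append(gs)
        return sets

    def test_bonferroni_threshold_family_size_override(self, rng):
        scan = gene_scan(self.make_sets(rng), alpha_fw=0.05, n_tests=20_000)
        assert scan.threshold == pytest.approx(2.5e-6, rel=1e-12)

    def test_default_family_size_is_genes_tested(self, rng):
        sets = self.make_sets(rng, n=5)
        scan = gene_scan(sets, alpha_fw=0.05)
        assert scan.threshold == pytest.approx(0.01)
        assert scan.n_tested == 5

    def test_single_gene_nominal_threshold(self, rng):
        sets = self.make_sets(rng, n=1)
        scan = gene_scan(sets, alpha_fw=0.05)
        assert scan.threshold == 0.05
        assert scan.results.loc[0, "significant"] == (scan.results.loc[0, "p_at"] < 0.05)

    def test_manhattan_table_columns(self, rng):
        scan = gene_scan(self.make_sets(rng))
        assert list(scan.manhattan.columns) == [
            "gene_id", "chrom", "midpoint", "p_at", "neg_log10_p",
        ]
        np.testing.assert_allclose(
            scan.manhattan["neg_log10_p"], -np.log10(scan.results["p_at"])
        )

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            gene_scan([])
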
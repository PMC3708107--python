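import math

import numpy as np
import pytest
from scipy import stats

import oracles
from rnasnip import (BackgroundTable, DistributionFitError, ParameterError,
                     RnaSnpConfig, TableError, TableSet, fit_beta, fit_gumbel,
                     ks_check, pvalue, random_sequence, sample_null)
from rnasnip import background as bg

BUILTIN = RnaSnpConfig(backend="builtin")


class TestRandomSequence:
    def test_gc_fraction_matches_target(self, rng):
        gc_target = 0.6
        n, length = 1000, 400
        count = sum(random_sequence(length, gc_target, rng).residues.count(b)
                    for _ in range(n) for b in "GC")
        total = n * length
        se = math.sqrt(gc_target * (1 - gc_target) / total)
        assert abs(count / total - gc_target) < 3 * se

    def test_same_seed_gives_identical_sequence(self):
        a = random_sequence(100, 0.5, np.random.default_rng(7))
        b = random_sequence(100, 0.5, np.random.default_rng(7))
        assert a.residues == b.residues

    def test_gc_grid_covers_20_to_80_percent(self):
        assert bg.GC_GRID == (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)

    def test_invalid_gc_target(self, rng):
        with pytest.raises(ParameterError):
            random_sequence(50, 0.0, rng)


class TestSampleNull:
    def test_distances_are_nonnegative_and_deterministic(self):
        kw = dict(length=80, gc=0.5, position=40, n_samples=25,
                  config=BUILTIN, min_samples=25)
        a = sample_null("d_max", "global", rng=np.random.default_rng(3), **kw)
        b = sample_null("d_max", "global", rng=np.random.default_rng(3), **kw)
        assert np.all(a.scores >= 0)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_survival_at_median_is_half(self, rng):
        s = sample_null("d_max", "global", 80, 0.5, 40, 30, rng,
                        BUILTIN, min_samples=30)
        med = np.median(s.scores)
        frac = np.mean(s.scores >= med)
        assert 0.4 <= frac <= 0.6

    def test_unsupported_combination_rejected(self, rng):
        with pytest.raises(ParameterError):
            sample_null("r_min", "scanning", 80, 0.5, 40, 30, rng,
                        BUILTIN, min_samples=30)

    def test_min_samples_enforced(self, rng):
        with pytest.raises(ParameterError, match="min_samples"):
            sample_null("d_max", "global", 80, 0.5, 40, 10, rng, BUILTIN)


class TestFits:
    def test_gumbel_parameter_recovery(self, rng):
        mu, sigma = 2.0, 0.5
        x = stats.gumbel_r.rvs(mu, sigma, size=5000, random_state=rng)
        d = np.exp(1.0 - x)  # invert the 1 - log(d) transform
        mu_hat, sig_hat = fit_gumbel(d)
        assert abs(mu_hat - mu) / mu < 0.05
        assert abs(sig_hat - sigma) / sigma < 0.05
        assert sig_hat > 0

    def test_gumbel_location_bracketing(self):
        d = np.exp(1.0 - np.array([1.0, 3.0] * 50))  # x in {1, 3}
        mu_hat, _ = fit_gumbel(d)
        assert 1.0 < mu_hat < 3.0

    def test_gumbel_degenerate_sample(self):
        with pytest.raises(DistributionFitError):
            fit_gumbel(np.full(100, 0.7))

    def test_gumbel_drops_zero_distances(self, rng):
        x = stats.gumbel_r.rvs(1.0, 0.3, size=2000, random_state=rng)
        d = np.concatenate([np.exp(1.0 - x), np.zeros(50)])
        mu_hat, _ = fit_gumbel(d)
        assert np.isfinite(mu_hat)

    def test_beta_parameter_recovery(self, rng):
        y = stats.beta.rvs(5.0, 2.0, size=5000, random_state=rng)
        r = 2.0 * y - 1.0
        a, b = fit_beta(r)
        assert abs(a - 5.0) / 5.0 < 0.05 and abs(b - 2.0) / 2.0 < 0.05
        assert a > 0 and b > 0

    def test_beta_transform_endpoints(self):
        p = bg.fitted_pvalues(np.array([-1.0, 1.0]), "beta", (2.0, 2.0))
        assert p[0] == pytest.approx(0.0, abs=1e-6)
        assert p[1] == pytest.approx(1.0, abs=1e-6)

    def test_beta_rejects_out_of_range(self):
        with pytest.raises(ParameterError):
            fit_beta(np.array([0.0, 1.5] * 20))


class TestPvalue:
    def _table(self, mu=1.5, sigma=0.4):
        return BackgroundTable(
            measure="d_max", backend="global", engine="builtin",
            family="gumbel",
            cells={(120, 0.5, 0.5): {"params": (mu, sigma), "n": 500, "ks": None}})

    def test_p_at_location_is_exp_minus_one(self):
        mu = 1.5
        t = self._table(mu=mu)
        d_at_mu = math.exp(1.0 - mu)
        assert t.pvalue(d_at_mu, 120, 0.5, 60) == pytest.approx(math.exp(-1.0))

    def test_zero_distance_is_maximally_nonsignificant(self):
        assert self._table().pvalue(0.0, 120, 0.5, 60) == 1.0

    def test_monotone_decreasing_in_distance(self):
        t = self._table()
        d = np.linspace(0.05, 5.0, 50)
        p = [t.pvalue(x, 120, 0.5, 60) for x in d]
        assert np.all(np.diff(p) < 0)

    def test_monotone_increasing_in_correlation(self):
        t = BackgroundTable(
            measure="r_min", backend="global", engine="builtin", family="beta",
            cells={(120, 0.5, 0.5): {"params": (5.0, 2.0), "n": 500, "ks": None}})
        r = np.linspace(-0.99, 0.99, 50)
        p = [t.pvalue(x, 120, 0.5, 60) for x in r]
        assert np.all(np.diff(p) > 0)

    def test_lookup_clamps_to_nearest_cell(self):
        t = self._table()
        assert t.pvalue(1.0, 5000, 0.95, 4999) == t.pvalue(1.0, 120, 0.5, 60)

    def test_missing_table_errors_instruct_generation(self, tmp_path):
        with pytest.raises(TableError, match="table build"):
            pvalue(1.0, None, 120, 0.5, 60)
        with pytest.raises(TableError, match="not found"):
            BackgroundTable.load(tmp_path / "nope.json")
        with pytest.raises(TableError, match="missing background table"):
            TableSet().get_required("d_max", "global")


class TestKsCheck:
    def test_sample_from_fitted_distribution_passes(self, rng):
        x = stats.gumbel_r.rvs(1.2, 0.4, size=800, random_state=rng)
        res = ks_check(np.exp(1.0 - x), "gumbel", (1.2, 0.4))
        assert res.ok and res.statistic < 0.05

    def test_shifted_distribution_warns(self, rng):
        x = stats.gumbel_r.rvs(3.0, 0.4, size=800, random_state=rng)
        res = ks_check(np.exp(1.0 - x), "gumbel", (1.2, 0.4))
        assert not res.ok

    def test_statistic_equals_direct_ecdf_computation(self, rng):
        x = stats.gumbel_r.rvs(1.0, 0.5, size=300, random_state=rng)
        d = np.exp(1.0 - x)
        res = ks_check(d, "gumbel", (1.1, 0.45))
        want = oracles.ks_statistic_direct(
            1.0 - np.log(d), lambda v: stats.gumbel_r.cdf(v, 1.1, 0.45))
        assert res.statistic == pytest.approx(want, abs=1e-12)


class TestTablePersistence:
    def test_build_roundtrip(self, tmp_path, rng):
        t = BackgroundTable.build(
            "d_max", "global", lengths=[60], gc_bins=[0.5], pos_bins=[0.5],
            n_samples=40, rng=rng, config=BUILTIN, min_samples=40, seed=11)
        assert t.family == "gumbel" and len(t.cells) == 1
        (params,) = [c["params"] for c in t.cells.values()]
        assert params[1] > 0
        t.save(tmp_path / "t.json")
        back = BackgroundTable.load(tmp_path / "t.json")
        assert back.cells == t.cells
        assert back.pvalue(0.8, 60, 0.5, 30) == t.pvalue(0.8, 60, 0.5, 30)


@pytest.fixture(scope="module")
def calibration():
    length, pos, n = 120, 60, 250
    table_sample = sample_null(
        "d_max", "global", length, 0.5, pos, n,
        np.random.default_rng(41), BUILTIN, min_samples=n)
    held_out = sample_null(
        "d_max", "global", length, 0.5, pos, 500,
        np.random.default_rng(42), BUILTIN, min_samples=500)
    params = fit_gumbel(table_sample)
    table = BackgroundTable(
        measure="d_max", backend="global", engine="builtin", family="gumbel",
        cells={(length, 0.5, 0.5): {"params": params, "n": n, "ks": None}})
    return np.array([table.pvalue(s, length, 0.5, pos)
                     for s in held_out.scores])


class TestNullCalibration:
    """P-values of fresh null data against an independently built table."""

    def test_held_out_pvalues_are_approximately_uniform(self, calibration):
        res = stats.kstest(calibration, "uniform")
        assert res.pvalue > 0.01

    def test_fraction_below_10_percent_is_binomially_consistent(self, calibration):
        n = len(calibration)
        hits = int((calibration < 0.1).sum())
        ci = stats.binomtest(hits, n, 0.1).proportion_ci(confidence_level=0.99)
        assert ci.low <= 0.1 <= ci.high

    def test_shuffled_fitted_pvalues_lose_rank_correlation(self, rng):
        d = np.exp(1.0 - stats.gumbel_r.rvs(1.0, 0.4, size=400, random_state=rng))
        fitted = bg.fitted_pvalues(d, "gumbel", (1.0, 0.4))
        ranked = bg.rank_pvalues(d, "distance")
        assert np.corrcoef(fitted, ranked)[0, 1] > 0.99
        rng.shuffle(fitted)
        assert abs(np.corrcoef(fitted, ranked)[0, 1]) < 0.2
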
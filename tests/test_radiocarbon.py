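import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats

from stemchron.io import C14Measurement, CalCurve
from stemchron.radiocarbon import (
    InfeasibleSequenceError,
    NoOverlapError,
    _sequence_marginals,
    calibrate_sequence,
    format_table_style,
    hpd_intervals,
    make_grid,
    single_likelihood,
    stem_ages,
    summarize,
)


def brute_force_marginals(L: np.ndarray) -> np.ndarray:
    """Independent oracle: enumerate the ordered joint on the grid (n <= 3)."""
    n, g = L.shape
    idx = np.arange(g)
    if n == 1:
        joint = L[0].copy()
        return (joint / joint.sum())[None, :]
    if n == 2:
        joint = L[0][:, None] * L[1][None, :] * (idx[:, None] <= idx[None, :])
        joint /= joint.sum()
        return np.vstack([joint.sum(axis=1), joint.sum(axis=0)])
    if n == 3:
        mask = (idx[:, None, None] <= idx[None, :, None]) & (
            idx[None, :, None] <= idx[None, None, :]
        )
        joint = L[0][:, None, None] * L[1][None, :, None] * L[2][None, None, :] * mask
        joint /= joint.sum()
        return np.vstack(
            [joint.sum(axis=(1, 2)), joint.sum(axis=(0, 2)), joint.sum(axis=(0, 1))]
        )
    raise ValueError("oracle supports n <= 3")


def meas(pmc, sigma=1.0, stem="s", dist=1.0):
    return C14Measurement(stem, dist, pmc, sigma)


class TestSingleLikelihood:
    def test_matches_closed_form_on_linear_curve(self, linear_curve):
        """Unit pMC/yr slope: posterior for 110 +- 1 is Normal(1960, 1 yr)."""
        grid = make_grid(linear_curve, step=0.1)
        p = single_likelihood(meas(110.0), linear_curve, grid)
        mean, sd, _ = summarize(p, grid)
        assert mean == pytest.approx(1960.0, abs=0.05)
        assert sd == pytest.approx(1.0, abs=0.05)

    def test_delta_limit_concentrates(self, linear_curve):
        grid = make_grid(linear_curve, step=0.5)
        p = single_likelihood(meas(110.0, sigma=1e-3), linear_curve, grid)
        assert grid[np.argmax(p)] == pytest.approx(1960.0, abs=0.5)
        assert p.max() > 0.99

    def test_bomb_pulse_gives_bimodal_posterior(self, bomb_curve):
        """A mid-pulse activity matches both limbs: rising and falling modes."""
        grid = make_grid(bomb_curve, step=0.2)
        p = single_likelihood(meas(130.0, sigma=0.4), bomb_curve, grid)
        # oracle: direct evaluation of the likelihood on the grid
        mu, sc = bomb_curve.interp(grid)
        direct = np.exp(-0.5 * (130.0 - mu) ** 2 / (0.4**2 + sc**2))
        assert np.allclose(p, direct / direct.sum(), atol=1e-12)
        # substantial mass on each limb; the steep rising limb carries less
        assert p[grid < 1965.0].sum() > 0.1
        assert p[grid > 1965.0].sum() > 0.1
        # widening the HPD past the larger mode's mass exposes both intervals
        assert len(hpd_intervals(p, grid, 0.95)) == 2

    def test_no_overlap_raises(self, linear_curve):
        grid = make_grid(linear_curve, step=0.5)
        with pytest.raises(NoOverlapError):
            single_likelihood(meas(500.0, sigma=0.1), linear_curve, grid)


class TestSequenceMarginals:
    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_dp_matches_enumeration_random(self, n, rng):
        for _ in range(20):
            L = rng.uniform(0.01, 1.0, size=(n, rng.integers(10, 61)))
            assert np.abs(_sequence_marginals(L) - brute_force_marginals(L)).max() < 1e-9

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        L=hnp.arrays(
            float,
            shape=st.tuples(st.integers(1, 3), st.integers(5, 40)),
            elements=st.floats(1e-3, 1.0),
        )
    )
    def test_dp_matches_enumeration_property(self, L):
        assert np.abs(_sequence_marginals(L) - brute_force_marginals(L)).max() < 1e-9

    def test_dp_matches_enumeration_structured(self, rng):
        """Peaked, partially overlapping likelihoods (the realistic case)."""
        g = np.linspace(0, 1, 60)
        for _ in range(10):
            centers = np.sort(rng.uniform(0.2, 0.8, 3))
            L = np.exp(-0.5 * ((g[None, :] - centers[:, None]) / 0.08) ** 2)
            dp = _sequence_marginals(L)
            bf = brute_force_marginals(L)
            assert np.abs(dp - bf).max() < 1e-9

    def test_inactive_constraint_leaves_posteriors_unchanged(self, linear_curve):
        """Disjoint ordered likelihoods: marginals equal single calibrations."""
        ms = [meas(105.0, 0.5, dist=1.0), meas(140.0, 0.5, dist=10.0)]
        dates = calibrate_sequence(ms, linear_curve, collection_year=2009.0, grid_step=0.2)
        grid = dates[0].grid
        for m, d in zip(ms, dates):
            single = single_likelihood(m, linear_curve, grid)
            assert np.abs(single - d.posterior).sum() < 1e-6  # total variation

    def test_identical_measurements_split_symmetrically(self, linear_curve):
        """Two equal unimodal likelihoods: ordering pushes one early, one late,
        symmetrically about the unconstrained mean."""
        ms = [meas(110.0, 2.0, dist=1.0), meas(110.0, 2.0, dist=5.0)]
        dates = calibrate_sequence(ms, linear_curve, collection_year=2009.0, grid_step=0.2)
        e1, e2 = dates[0].mean_year, dates[1].mean_year
        assert e1 < 1960.0 < e2
        assert e1 + e2 == pytest.approx(2 * 1960.0, abs=0.2)

    def test_sequence_disambiguates_bomb_limbs(self, bomb_curve):
        """~140 pMC between two pre-peak slices is forced onto the rising limb."""
        ms = [
            meas(120.0, 0.4, dist=1.0),
            meas(140.0, 0.4, dist=5.0),
            meas(151.5, 0.4, dist=9.0),
        ]
        dates = calibrate_sequence(ms, bomb_curve, collection_year=2008.79, grid_step=0.2)
        mid = dates[1]
        falling_mass = mid.posterior[mid.grid > 1965.0].sum()
        assert falling_mass < 0.05
        assert mid.mean_year < 1965.0

    def test_expected_years_non_decreasing(self, bomb_curve, rng):
        for _ in range(5):
            true_years = np.sort(rng.uniform(1940, 2005, 5))
            mu, _ = bomb_curve.interp(true_years)
            ms = [
                C14Measurement("s", float(i + 1) * 5, float(m + rng.normal(0, 0.4)), 0.4)
                for i, m in enumerate(mu)
            ]
            dates = calibrate_sequence(ms, bomb_curve)
            means = [d.mean_year for d in dates]
            assert np.all(np.diff(means) >= -1e-9)

    def test_single_measurement_reduces_to_truncated_single(self, bomb_curve):
        ms = [meas(110.0, 0.4)]
        dates = calibrate_sequence(ms, bomb_curve, collection_year=2008.79)
        grid = dates[0].grid
        assert grid[-1] <= 2008.79
        single = single_likelihood(ms[0], bomb_curve, grid)
        assert np.abs(single - dates[0].posterior).sum() < 1e-12

    def test_infeasible_sequence_raises(self, linear_curve):
        # inner slice younger than collection bound allows, outer slice older: impossible
        ms = [meas(108.0, 0.05, dist=1.0), meas(102.0, 0.05, dist=2.0)]
        with pytest.raises(InfeasibleSequenceError):
            calibrate_sequence(ms, linear_curve, collection_year=2009.0, grid_step=0.5)


class TestMcmcEngine:
    def test_gibbs_agrees_with_dp(self, bomb_curve):
        true_years = [1950.0, 1962.0, 1972.0, 1990.0]
        mu, _ = bomb_curve.interp(np.array(true_years))
        ms = [C14Measurement("s", 5.0 * (i + 1), float(m), 0.4) for i, m in enumerate(mu)]
        dp = calibrate_sequence(ms, bomb_curve, engine="dp")
        mc = calibrate_sequence(ms, bomb_curve, engine="mcmc", seed=11, n_iter=6000)
        for d, m in zip(dp, mc):
            # batch-means Monte Carlo SE from the mcmc marginal itself
            se = m.sigma_year / np.sqrt(6000 / 20)  # conservative autocorrelation factor
            assert abs(d.mean_year - m.mean_year) < max(3 * se, 0.15)


class TestSummaries:
    def test_point_mass(self):
        grid = np.arange(1950.0, 1970.0)
        p = np.zeros(len(grid))
        p[10] = 1.0
        mean, sd, hpd = summarize(p, grid)
        assert mean == pytest.approx(1960.0) and sd == 0.0
        assert hpd == ((1960.0, 1960.0),)
        date = type("D", (), dict(mean_year=mean, sigma_year=sd))
        assert format_table_style(date) == (1960, 1)

    def test_symmetric_triangle(self):
        grid = np.array([1958.0, 1959, 1960, 1961, 1962])
        p = np.array([1, 2, 3, 2, 1], dtype=float)
        p /= p.sum()
        mean, _, _ = summarize(p, grid)
        assert mean == pytest.approx(1960.0)

    def test_discretized_normal_hpd(self):
        grid = np.arange(1940.0, 1980.0, 0.1)
        p = stats.norm.pdf(grid, 1960.0, 2.0)
        p /= p.sum()
        mean, sd, hpd = summarize(p, grid)
        assert mean == pytest.approx(1960.0, abs=0.01)
        assert sd == pytest.approx(2.0, abs=0.02)
        assert len(hpd) == 1
        lo, hi = hpd[0]
        assert lo == pytest.approx(1958.0, abs=0.2)
        assert hi == pytest.approx(1962.0, abs=0.2)

    def test_hpd_mass_is_at_least_nominal(self, rng):
        grid = np.arange(0.0, 100.0, 0.5)
        p = rng.uniform(size=len(grid)) ** 3
        p /= p.sum()
        intervals = hpd_intervals(p, grid)
        mass = sum(
            p[(grid >= lo) & (grid <= hi)].sum() for lo, hi in intervals
        )
        assert mass >= 0.682


class TestStemAges:
    def test_reference_stems(self):
        from types import SimpleNamespace

        from stemchron.reference import slice_table

        df = slice_table()
        by = {}
        for r in df.itertuples():
            by.setdefault(r.stem_id, []).append(
                SimpleNamespace(
                    distance_mm=r.distance_mm,
                    mean_year=float(r.year),
                    sigma_year=float(r.sigma_year),
                )
            )
        ages, (lo, hi) = stem_ages(by, 2008)
        assert ages["1"] == (48.0, 1.0)
        assert ages["3"] == (89.0, 23.0)
        assert (lo, hi) == (47.0, 112.0)

    def test_zero_age(self):
        from types import SimpleNamespace

        d = SimpleNamespace(distance_mm=1.0, mean_year=2008.0, sigma_year=1.0)
        ages, _ = stem_ages({"s": [d]}, 2008)
        assert ages["s"][0] == 0.0
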
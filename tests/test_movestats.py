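"""Movement statistics: classification, steps, fits, tests, diagnostics."""
import numpy as np
import pytest
from scipy import integrate, stats

from linefpt.movestats import (
    MovementParams,
    circular_correlation,
    classify_locations,
    extract_steps,
    fit_axial_vonmises,
    fit_step_length,
    fit_toward_vonmises,
    msd_curve,
    patlak_factor,
    scale_msd_daily,
)
from linefpt.synthetic import Domain, GPSTrack, Landscape


def _track(xy, tau=5.0):
    xy = np.asarray(xy, dtype=float)
    return GPSTrack(np.arange(len(xy)) * tau / 60.0, xy, tau)


class TestClassify:
    @pytest.mark.parametrize(
        "dist_km,label",
        [(0.010, "on"), (0.026, "on"), (0.027, "on"), (0.040, "near"),
         (0.050, "near"), (0.0501, "off"), (0.100, "off")],
    )
    def test_thresholds(self, one_line_landscape, dist_km, label):
        tr = _track([[5.0, 2.0 + dist_km], [5.1, 2.0 + dist_km]])
        assert classify_locations(tr, one_line_landscape)[0] == label

    def test_empty_landscape_all_off(self, empty_landscape):
        tr = _track([[1, 1], [2, 2], [3, 3]])
        assert list(classify_locations(tr, empty_landscape)) == ["off"] * 3

    def test_matches_bruteforce_distance_oracle(self):
        rng = np.random.default_rng(0)
        dom = Domain.square(5.0)
        segs = rng.uniform(0.5, 4.5, size=(8, 4))
        ls = Landscape(segs, dom)
        pts = rng.uniform(0, 5, size=(300, 2))

        def seg_dist(p, s):
            a, b = s[:2], s[2:]
            ab = b - a
            t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0, 1)
            return np.linalg.norm(p - (a + t * ab))

        brute = np.array([min(seg_dist(p, s) for s in segs) for p in pts])
        expected = np.where(brute <= 0.027, "on", np.where(brute <= 0.050, "near", "off"))
        assert list(ls.classify(pts)) == list(expected)


class TestExtractSteps:
    def test_toward_line_geometry_gives_zero_xi(self, one_line_landscape):
        # step due North from below the line: heading equals bearing-to-line
        tr = _track([[5.0, 1.5], [5.0, 1.6]])
        steps = extract_steps(tr, one_line_landscape)
        assert steps["rel_direction_deg"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert steps["direction_deg"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_short_step_kept_for_length_not_direction(self, one_line_landscape):
        tr = _track([[5.0, 1.5], [5.0, 1.55], [5.0, 1.65]])
        steps = extract_steps(tr, one_line_landscape)
        assert len(steps) == 2
        assert not steps["usable_direction"].iloc[0]  # 50 m
        assert steps["usable_direction"].iloc[1]  # 100 m

    def test_xi_matches_trigonometric_oracle(self, one_line_landscape):
        rng = np.random.default_rng(3)
        xy = np.column_stack([rng.uniform(1, 9, 40), rng.uniform(0.3, 1.9, 40)])
        tr = _track(xy)
        steps = extract_steps(tr, one_line_landscape)
        for i in range(len(steps)):
            p, q = xy[i], xy[i + 1]
            heading = np.arctan2(q[1] - p[1], q[0] - p[0])
            bearing = np.arctan2(2.0 - p[1], 0.0)  # nearest point is straight up
            xi = np.degrees((heading - bearing + np.pi) % (2 * np.pi) - np.pi)
            got = steps["rel_direction_deg"].iloc[i]
            assert abs((got - xi + 180) % 360 - 180) < 1e-9

    def test_single_fix_rejected(self, one_line_landscape):
        with pytest.raises(ValueError):
            extract_steps(_track([[1.0, 1.0]]), one_line_landscape)


class TestStepLength:
    def test_mean_is_exact(self):
        fit = fit_step_length([0.1, 0.2, 0.3], seed=0)
        assert fit.alpha == pytest.approx(0.2, abs=1e-15)

    def test_exponential_recovery(self):
        rng = np.random.default_rng(12)
        x = rng.exponential(0.147, 2000)
        fit = fit_step_length(x, seed=1)
        assert abs(fit.alpha - 0.147) < 3 * 0.147 / np.sqrt(2000)
        assert fit.ci[0] <= fit.alpha <= fit.ci[1]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fit_step_length([0.1], seed=0)


class TestVonMises:
    def test_uniform_sample_gives_null(self):
        rng = np.random.default_rng(7)
        xi = np.degrees(rng.uniform(-np.pi, np.pi, 500))
        for fitter in (fit_axial_vonmises, fit_toward_vonmises):
            f = fitter(xi, seed=1)
            assert f.kappa < 0.15
            assert f.p_value > 0.05

    def test_axial_kappa2_recovery(self):
        rng = np.random.default_rng(8)
        u = rng.vonmises(0.0, 2.0, 500)
        xi = 90.0 + np.degrees(u) / 2.0
        xi = np.where(rng.random(500) < 0.5, xi - 180.0, xi)
        f = fit_axial_vonmises(xi, seed=2)
        assert 1.6 <= f.kappa <= 2.4
        assert f.p_value <= 0.001

    def test_toward_kappa1_recovery_and_bessel_identity(self):
        rng = np.random.default_rng(9)
        xi = np.degrees(rng.vonmises(0.0, 1.0, 500))
        f = fit_toward_vonmises(xi, seed=3)
        assert 0.8 <= f.kappa <= 1.2
        assert f.p_value < 0.01
        # mean resultant length equals I1(k)/I0(k) at the MLE (quadrature oracle)
        num = integrate.quad(lambda t: np.cos(t) * np.exp(f.kappa * np.cos(t)), -np.pi, np.pi)[0]
        den = integrate.quad(lambda t: np.exp(f.kappa * np.cos(t)), -np.pi, np.pi)[0]
        assert abs(f.rbar - num / den) < 1e-6

    def test_pblr_null_calibration(self):
        # type-I error near nominal and p-values uniform under the null
        rng = np.random.default_rng(42)
        ps = []
        for _ in range(200):
            xi = np.degrees(rng.uniform(-np.pi, np.pi, 100))
            ps.append(
                fit_toward_vonmises(
                    xi, n_pblr=199, n_boot=50, seed=int(rng.integers(2**31))
                ).p_value
            )
        ps = np.asarray(ps)
        assert 0.02 <= np.mean(ps <= 0.05) <= 0.09
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_too_few_directions(self):
        with pytest.raises(ValueError):
            fit_toward_vonmises(np.zeros(5), seed=0)


class TestMSD:
    def test_ballistic_track_exact(self):
        v = 1.2  # km/h straight-line motion
        t = np.arange(25) * 5 / 60.0
        tr = GPSTrack(t, np.column_stack([v * t, np.zeros_like(t)]), 5.0)
        curve = msd_curve(tr, [5, 15, 30, 60])
        for _, row in curve.iterrows():
            assert row["msd_km2"] == pytest.approx((v * row["lag_min"] / 60) ** 2, rel=1e-12)

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(5)
        xy = rng.normal(size=(60, 2))
        tr = _track(xy)
        curve = msd_curve(tr, [5, 10, 25])
        for _, row in curve.iterrows():
            k = int(row["lag_min"] / 5)
            brute = np.mean(
                [np.sum((xy[i + k] - xy[i]) ** 2) for i in range(len(xy) - k)]
            )
            assert row["msd_km2"] == pytest.approx(brute, rel=1e-12)

    def test_overlong_lag_skipped_with_warning(self):
        tr = _track(np.zeros((4, 2)) + np.arange(4)[:, None])
        with pytest.warns(UserWarning):
            curve = msd_curve(tr, [5, 500])
        assert len(curve) == 1

    @pytest.mark.parametrize("msd,expected", [(0.017, 4.90), (0.043, 12.4), (0.0, 0.0)])
    def test_daily_scaling(self, msd, expected):
        assert scale_msd_daily(msd) == expected


class TestCircularCorrelation:
    def test_independent_uniform_near_zero(self):
        rng = np.random.default_rng(6)
        d = np.degrees(rng.uniform(-np.pi, np.pi, 10_001))
        assert abs(circular_correlation(d)) < 0.05

    def test_wrapped_autoregression_positive_and_converged(self):
        # persistent headings: d_{t+1} = d_t + von Mises noise
        def make(n, seed):
            rng = np.random.default_rng(seed)
            steps = rng.vonmises(0.0, 2.0, n)
            return np.degrees((np.cumsum(steps) + np.pi) % (2 * np.pi) - np.pi)

        big = circular_correlation(make(100_000, 1))  # Monte-Carlo reference
        small = circular_correlation(make(100_000, 2))
        assert big > 0.3
        assert abs(small - big) < 0.02

    def test_rotation_invariance(self):
        rng = np.random.default_rng(10)
        d = np.degrees(rng.vonmises(0.3, 1.0, 500))
        base = circular_correlation(d)
        rotated = circular_correlation((d + 77.7 + 180) % 360 - 180)
        assert rotated == pytest.approx(base, abs=1e-10)

    def test_degenerate_signalled(self):
        with pytest.raises(ValueError):
            circular_correlation(np.full(50, 45.0))


class TestPatlak:
    @pytest.mark.parametrize("psi,pct", [(0.18, 22), (0.43, 75), (0.0, 0)])
    def test_percent_increase(self, psi, pct):
        assert round(100 * (patlak_factor(psi) - 1)) == pct

    def test_psi_at_one_rejected(self):
        with pytest.raises(ValueError):
            patlak_factor(1.0)
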
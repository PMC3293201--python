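"""Generators: landscape density contracts, CSR prey, walk statistics."""
import numpy as np
import pytest
from scipy import stats
from scipy.spatial import cKDTree

from linefpt.movestats import MovementParams, extract_steps, msd_curve
from linefpt.synthetic import (
    Domain,
    GPSTrack,
    Landscape,
    generate_landscape,
    place_prey,
    simulate_track,
)


class TestGenerateLandscape:
    def test_zero_density_is_empty(self, square10):
        ls = generate_landscape(0.0, square10, seed=1)
        assert ls.is_empty and ls.density_S == 0.0

    def test_negative_density_rejected(self, square10):
        with pytest.raises(ValueError):
            generate_landscape(-1.0, square10, seed=1)

    @pytest.mark.parametrize("target", [0.5, 2.23, 4.46, 10.0])
    def test_density_within_one_percent(self, square10, target):
        ls = generate_landscape(target, square10, seed=3)
        assert abs(ls.density_S - target) <= 0.01 * target
        # recomputing total length / area from the segments matches density_S
        d = ls.segments[:, 2:4] - ls.segments[:, 0:2]
        brute = np.hypot(d[:, 0], d[:, 1]).sum() / square10.area
        assert brute == pytest.approx(ls.density_S, abs=1e-9)

    def test_baseline_total_length(self):
        # 4.46 km/km² on 25 x 25 km: total length within 1% of 2787.5 km
        ls = generate_landscape(4.46, Domain.square(25.0), seed=7)
        assert 2777.0 <= ls.total_length <= 2797.8

    def test_seed_reproducibility(self, square10):
        a = generate_landscape(3.0, square10, seed=42)
        b = generate_landscape(3.0, square10, seed=42)
        c = generate_landscape(3.0, square10, seed=43)
        np.testing.assert_array_equal(a.segments, b.segments)
        assert a.segments.shape != c.segments.shape or not np.array_equal(
            a.segments, c.segments
        )

    def test_unreachable_target_raises_with_achieved_density(self, square10):
        with pytest.raises(RuntimeError, match="achieved"):
            generate_landscape(8.0, square10, seed=1, max_lines=2)

    def test_segments_inside_domain(self, square10):
        ls = generate_landscape(5.0, square10, seed=11)
        pts = ls.segments.reshape(-1, 2)
        assert np.all(square10.contains(pts, atol=1e-6))


class TestPlacePrey:
    def test_counts(self):
        dom = Domain.square(25.0)
        assert len(place_prey(0.0, dom, seed=1)) == 0
        assert len(place_prey(0.16, dom, seed=1)) == 100
        assert len(place_prey(3.0, dom, seed=1)) == 1875

    def test_bad_radius(self, square10):
        with pytest.raises(ValueError):
            place_prey(1.0, square10, radius_r=0.0, seed=1)

    def test_nearest_neighbour_distances_match_csr(self):
        # two-sample KS against an independent complete-spatial-randomness draw
        dom = Domain.square(10.0)
        prey = place_prey(100.0, dom, seed=5)  # 10^4 points
        rng = np.random.default_rng(99)
        ref = rng.uniform(0.0, 10.0, size=(10_000, 2))

        def nn(pts):
            d, _ = cKDTree(pts).query(pts, k=2)
            return d[:, 1]

        p = stats.ks_2samp(nn(prey.points), nn(ref)).pvalue
        assert p > 0.01


class TestSimulateTrack:
    def test_isotropic_collapse_uniform_relative_directions(self, one_line_landscape):
        # kappa = 0 and equal alphas everywhere: xi should be uniform
        p = MovementParams(
            alpha_on=0.1, alpha_near=0.1, alpha_off=0.1, kappa_on=0.0,
            kappa_near=0.0, bias_enabled=True,
        )
        tr = simulate_track(p, one_line_landscape, 10_000, seed=21)
        steps = extract_steps(tr, one_line_landscape)
        xi = steps.loc[steps.usable_direction, "rel_direction_deg"].to_numpy()
        counts, _ = np.histogram(xi, bins=36, range=(-180, 180))
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        assert stats.chi2.sf(chi2, df=35) > 0.01

    def test_mean_step_length_lln(self, big_empty_landscape, iso_params):
        tr = simulate_track(
            iso_params, big_empty_landscape, 100_000, seed=4, start=(50.0, 50.0)
        )
        lengths = np.hypot(*np.diff(tr.xy, axis=0).T)
        se = iso_params.alpha_off / np.sqrt(lengths.size)
        assert abs(lengths.mean() - iso_params.alpha_off) < 3.5 * se

    def test_daily_msd_of_off_line_walk(self, big_empty_landscape, iso_params):
        # E[L^2] = 2 alpha^2 = 0.017 km^2 per 5 min -> 4.90 km^2/day
        tr = simulate_track(
            iso_params, big_empty_landscape, 50_000, seed=8, start=(50.0, 50.0)
        )
        msd5 = msd_curve(tr, [5.0])["msd_km2"].iloc[0]
        se = np.sqrt(20) * iso_params.alpha_off**2 / np.sqrt(50_000)
        assert abs(msd5 - 0.017) < 3 * se
        assert abs(msd5 * 288 - 4.90) < 3 * se * 288

    def test_msd_linear_in_lag(self, big_empty_landscape, iso_params):
        tr = simulate_track(
            iso_params, big_empty_landscape, 100_000, seed=9, start=(50.0, 50.0)
        )
        lags = [5.0 * k for k in range(1, 25)]
        curve = msd_curve(tr, lags)
        r = stats.linregress(curve["lag_min"], curve["msd_km2"])
        assert r.rvalue**2 > 0.99

    def test_track_stays_in_domain_and_reproduces(self, cross_landscape):
        p = MovementParams(
            alpha_on=0.15, alpha_near=0.09, alpha_off=0.09, kappa_on=2.0,
            kappa_near=1.0, bias_enabled=True,
        )
        a = simulate_track(p, cross_landscape, 500, seed=13)
        b = simulate_track(p, cross_landscape, 500, seed=13)
        np.testing.assert_array_equal(a.xy, b.xy)
        assert np.all(cross_landscape.domain.contains(a.xy))

    def test_invalid_steps(self, empty_landscape, iso_params):
        with pytest.raises(ValueError):
            simulate_track(iso_params, empty_landscape, 0, seed=1)


class TestIO:
    def test_landscape_roundtrip(self, square10, tmp_path):
        ls = generate_landscape(2.0, square10, seed=6)
        ls.to_geojson(tmp_path / "l.geojson")
        back = Landscape.from_geojson(tmp_path / "l.geojson")
        np.testing.assert_allclose(back.segments, ls.segments)
        assert back.density_S == pytest.approx(ls.density_S)
        ls.to_csv(tmp_path / "l.csv")
        back2 = Landscape.from_csv(tmp_path / "l.csv", square10)
        np.testing.assert_allclose(back2.segments, ls.segments)

    def test_track_roundtrip(self, empty_landscape, iso_params, tmp_path):
        tr = simulate_track(iso_params, empty_landscape, 50, seed=2)
        tr.to_csv(tmp_path / "t.csv")
        back = GPSTrack.from_csv(tmp_path / "t.csv")
        np.testing.assert_allclose(back.xy, tr.xy, atol=1e-9)
        # 5-min cadence survives the ISO round trip
        np.testing.assert_allclose(np.diff(back.times), 5.0 / 60.0, atol=1e-9)

    def test_nonmonotone_times_rejected(self):
        with pytest.raises(ValueError):
            GPSTrack(np.array([0.0, 0.0, 1.0]), np.zeros((3, 2)))
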
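import numpy as np
import pandas as pd
import pytest

from dyneinflex import (
    ConfigurationError,
    GenConfig,
    ImageParams,
    MechanicalParams,
    place_on_mt,
    render_micrograph,
    sample_offset_dimers,
    sample_superposed_dimers,
    simulate_runs,
    to_particle_table,
)
from conftest import block_se


def quadrature_moments_1d(kappa, rest_deg, kbt, half_width_sd=8.0, n=4001):
    """Trapezoid quadrature of the single-hinge Boltzmann density."""
    th0 = np.radians(rest_deg)
    s = np.sqrt(kbt / kappa)
    g = np.linspace(th0 - half_width_sd * s, th0 + half_width_sd * s, n)
    w = np.exp(-0.5 * kappa * (g - th0) ** 2 / kbt)
    w /= np.trapezoid(w, g)
    mean = np.trapezoid(w * g, g)
    var = np.trapezoid(w * (g - mean) ** 2, g)
    return np.degrees(mean), np.degrees(np.sqrt(var))


def quadrature_moments_2d(mech, geom, sep, attach=None, n=400):
    """Grid quadrature of the coupled offset-dimer Boltzmann density."""
    attach = geom.lever_length if attach is None else attach
    kbt = mech.thermal_energy
    th0 = np.radians(mech.rest_angle)
    s = np.sqrt(kbt / min(mech.kappa_trailing, mech.kappa_leading))
    g = np.linspace(th0 - 6 * s, th0 + 6 * s, n)
    TT, TL = np.meshgrid(g, g, indexing="ij")
    ext = sep - attach * np.cos(TL) + attach * np.cos(TT)
    E = (
        0.5 * mech.kappa_trailing * (TT - th0) ** 2
        + 0.5 * mech.kappa_leading * (TL - th0) ** 2
        + 0.5 * mech.tether_stiffness * (ext - mech.tether_rest_separation) ** 2
    )
    w = np.exp(-E / kbt)
    w /= w.sum()
    mt, ml = (w * TT).sum(), (w * TL).sum()
    st = np.sqrt((w * (TT - mt) ** 2).sum())
    sl = np.sqrt((w * (TL - ml) ** 2).sum())
    return tuple(np.degrees(v) for v in (mt, ml, st, sl))


class TestMechanicalParams:
    def test_thermal_energy_computed_from_temperature(self):
        mech = MechanicalParams()
        assert mech.thermal_energy == pytest.approx(4.045, abs=0.005)

    def test_inconsistent_thermal_energy_rejected(self):
        with pytest.raises(ConfigurationError):
            MechanicalParams(temperature=293.0, thermal_energy=4.5)

    def test_negative_stiffness_rejected(self):
        with pytest.raises(ConfigurationError):
            MechanicalParams(kappa_leading=-1.0)


class TestGenConfig:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            GenConfig(separation_weights={8.3: 0.5, 16.6: 0.4})

    def test_positive_n(self):
        with pytest.raises(ConfigurationError):
            GenConfig(n_dimers=0)


class TestSuperposedSampler:
    def test_equipartition_sd(self, geom):
        # kappa = 100.4 pN nm rad^-2 corresponds to an 11.5 deg angular s.d.
        mech = MechanicalParams(kappa_superposed=100.4)
        theta = sample_superposed_dimers(mech, geom, 100_000, seed=1)["theta_deg"]
        se = 11.5 / np.sqrt(2 * (theta.size - 1))
        assert theta.std(ddof=1) == pytest.approx(11.5, abs=3 * se)

    def test_stiff_limit_collapses_to_rest_angle(self, geom):
        mech = MechanicalParams(kappa_superposed=1e6)
        theta = sample_superposed_dimers(mech, geom, 20_000, seed=2)["theta_deg"]
        expected_sd = np.degrees(np.sqrt(mech.thermal_energy / 1e6))  # ~0.12 deg
        assert theta.std(ddof=1) == pytest.approx(expected_sd, rel=0.05)
        assert theta.std(ddof=1) < 0.2  # essentially all mass at the rest angle
        assert theta.mean() == pytest.approx(42.0, abs=0.01)

    def test_moments_match_quadrature(self, geom, mech):
        theta = sample_superposed_dimers(mech, geom, 50_000, seed=3)["theta_deg"]
        qmean, qsd = quadrature_moments_1d(
            mech.kappa_superposed, mech.rest_angle, mech.thermal_energy
        )
        se = qsd / np.sqrt(theta.size)
        assert theta.mean() == pytest.approx(qmean, abs=3 * se)
        assert theta.std(ddof=1) == pytest.approx(qsd, abs=3 * qsd / np.sqrt(2 * theta.size))

    def test_nonpositive_kappa_rejected(self, geom):
        mech = MechanicalParams(kappa_superposed=0.0, tether_stiffness=0.0)
        with pytest.raises(ConfigurationError):
            sample_superposed_dimers(mech, geom, 10, seed=0)


class TestOffsetSampler:
    def test_no_tether_gives_independent_equipartition_angles(self, geom):
        mech = MechanicalParams(
            kappa_trailing=70.75, kappa_leading=70.75, tether_stiffness=0.0
        )
        df = sample_offset_dimers(mech, geom, 8.3, 100_000, seed=1)
        # kappa = 70.75 corresponds to a 13.7 deg s.d. per angle
        for col in ("theta_trailing_deg", "theta_leading_deg"):
            sd = df[col].std(ddof=1)
            assert sd == pytest.approx(13.7, abs=0.15)
        corr = np.corrcoef(df.theta_trailing_deg, df.theta_leading_deg)[0, 1]
        assert abs(corr) < 0.02

    @pytest.mark.parametrize("sep", [0.9, 16.6])
    def test_moments_match_grid_quadrature(self, geom, mech, sep):
        df = sample_offset_dimers(mech, geom, sep, 20_000, seed=3)
        qmt, qml, qst, qsl = quadrature_moments_2d(mech, geom, sep)
        for col, qmean, qsd in (
            ("theta_trailing_deg", qmt, qst),
            ("theta_leading_deg", qml, qsl),
        ):
            se = block_se(df[col].to_numpy())
            assert df[col].mean() == pytest.approx(qmean, abs=3 * se)
            assert df[col].std(ddof=1) == pytest.approx(qsd, rel=0.03)

    def test_tether_tilts_the_two_stalks_apart(self, geom, mech):
        """Larger stalkhead separation steepens the trailing stalk and
        shallows the leading stalk (the tether pulls the heads together)."""
        means = {}
        for i, sep in enumerate((0.9, 24.9)):
            df = sample_offset_dimers(mech, geom, sep, 20_000, seed=20 + i)
            means[sep] = (df.theta_trailing_deg.mean(), df.theta_leading_deg.mean())
        assert means[24.9][0] > means[0.9][0] + 2.0  # trailing steeper
        assert means[24.9][1] < means[0.9][1] - 2.0  # leading shallower

    def test_bitwise_reproducible(self, geom, mech):
        a = sample_offset_dimers(mech, geom, 8.3, 5000, seed=9)
        b = sample_offset_dimers(mech, geom, 8.3, 5000, seed=9)
        pd.testing.assert_frame_equal(a, b)
        c = sample_superposed_dimers(mech, geom, 5000, seed=9)
        d = sample_superposed_dimers(mech, geom, 5000, seed=9)
        pd.testing.assert_frame_equal(c, d)

    def test_zero_stiffness_with_tether_rejected(self, geom):
        mech = MechanicalParams(kappa_trailing=0.0, tether_stiffness=0.035)
        with pytest.raises(ConfigurationError):
            sample_offset_dimers(mech, geom, 8.3, 10, seed=0)


class TestParticleTable:
    def test_mean_configuration_height(self, geom):
        # h = 1.8 + 18.8 sin(42 deg) = 14.38 nm, matching the measured
        # 14.4 +- 3.0 nm ring height of superposed dimers
        tbl = to_particle_table([42.0], geom, [100.0], noise_sd=0.0)
        assert tbl["ring_height_nm"].iloc[0] == pytest.approx(14.38, abs=0.01)

    def test_flat_stalk(self, geom):
        tbl = to_particle_table([0.0], geom, [100.0], noise_sd=0.0)
        assert tbl["ring_height_nm"].iloc[0] == pytest.approx(geom.hinge_height)
        assert tbl["axial_x_nm"].iloc[0] == pytest.approx(100.0 - 18.8)

    def test_angle_out_of_range_rejected(self, geom):
        with pytest.raises(ValueError):
            to_particle_table([195.0], geom, [0.0])
        with pytest.raises(ValueError):
            to_particle_table([-95.0], geom, [0.0])

    def test_past_vertical_angle_folds_in_projection(self, geom):
        # theta and 180 - theta project to the same ring height
        a = to_particle_table([100.0], geom, [50.0])
        b = to_particle_table([80.0], geom, [50.0])
        assert a["ring_height_nm"].iloc[0] == pytest.approx(b["ring_height_nm"].iloc[0])

    def test_noise_reproducible(self, geom):
        a = to_particle_table([40.0] * 100, geom, 0.0, noise_sd=2.0, seed=5)
        b = to_particle_table([40.0] * 100, geom, 0.0, noise_sd=2.0, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestPlaceOnMt:
    def test_expected_counts(self):
        df = place_on_mt(density=2.0, mt_length=1000.0, n_mts=200, seed=4)
        expected = 2.0 * 1000.0 / 100.0 * 200  # Poisson mean over all MTs
        assert len(df) == pytest.approx(expected, abs=3 * np.sqrt(expected))

    def test_zero_density_empty(self):
        assert len(place_on_mt(0.0, 1000.0, 5, seed=1)) == 0

    def test_deterministic(self):
        a = place_on_mt(1.0, 500.0, 10, seed=3)
        b = place_on_mt(1.0, 500.0, 10, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestRender:
    def make_particles(self, n_rings, x=60.0, h=14.4):
        return pd.DataFrame(
            {
                "particle_id": [0],
                "mt_id": [0],
                "axial_x_nm": [x],
                "ring_height_nm": [h],
                "n_rings_visible": [n_rings],
            }
        )

    def test_two_rings_exactly_double_intensity(self, geom):
        params = ImageParams(mt_intensity=0.0)  # isolate the particle signal
        one = render_micrograph(self.make_particles(1), geom, params)
        two = render_micrograph(self.make_particles(2), geom, params)
        assert one.sum() > 0
        assert two.sum() == pytest.approx(2 * one.sum())

    def test_background_is_zero_mean(self, geom):
        img = render_micrograph(self.make_particles(1), geom, ImageParams())
        corner = img[:20, 200:]
        assert corner.mean() == pytest.approx(0.0)

    def test_ring_centroid_matches_requested_centre(self, geom):
        params = ImageParams(mt_intensity=0.0)
        x, h = 60.0, 14.4
        img = render_micrograph(self.make_particles(1, x, h), geom, params)
        rows, cols = np.nonzero(img)
        weights = img[rows, cols]
        crow = (rows * weights).sum() / weights.sum()
        ccol = (cols * weights).sum() / weights.sum()
        assert ccol == pytest.approx(x / params.pixel_size, abs=0.5)
        assert crow == pytest.approx(
            params.mt_surface_row - h / params.pixel_size, abs=0.5
        )


class TestSimulateRuns:
    def test_survival_per_step_matches_independent_heads(self):
        r, n = 0.85, 100_000
        runs = simulate_runs(r, 8.3, n, seed=6)
        q = 1 - (1 - r) ** 2  # per-cycle survival
        surv = (runs >= 8.3).mean()  # completed at least one cycle
        se = np.sqrt(q * (1 - q) / n)
        assert surv == pytest.approx(q, abs=3 * se)

    def test_low_duty_ratio_terminates_immediately(self):
        runs = simulate_runs(0.01, 8.3, 10_000, seed=7)
        assert np.median(runs) < 2 * 8.3

    def test_domain(self):
        with pytest.raises(ValueError):
            simulate_runs(0.0, 8.3, 10, seed=0)
        with pytest.raises(ValueError):
            simulate_runs(1.0, 8.3, 10, seed=0)

    def test_deterministic(self):
        a = simulate_runs(0.9, 8.3, 1000, seed=8)
        b = simulate_runs(0.9, 8.3, 1000, seed=8)
        np.testing.assert_array_equal(a, b)
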
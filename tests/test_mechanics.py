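import numpy as np
import pandas as pd
import pytest

from dyneinflex import (
    MechanicalParams,
    MechanicsError,
    RegressionFit,
    cantilever_stiffness,
    equilibrium_constant,
    mechanics_report,
    ols_fit,
    pairwise_difference_slope,
    ring_sep_from_regressions,
    running_stats,
    sample_offset_dimers,
    stiffness_report,
    tension_at,
    tension_per_nm,
    tether_stiffness,
    torsional_stiffness,
)

KBT = 4.045  # pN nm at 293 K

PAPER_FIT_TRAILING = RegressionFit(slope=0.222, intercept=40.0, n=359)
PAPER_FIT_LEADING = RegressionFit(slope=-0.200, intercept=44.1, n=359)


class TestTorsionalStiffness:
    @pytest.mark.parametrize(
        "sigma, expected, tol",
        [
            (13.7, 71.0, 0.02),  # trailing motor (printed as 71)
            (11.5, 101.0, 0.02),  # superposed dimer (printed as 101)
        ],
    )
    def test_equipartition_values(self, sigma, expected, tol):
        kappa = torsional_stiffness(sigma, KBT)
        assert kappa == pytest.approx(expected, rel=tol)

    def test_unit_variance(self):
        assert torsional_stiffness(np.degrees(1.0), KBT) == pytest.approx(KBT)

    def test_domain(self):
        with pytest.raises(MechanicsError):
            torsional_stiffness(0.0)


class TestCantileverStiffness:
    @pytest.mark.parametrize(
        "kappa, phi, expected, tol",
        [
            (72.0, 41.9, 1.07, 0.01),
            (71.0, 42.7, 1.03, 0.01),
            (101.0, 41.5, 1.53, 0.02),  # printed value carries a rounding gap
        ],
    )
    def test_printed_triplet(self, kappa, phi, expected, tol):
        assert cantilever_stiffness(kappa, 12.3, phi) == pytest.approx(expected, rel=tol)

    def test_perpendicular_lever(self):
        assert cantilever_stiffness(72.0, 12.3, 90.0) == pytest.approx(72.0 / 12.3**2)

    def test_algebraic_closure(self):
        # k (L sin phi)^2 == kappa identically
        for kappa, phi in ((50.0, 30.0), (101.0, 41.5), (7.0, 80.0)):
            k = cantilever_stiffness(kappa, 12.3, phi)
            assert k * (12.3 * np.sin(np.radians(phi))) ** 2 == pytest.approx(kappa)

    def test_domain(self):
        with pytest.raises(MechanicsError):
            cantilever_stiffness(72.0, 12.3, 0.0)


class TestOlsFit:
    def test_recovers_noiseless_line(self):
        x = np.linspace(0, 25, 50)
        fit = ols_fit(x, 40.0 + 0.222 * x)
        assert fit.slope == pytest.approx(0.222, abs=1e-10)
        assert fit.intercept == pytest.approx(40.0, abs=1e-9)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 25, 500)
        y = 40 + 0.2 * x + rng.normal(0, 5, 500)
        fit = ols_fit(x, y)
        # closed-form normal equations
        sxx = np.sum((x - x.mean()) ** 2)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        intercept = y.mean() - slope * x.mean()
        assert fit.slope == pytest.approx(slope, abs=1e-9)
        assert fit.intercept == pytest.approx(intercept, abs=1e-9)

    def test_generator_closure_slope_signs(self, geom, mech):
        """With the tether on, trailing angles rise and leading angles fall
        with stalkhead separation, matching the observed regressions."""
        frames = []
        for i, sep in enumerate((0.9, 8.3, 16.6, 24.9)):
            df = sample_offset_dimers(mech, geom, sep, 2500, seed=30 + i)
            df["sep"] = sep
            frames.append(df)
        data = pd.concat(frames, ignore_index=True)
        assert ols_fit(data["sep"], data["theta_trailing_deg"]).slope > 0
        assert ols_fit(data["sep"], data["theta_leading_deg"]).slope < 0

    def test_degenerate_inputs(self):
        with pytest.raises(MechanicsError):
            ols_fit([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(MechanicsError):
            ols_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRunningStats:
    def test_single_window_equals_global_stats(self):
        rng = np.random.default_rng(1)
        x, y = np.sort(rng.uniform(0, 25, 100)), rng.normal(42, 13, 100)
        out = running_stats(x, y, window=100)
        assert len(out) == 1
        assert out["mean_x"].iloc[0] == pytest.approx(x.mean())
        assert out["mean_y"].iloc[0] == pytest.approx(y.mean())
        assert out["sd_y"].iloc[0] == pytest.approx(y.std(ddof=1))

    def test_output_length(self):
        rng = np.random.default_rng(2)
        out = running_stats(rng.uniform(0, 25, 359), rng.normal(42, 13, 359), 100)
        assert len(out) == 359 - 100 + 1 == 260

    def test_matches_naive_recomputation_exactly(self):
        rng = np.random.default_rng(3)
        x, y = rng.uniform(0, 25, 250), rng.normal(42, 13, 250)
        window = 40
        out = running_stats(x, y, window)
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y[order]
        for i in range(len(xs) - window + 1):
            assert out["mean_x"].iloc[i] == xs[i : i + window].mean()
            assert out["mean_y"].iloc[i] == ys[i : i + window].mean()
            assert out["sd_y"].iloc[i] == ys[i : i + window].std(ddof=1)

    def test_too_few_points(self):
        with pytest.raises(MechanicsError):
            running_stats([1.0, 2.0], [1.0, 2.0], window=100)


class TestPairwiseDifferenceSlope:
    def test_printed_value(self):
        slope = pairwise_difference_slope(PAPER_FIT_LEADING, PAPER_FIT_TRAILING)
        assert slope == pytest.approx(-0.422, abs=1e-12)

    def test_symmetry(self):
        f = RegressionFit(0.3, 40.0, 10)
        assert pairwise_difference_slope(f, f) == 0.0
        g = RegressionFit(-0.3, 40.0, 10)
        assert pairwise_difference_slope(g, f) == pytest.approx(-0.6)


class TestTension:
    @pytest.mark.parametrize(
        "kappa, slope, phi, expected",
        [
            (71.0, 0.222, 42.7, 0.033),  # trailing
            (72.0, 0.200, 41.9, 0.031),  # leading
        ],
    )
    def test_per_nm(self, kappa, slope, phi, expected):
        assert tension_per_nm(kappa, slope, 12.3, phi) == pytest.approx(expected, abs=5e-4)

    def test_zero_stiffness(self):
        assert tension_per_nm(0.0, 0.2, 12.3, 42.0) == 0.0

    @pytest.mark.parametrize(
        "sep, expected", [(8.3, 0.26), (16.6, 0.53), (24.9, 0.79)]
    )
    def test_tension_at_separation_classes(self, sep, expected):
        assert tension_at(sep, 0.032) == pytest.approx(expected, abs=0.01)

    def test_tension_at_zero(self):
        assert tension_at(0.0, 0.032) == 0.0


class TestRingSepFromRegressions:
    @pytest.mark.parametrize(
        "x, expected",
        [(0.9, -0.1), (8.3, 6.6), (16.6, 14.2), (24.9, 21.7)],
    )
    def test_as_published_reproduces_printed_values(self, x, expected):
        val = ring_sep_from_regressions(
            x, PAPER_FIT_TRAILING, PAPER_FIT_LEADING, 18.8, "as_published"
        )
        assert val == pytest.approx(expected, abs=0.05)

    def test_zero_slope_identity(self):
        f = RegressionFit(0.0, 42.0, 10)
        assert ring_sep_from_regressions(16.6, f, f, 18.8, "as_published") == pytest.approx(16.6)

    def test_geometric_mode_differs_by_design(self):
        # the self-consistent rigid-body evaluation gives ~+0.9 nm at x=0
        val = ring_sep_from_regressions(
            0.0, PAPER_FIT_TRAILING, PAPER_FIT_LEADING, 18.8, "geometric"
        )
        assert val == pytest.approx(0.9, abs=0.05)

    def test_unknown_mode(self):
        with pytest.raises(MechanicsError):
            ring_sep_from_regressions(1.0, PAPER_FIT_TRAILING, PAPER_FIT_LEADING, 18.8, "x")


class TestTetherStiffness:
    def test_printed_increments(self):
        assert tether_stiffness(0.53 - 0.26, 14.2 - 6.6) == pytest.approx(0.035, abs=0.001)

    def test_zero_tension(self):
        assert tether_stiffness(0.0, 5.0) == 0.0

    def test_consistency_with_unrounded_chain(self):
        """per-nm tension divided by d(ring_sep)/dx gives the same stiffness."""
        tpn = 0.5 * (
            tension_per_nm(71.0, 0.222, 12.3, 42.7)
            + tension_per_nm(72.0, 0.200, 12.3, 41.9)
        )
        r1 = ring_sep_from_regressions(8.3, PAPER_FIT_TRAILING, PAPER_FIT_LEADING, 18.8)
        r2 = ring_sep_from_regressions(16.6, PAPER_FIT_TRAILING, PAPER_FIT_LEADING, 18.8)
        k1 = tether_stiffness(tpn * (16.6 - 8.3), r2 - r1)
        drdx = (r2 - r1) / (16.6 - 8.3)
        assert k1 == pytest.approx(tpn / drdx, rel=0.02)

    def test_zero_increment_rejected(self):
        with pytest.raises(MechanicsError):
            tether_stiffness(0.1, 0.0)


class TestEquilibriumConstant:
    def test_printed_counts(self):
        assert equilibrium_constant(318, 31) == pytest.approx(10.26, abs=0.01)

    def test_identity_and_zero(self):
        assert equilibrium_constant(5, 5) == 1.0
        assert equilibrium_constant(0, 5) == 0.0

    def test_zero_denominator(self):
        with pytest.raises(MechanicsError):
            equilibrium_constant(10, 0)


class TestStiffnessReport:
    def test_invariants(self):
        rng = np.random.default_rng(4)
        angles = rng.normal(42, 13, 1000)
        rep = stiffness_report(angles, KBT, 12.3)
        sigma_rad = np.radians(rep.sigma_deg)
        assert rep.kappa == pytest.approx(KBT / sigma_rad**2)
        assert rep.cantilever_k == pytest.approx(
            rep.kappa / (12.3 * np.sin(np.radians(rep.phi_mean))) ** 2
        )
        assert rep.n == 1000


def test_mechanics_report_end_to_end(geom, mech):
    frames = []
    for i, sep in enumerate((0.9, 8.3, 16.6, 24.9)):
        df = sample_offset_dimers(mech, geom, sep, 1500, seed=40 + i)
        df["stalkhead_separation_nm"] = sep
        frames.append(df)
    dimers = pd.concat(frames, ignore_index=True)
    rep = mechanics_report(
        dimers,
        superposed_theta=np.random.default_rng(5).normal(41.5, 11.5, 400),
        geom=geom,
        mode="geometric",
        n_superposed_rings=318,
        n_offset_rings_superposed_stalkheads=31,
    )
    assert rep["regression"]["trailing"]["slope"] > 0
    assert rep["regression"]["leading"]["slope"] < 0
    assert 50 < rep["stiffness"]["trailing"]["kappa"] < 100
    assert rep["equilibrium_constant"]["value"] == pytest.approx(10.26, abs=0.01)
    assert "running_average" in rep
    assert rep["tension"]["tether_stiffness"] == pytest.approx(0.035, rel=0.5)
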
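"""Equipartition mechanics of the MT-bound dimer.

Chain of deductions from measured stalk-angle statistics:

* torsional stiffness of the stalk-stalkhead hinge by equipartition,
  kappa = kB T / sigma^2, with sigma the s.d. of the measured angle in
  radians;
* apparent cantilever stiffness of an attached motor (its resistance to
  axial force applied at the base of the stalk, a lever length L from the
  hinge), k = kappa / (L sin(phi))^2 at mean angle phi;
* the dependence of mean stalk angle on stalkhead separation (ordinary
  least-squares regression and 100-point running averages) converted to a
  time-averaged inter-head tension per nm of separation by torque balance,
  T' = kappa |m| / (L sin(phi)) with the slope m in rad/nm;
* the ring-centre separation predicted from the two regression lines,
  which together with the tension increments yields the stiffness of the
  elastic head-head linkage;
* the head-head association equilibrium constant from the ratio of
  superposed-ring to offset-ring counts among molecules whose stalkheads
  are superposed.

Angles enter and leave in degrees; radians appear only inside formulas.
Stiffnesses are in pN nm rad^-2 (torsional) and pN nm^-1 (linear).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import MotorGeometry
from .synthgen import BOLTZMANN_PN_NM

__all__ = [
    "MechanicsError",
    "StiffnessReport",
    "RegressionFit",
    "TensionReport",
    "torsional_stiffness",
    "cantilever_stiffness",
    "stiffness_report",
    "ols_fit",
    "running_stats",
    "pairwise_difference_slope",
    "tension_per_nm",
    "tension_at",
    "ring_sep_from_regressions",
    "tether_stiffness",
    "equilibrium_constant",
    "mechanics_report",
]

#: kB * 293 K in pN nm, the thermal energy at the imaging temperature.
THERMAL_ENERGY_293K = BOLTZMANN_PN_NM * 293.0


class MechanicsError(ValueError):
    """Raised for degenerate inputs to the mechanics chain."""


@dataclass(frozen=True)
class StiffnessReport:
    """Equipartition stiffness estimates for one motor class."""

    sigma_deg: float
    kappa: float  # pN nm rad^-2
    phi_mean: float  # deg
    cantilever_k: float  # pN nm^-1
    n: int


@dataclass(frozen=True)
class RegressionFit:
    """Unweighted least-squares line: angle (deg) vs separation (nm)."""

    slope: float  # deg / nm
    intercept: float  # deg
    n: int


@dataclass(frozen=True)
class TensionReport:
    """Inter-head tension estimates and the derived tether stiffness."""

    tension_per_nm_leading: float
    tension_per_nm_trailing: float
    tension_per_nm_mean: float
    tensions_at: dict[float, float]
    tether_stiffness: float


def torsional_stiffness(
    sigma: float, thermal_energy: float = THERMAL_ENERGY_293K
) -> float:
    """Hinge torsional stiffness (pN nm rad^-2) by equipartition.

    ``sigma`` is the s.d. of the stalk angle in degrees; each quadratic
    degree of freedom holds kB T / 2, so kappa = kB T / sigma_rad^2.
    """
    if sigma <= 0:
        raise MechanicsError("sigma must be positive")
    return thermal_energy / np.radians(sigma) ** 2


def cantilever_stiffness(kappa: float, lever: float, phi: float) -> float:
    """Apparent cantilever stiffness (pN nm^-1) of an attached motor.

    A torsional spring kappa at the hinge resists axial displacement x of
    the lever tip; with the stalk at angle ``phi`` (degrees) to the MT axis
    the effective lever is L sin(phi), hence k = kappa / (L sin(phi))^2.
    """
    if lever <= 0:
        raise MechanicsError("lever must be positive")
    if not 0.0 < phi <= 90.0:
        raise MechanicsError("phi must lie in (0, 90] degrees")
    return kappa / (lever * np.sin(np.radians(phi))) ** 2


def stiffness_report(
    angles_deg: Sequence[float] | np.ndarray,
    thermal_energy: float = THERMAL_ENERGY_293K,
    lever: float = 12.3,
) -> StiffnessReport:
    """Full equipartition report from a sample of stalk angles (degrees).

    The angle s.d. uses denominator n - 1; the cantilever stiffness is
    evaluated at the sample mean angle.
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size < 2:
        raise MechanicsError("need at least two angles")
    sigma = float(np.std(a, ddof=1))
    phi = float(np.mean(a))
    kappa = float(torsional_stiffness(sigma, thermal_energy))
    return StiffnessReport(
        sigma_deg=sigma,
        kappa=kappa,
        phi_mean=phi,
        cantilever_k=float(cantilever_stiffness(kappa, lever, phi)),
        n=int(a.size),
    )


def ols_fit(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Ordinary (unweighted) least-squares line of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise MechanicsError("x and y must have equal length")
    if x.size < 3:
        raise MechanicsError("need at least 3 points")
    if np.ptp(x) == 0:
        raise MechanicsError("x has zero variance")
    res = stats.linregress(x, y)
    return RegressionFit(slope=float(res.slope), intercept=float(res.intercept), n=int(x.size))


def running_stats(
    x: Sequence[float],
    y: Sequence[float],
    window: int = 100,
) -> pd.DataFrame:
    """Sliding-window running averages of y against x.

    With the data sorted by x, each of the n - window + 1 output rows holds
    the arithmetic mean of x, mean of y and s.d. of y (denominator n - 1)
    over one window; the window then advances by one point.  Input not
    already sorted by x is sorted (stably) first.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise MechanicsError("x and y must have equal length")
    if window < 2:
        raise MechanicsError("window must be >= 2")
    if x.size < window:
        raise MechanicsError(f"need at least window={window} points, got {x.size}")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    wx = np.lib.stride_tricks.sliding_window_view(xs, window)
    wy = np.lib.stride_tricks.sliding_window_view(ys, window)
    return pd.DataFrame(
        {
            "mean_x": wx.mean(axis=1),
            "mean_y": wy.mean(axis=1),
            "sd_y": wy.std(axis=1, ddof=1),
        }
    )


def pairwise_difference_slope(
    fit_leading: RegressionFit, fit_trailing: RegressionFit
) -> float:
    """Slope (deg/nm) of the leading-minus-trailing angle difference."""
    return fit_leading.slope - fit_trailing.slope


def tension_per_nm(
    kappa: float, slope: float, lever: float, phi_mean: float
) -> float:
    """Inter-head tension per nm of stalkhead separation (pN/nm).

    Torque balance at the hinge: an axial force F at the lever tip exerts
    torque F * L sin(phi), which a torsional spring balances with
    kappa * dtheta.  A measured angle-vs-separation slope |m| (deg/nm,
    converted to rad/nm) therefore implies dF/dx = kappa |m| / (L sin(phi)).
    """
    if lever <= 0:
        raise MechanicsError("lever must be positive")
    if not 0.0 < phi_mean <= 90.0:
        raise MechanicsError("phi_mean must lie in (0, 90] degrees")
    slope_rad = np.radians(abs(slope))
    return kappa * slope_rad / (lever * np.sin(np.radians(phi_mean)))


def tension_at(separation: float, per_nm: float) -> float:
    """Time-averaged tension (pN) at a given stalkhead separation (nm)."""
    return separation * per_nm


def ring_sep_from_regressions(
    stalkhead_sep: float,
    fit_trailing: RegressionFit,
    fit_leading: RegressionFit,
    ring_to_hinge: float,
    mode: str = "as_published",
) -> float:
    """Mean axial ring-centre separation at a given stalkhead separation.

    ``as_published`` uses the linearized form

        ring_sep(x) = x [1 - L (sin(b_t) |m_t| + sin(b_l) |m_l|)_rad]
                      + L (cos(b_l) - cos(b_t)),

    with b the regression intercepts and m the slopes in rad/nm, which
    reproduces the published estimates (-0.1, 6.6, 14.2, 21.7 nm at the
    four lattice separations).  ``geometric`` evaluates the self-consistent
    rigid-body expression

        ring_sep(x) = x - L cos(theta_l(x)) + L cos(theta_t(x))

    with both angles taken from the regression lines; the two conventions
    deliberately disagree by ~1 nm and are both retained (the geometric
    form is the one the synthetic-data generator obeys).
    """
    L = ring_to_hinge
    mt, ml = fit_trailing.slope, fit_leading.slope
    bt, bl = fit_trailing.intercept, fit_leading.intercept
    if mode == "as_published":
        shrink = L * np.radians(
            np.sin(np.radians(bt)) * abs(mt) + np.sin(np.radians(bl)) * abs(ml)
        )
        return float(
            stalkhead_sep * (1.0 - shrink)
            + L * (np.cos(np.radians(bl)) - np.cos(np.radians(bt)))
        )
    if mode == "geometric":
        th_t = np.radians(bt + mt * stalkhead_sep)
        th_l = np.radians(bl + ml * stalkhead_sep)
        return float(stalkhead_sep - L * np.cos(th_l) + L * np.cos(th_t))
    raise MechanicsError(f"unknown mode {mode!r}; use 'as_published' or 'geometric'")


def tether_stiffness(tension_increment: float, ring_sep_increment: float) -> float:
    """Stiffness (pN/nm) of the elastic head-head linkage.

    All dimer components carry the inter-head tension in series, so the
    linkage stiffness is the increment of tension between two separation
    classes divided by the corresponding increment of ring separation.
    """
    if ring_sep_increment == 0:
        raise MechanicsError("ring separation increment must be nonzero")
    return tension_increment / ring_sep_increment


def equilibrium_constant(
    n_superposed_rings: int, n_offset_rings_superposed_stalkheads: int
) -> float:
    """Head-head association constant under zero load.

    Ratio of superposed-ring to offset-ring counts among molecules whose
    stalkheads are superposed on the lattice.
    """
    if n_offset_rings_superposed_stalkheads == 0:
        raise MechanicsError("offset-ring count must be nonzero")
    return n_superposed_rings / n_offset_rings_superposed_stalkheads


def mechanics_report(
    dimers: pd.DataFrame,
    superposed_theta: Sequence[float] | np.ndarray | None = None,
    *,
    geom: MotorGeometry | None = None,
    thermal_energy: float = THERMAL_ENERGY_293K,
    separations: Sequence[float] = (0.9, 8.3, 16.6, 24.9),
    mode: str = "as_published",
    window: int = 100,
    n_superposed_rings: int | None = None,
    n_offset_rings_superposed_stalkheads: int | None = None,
) -> dict:
    """Run the full mechanics chain on a measured dimer table.

    ``dimers`` must carry ``stalkhead_separation_nm``, ``theta_trailing_deg``
    and ``theta_leading_deg`` columns.  Returns a JSON-serializable dict
    with the per-class stiffness reports, the regressions and running
    averages, the tension estimates, the predicted ring separations, the
    tether stiffness (from the increment between the second and third
    separation classes) and, if both counts are given, the head-head
    equilibrium constant.
    """
    geom = geom if geom is not None else MotorGeometry()
    sep = dimers["stalkhead_separation_nm"].to_numpy(dtype=float)
    th_t = dimers["theta_trailing_deg"].to_numpy(dtype=float)
    th_l = dimers["theta_leading_deg"].to_numpy(dtype=float)

    fit_t = ols_fit(sep, th_t)
    fit_l = ols_fit(sep, th_l)
    rep_t = stiffness_report(th_t, thermal_energy, geom.lever_length)
    rep_l = stiffness_report(th_l, thermal_energy, geom.lever_length)

    tpn_t = tension_per_nm(rep_t.kappa, fit_t.slope, geom.lever_length, rep_t.phi_mean)
    tpn_l = tension_per_nm(rep_l.kappa, fit_l.slope, geom.lever_length, rep_l.phi_mean)
    tpn_mean = 0.5 * (tpn_t + tpn_l)

    tensions = {float(s): float(tension_at(s, tpn_mean)) for s in separations}
    ring_seps = {
        float(s): ring_sep_from_regressions(s, fit_t, fit_l, geom.ring_to_hinge, mode)
        for s in separations
    }
    s_lo, s_hi = separations[1], separations[2]
    k_tether = tether_stiffness(
        tensions[s_hi] - tensions[s_lo], ring_seps[s_hi] - ring_seps[s_lo]
    )

    report: dict = {
        "mode": mode,
        "thermal_energy_pN_nm": float(thermal_energy),
        "lever_length_nm": float(geom.lever_length),
        "ring_to_hinge_nm": float(geom.ring_to_hinge),
        "stiffness": {
            "trailing": asdict(rep_t),
            "leading": asdict(rep_l),
        },
        "regression": {
            "trailing": asdict(fit_t),
            "leading": asdict(fit_l),
            "pairwise_difference_slope_deg_per_nm": float(
                pairwise_difference_slope(fit_l, fit_t)
            ),
        },
        "tension": asdict(
            TensionReport(
                tension_per_nm_leading=float(tpn_l),
                tension_per_nm_trailing=float(tpn_t),
                tension_per_nm_mean=float(tpn_mean),
                tensions_at=tensions,
                tether_stiffness=float(k_tether),
            )
        ),
        "ring_separations_nm": ring_seps,
    }
    if len(sep) >= window:
        rs_t = running_stats(sep, th_t, window)
        rs_l = running_stats(sep, th_l, window)
        report["running_average"] = {
            "window": int(window),
            "trailing": rs_t.to_dict(orient="list"),
            "leading": rs_l.to_dict(orient="list"),
        }
    if superposed_theta is not None and len(np.atleast_1d(superposed_theta)) >= 2:
        rep_s = stiffness_report(superposed_theta, thermal_energy, geom.lever_length)
        report["stiffness"]["superposed"] = asdict(rep_s)
    if (
        n_superposed_rings is not None
        and n_offset_rings_superposed_stalkheads is not None
        and n_offset_rings_superposed_stalkheads > 0
    ):
        report["equilibrium_constant"] = {
            "n_superposed_rings": int(n_superposed_rings),
            "n_offset_rings_superposed_stalkheads": int(
                n_offset_rings_superposed_stalkheads
            ),
            "value": float(
                equilibrium_constant(
                    n_superposed_rings, n_offset_rings_superposed_stalkheads
                )
            ),
        }
    return report
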
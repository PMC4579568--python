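"""Synthetic data: a Boltzmann mechanical model of MT-bound dimers.

The generator stands in for raw cryo-EM and single-molecule fluorescence
data.  Each motor of a dimer is a rigid body hinged at the stalk-stalkhead
junction, with a torsional spring (stiffness ``kappa``, rest angle ~42 deg)
at the hinge.  The two motors of an offset dimer are coupled by a linear
spring (the GST/linker tether, stiffness ``k_tether``) acting between the
linker ends at the base of the two stalks, a lever length from each hinge.
For stalkheads fixed a lattice separation apart, the configurational
energy of the dimer is

    E(th_t, th_l) = 1/2 kappa_t (th_t - th0)^2 + 1/2 kappa_l (th_l - th0)^2
                    + 1/2 k_tether (ext(th_t, th_l) - d0)^2,

    ext = separation - L_a cos(th_l) + L_a cos(th_t),

with ``L_a`` the tether attachment length (default: the lever length) and
angles in radians inside the formula.  Angle pairs are drawn from the
Boltzmann distribution exp(-E / kB T) by a Metropolis random walk; the
uncoupled single-hinge case (superposed dimers) is exactly Gaussian and is
sampled directly.

Forward geometry converts sampled angles into the particle-table
observables measured from micrographs (ring axial position and height
above the MT surface), optionally with Gaussian measurement noise, and a
toy renderer produces 2-D intensity images for testing the pixel-sum
discrimination.  A stochastic run-length simulator with independent heads
provides synthetic single-molecule run tables.

All samplers are reproducible bit-for-bit given (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.draw import disk, line

from .geometry import MotorGeometry

__all__ = [
    "BOLTZMANN_PN_NM",
    "ConfigurationError",
    "MechanicalParams",
    "GenConfig",
    "ImageParams",
    "sample_offset_dimers",
    "sample_superposed_dimers",
    "to_particle_table",
    "place_on_mt",
    "render_micrograph",
    "simulate_runs",
]

#: Boltzmann constant in pN nm / K.
BOLTZMANN_PN_NM = 1.380649e-2


class ConfigurationError(ValueError):
    """Raised for physically inconsistent generator parameters."""


@dataclass(frozen=True)
class MechanicalParams:
    """Mechanical constants of the dimer model.

    Torsional stiffnesses are in pN nm rad^-2, the tether stiffness in
    pN nm^-1, angles in degrees, ``thermal_energy`` (kB*T) in pN nm.  If
    ``thermal_energy`` is omitted it is computed from the temperature; a
    supplied value must agree with kB*T to 0.1%.

    The tether rest separation defaults to 0 nm: the superposed
    configuration, with the two linker ends stacked, is taken as the
    zero-strain state of the head-head linkage.
    """

    kappa_leading: float = 72.0
    kappa_trailing: float = 71.0
    kappa_superposed: float = 101.0
    rest_angle: float = 42.0
    tether_stiffness: float = 0.035
    tether_rest_separation: float = 0.0
    temperature: float = 293.0
    thermal_energy: float | None = None

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ConfigurationError("temperature must be positive")
        for name in ("kappa_leading", "kappa_trailing", "kappa_superposed",
                     "tether_stiffness"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        kbt = BOLTZMANN_PN_NM * self.temperature
        if self.thermal_energy is None:
            object.__setattr__(self, "thermal_energy", kbt)
        elif abs(self.thermal_energy - kbt) > 1e-3 * kbt:
            raise ConfigurationError(
                f"thermal_energy {self.thermal_energy:g} disagrees with "
                f"kB*T = {kbt:g} pN nm by more than 0.1%"
            )


def _default_weights() -> dict[float, float]:
    # Emulates the observed stalkhead-separation histogram: most at ~8 nm,
    # fewer at ~16 nm, few at ~25 nm, a small stagger-only class.
    return {0.9: 0.10, 8.3: 0.55, 16.6: 0.25, 24.9: 0.10}


@dataclass
class GenConfig:
    """Settings of the synthetic particle-field generator."""

    n_dimers: int = 2000
    seed: int = 0
    separation_weights: dict[float, float] = field(default_factory=_default_weights)
    measurement_noise_sd: float = 1.0
    crowding_density: float = 1.0  # molecules per 100 nm of MT
    superposed_fraction: float = 0.5
    mt_length: float = 2000.0

    def __post_init__(self) -> None:
        if self.n_dimers <= 0:
            raise ConfigurationError("n_dimers must be positive")
        total = sum(self.separation_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError("separation_weights must sum to 1")
        if not 0.0 <= self.superposed_fraction <= 1.0:
            raise ConfigurationError("superposed_fraction must be in [0, 1]")
        if self.measurement_noise_sd < 0 or self.crowding_density < 0:
            raise ConfigurationError("noise and density must be >= 0")


def sample_offset_dimers(
    mech: MechanicalParams,
    geom: MotorGeometry,
    lattice_sep: float,
    n: int,
    seed: int,
    *,
    burn_in: int = 1000,
    thinning: int = 10,
    proposal_sd: float = 5.0,
    n_chains: int | None = None,
    tether_attach_length: float | None = None,
) -> pd.DataFrame:
    """Draw (trailing, leading) stalk-angle pairs for an offset dimer.

    Metropolis random walk in the (th_t, th_l) plane with isotropic
    Gaussian proposals (s.d. ``proposal_sd`` degrees), run as ``n_chains``
    parallel chains each burnt in for ``burn_in`` sweeps and thinned by
    ``thinning``.  Returns a DataFrame with ``theta_trailing_deg`` and
    ``theta_leading_deg`` columns of length ``n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if lattice_sep < 0:
        raise ValueError("lattice_sep must be >= 0")
    if mech.tether_stiffness > 0 and (
        mech.kappa_trailing <= 0 or mech.kappa_leading <= 0
    ):
        raise ConfigurationError(
            "non-positive hinge stiffness with a nonzero tether leaves the "
            "dimer energy unbounded below"
        )
    attach = geom.lever_length if tether_attach_length is None else tether_attach_length
    kbt = mech.thermal_energy
    th0 = np.radians(mech.rest_angle)
    kt, kl = mech.kappa_trailing, mech.kappa_leading
    ksp, d0 = mech.tether_stiffness, mech.tether_rest_separation

    def energy(tt: np.ndarray, tl: np.ndarray) -> np.ndarray:
        ext = lattice_sep - attach * np.cos(tl) + attach * np.cos(tt)
        return (
            0.5 * kt * (tt - th0) ** 2
            + 0.5 * kl * (tl - th0) ** 2
            + 0.5 * ksp * (ext - d0) ** 2
        )

    rng = np.random.default_rng(seed)
    chains = int(n_chains) if n_chains is not None else min(n, 256)
    draws = -(-n // chains)
    tt = np.full(chains, th0)
    tl = np.full(chains, th0)
    e = energy(tt, tl)
    step = np.radians(proposal_sd)
    out_t = np.empty((draws, chains))
    out_l = np.empty((draws, chains))
    kept = 0
    for sweep in range(burn_in + thinning * draws):
        pt = tt + rng.normal(0.0, step, chains)
        pl = tl + rng.normal(0.0, step, chains)
        e_new = energy(pt, pl)
        accept = np.log(rng.random(chains)) < -(e_new - e) / kbt
        tt = np.where(accept, pt, tt)
        tl = np.where(accept, pl, tl)
        e = np.where(accept, e_new, e)
        done = sweep - burn_in + 1
        if done > 0 and done % thinning == 0:
            out_t[kept] = tt
            out_l[kept] = tl
            kept += 1
    return pd.DataFrame(
        {
            "theta_trailing_deg": np.degrees(out_t.ravel()[:n]),
            "theta_leading_deg": np.degrees(out_l.ravel()[:n]),
        }
    )


def sample_superposed_dimers(
    mech: MechanicalParams,
    geom: MotorGeometry,
    n: int,
    seed: int,
) -> pd.DataFrame:
    """Draw single stalk angles for superposed dimers.

    The single-hinge Boltzmann density exp(-kappa (th - th0)^2 / 2 kB T) is
    exactly Gaussian with s.d. sqrt(kB T / kappa), so it is sampled
    directly (no Markov chain needed).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mech.kappa_superposed <= 0:
        raise ConfigurationError("kappa_superposed must be positive")
    sigma_deg = np.degrees(np.sqrt(mech.thermal_energy / mech.kappa_superposed))
    rng = np.random.default_rng(seed)
    theta = mech.rest_angle + rng.normal(0.0, sigma_deg, n)
    return pd.DataFrame({"theta_deg": theta})


def to_particle_table(
    theta_deg: Sequence[float] | np.ndarray,
    geom: MotorGeometry,
    stalkhead_x: Sequence[float] | np.ndarray | float,
    noise_sd: float = 0.0,
    seed: int | None = None,
    *,
    mt_id: int | Sequence[int] = 0,
    start_id: int = 0,
    n_rings_visible: int = 1,
    pixel_sum: float | None = None,
    class_label: str = "unknown",
) -> pd.DataFrame:
    """Forward geometry: angles + stalkhead anchors -> measured particles.

    Inverse of the trigonometric deduction: the ring centre sits at height
    ``hinge_height + ring_to_hinge * sin(theta)`` above the MT surface and
    ``ring_to_hinge * cos(theta)`` plus-end-ward of its stalkhead.
    Independent Gaussian noise of s.d. ``noise_sd`` nm is added to both
    coordinates; with ``noise_sd = 0`` and angles below 90 degrees the
    table round-trips exactly through the geometry module.  Angles outside
    (0, 90) degrees are accepted up to [-90, 180]: past vertical the
    projected height folds (the deduction recovers 180 - theta, as it
    would for a real micrograph), while negative angles put the ring below
    the hinge and yield particles the measurement stage must discard.
    """
    theta = np.asarray(theta_deg, dtype=float)
    if np.any(theta < -90) or np.any(theta > 180):
        raise ValueError("theta must lie in [-90, 180] degrees")
    sh = np.broadcast_to(np.asarray(stalkhead_x, dtype=float), theta.shape).copy()
    th = np.radians(theta)
    ring_x = sh - geom.ring_to_hinge * np.cos(th)
    height = geom.hinge_height + geom.ring_to_hinge * np.sin(th)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ring_x = ring_x + rng.normal(0.0, noise_sd, theta.shape)
        height = height + rng.normal(0.0, noise_sd, theta.shape)
    n = theta.size
    if pixel_sum is None:
        pixel_sum = float(n_rings_visible)
    return pd.DataFrame(
        {
            "particle_id": np.arange(start_id, start_id + n, dtype=int),
            "mt_id": np.broadcast_to(np.asarray(mt_id), theta.shape).astype(int),
            "axial_x_nm": ring_x,
            "ring_height_nm": height,
            "n_rings_visible": np.full(n, n_rings_visible, dtype=int),
            "pixel_sum": np.full(n, pixel_sum, dtype=float),
            "class_label": np.full(n, class_label, dtype=object),
        }
    )


def place_on_mt(
    density: float,
    mt_length: float,
    n_mts: int,
    seed: int,
) -> pd.DataFrame:
    """Poisson placement of molecules along microtubules.

    ``density`` is in molecules per 100 nm of MT; each MT receives a
    Poisson-distributed count with mean ``density * mt_length / 100`` and
    uniform axial positions, sorted within each MT.
    """
    if density < 0 or mt_length <= 0 or n_mts < 1:
        raise ValueError("need density >= 0, mt_length > 0, n_mts >= 1")
    rng = np.random.default_rng(seed)
    frames = []
    next_id = 0
    for mt in range(n_mts):
        count = int(rng.poisson(density * mt_length / 100.0))
        xs = np.sort(rng.uniform(0.0, mt_length, count))
        frames.append(
            pd.DataFrame(
                {
                    "particle_id": np.arange(next_id, next_id + count, dtype=int),
                    "mt_id": np.full(count, mt, dtype=int),
                    "axial_x_nm": xs,
                }
            )
        )
        next_id += count
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["particle_id", "mt_id", "axial_x_nm"]
    )


@dataclass(frozen=True)
class ImageParams:
    """Toy micrograph geometry: sizes in pixels, lengths in nm.

    The MT runs horizontally; its upper surface is at row
    ``mt_surface_row`` and heights increase upward (decreasing row index).
    Protein is pale (positive) on a zero-mean background, as in
    contrast-inverted cryo-EM images.
    """

    shape: tuple[int, int] = (128, 256)
    pixel_size: float = 0.5
    mt_surface_row: int = 96
    mt_width_nm: float = 25.0
    mt_intensity: float = 0.5
    ring_intensity: float = 1.0
    stalk_intensity: float = 0.5
    ring_inner_fraction: float = 0.45
    noise_sd: float = 0.0


def render_micrograph(
    particles: pd.DataFrame,
    geom: MotorGeometry,
    params: ImageParams | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Render a simple additive intensity image of particles on one MT.

    Each particle contributes an annulus (the AAA+ ring, outer radius
    ``head_radius``) centred at its ring position; if a ``theta_deg``
    column is present a stalk line segment is drawn from the stalkhead on
    the MT surface to the ring centre.  Rings are drawn ``n_rings_visible``
    times so superposed dimers are exactly twice as bright as monomers.
    Optional Gaussian noise of s.d. ``noise_sd`` is added last.
    """
    params = params if params is not None else ImageParams()
    img = np.zeros(params.shape, dtype=np.float32)
    px = params.pixel_size

    # MT band below its upper surface
    top = params.mt_surface_row
    bottom = min(params.shape[0], top + max(1, round(params.mt_width_nm / px)))
    img[top:bottom, :] += params.mt_intensity

    r_out = geom.head_radius / px
    r_in = params.ring_inner_fraction * r_out
    for row in particles.itertuples(index=False):
        col = float(row.axial_x_nm) / px
        rr = top - float(row.ring_height_nm) / px
        weight = int(getattr(row, "n_rings_visible", 1))
        ro, co = disk((rr, col), r_out, shape=params.shape)
        ri, ci = disk((rr, col), r_in, shape=params.shape)
        ring = np.zeros(params.shape, dtype=bool)
        ring[ro, co] = True
        ring[ri, ci] = False
        img[ring] += weight * params.ring_intensity
        theta = getattr(row, "theta_deg", None)
        if theta is not None and np.isfinite(theta):
            shx = float(row.axial_x_nm) + geom.ring_to_hinge * np.cos(np.radians(theta))
            r0 = int(np.clip(top, 0, params.shape[0] - 1))
            c0 = int(np.clip(round(shx / px), 0, params.shape[1] - 1))
            r1 = int(np.clip(round(rr), 0, params.shape[0] - 1))
            c1 = int(np.clip(round(col), 0, params.shape[1] - 1))
            lr, lc = line(r0, c0, r1, c1)
            img[lr, lc] += weight * params.stalk_intensity
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, params.noise_sd, params.shape).astype(np.float32)
    return img


def simulate_runs(
    duty_ratio: float,
    step_nm: float,
    n_runs: int,
    seed: int,
) -> np.ndarray:
    """Stochastic run lengths for a two-headed motor with independent heads.

    Per mechanical cycle the run terminates if both heads are detached
    simultaneously, probability (1 - r)^2; otherwise it completes one step.
    The number of completed cycles is geometric and the run length is that
    count times ``step_nm``.
    """
    if not 0.0 < duty_ratio < 1.0:
        raise ValueError("duty_ratio must lie strictly in (0, 1)")
    if step_nm <= 0 or n_runs < 1:
        raise ValueError("need step_nm > 0 and n_runs >= 1")
    p_term = (1.0 - duty_ratio) ** 2
    rng = np.random.default_rng(seed)
    cycles = rng.geometric(p_term, n_runs) - 1  # completed cycles before failure
    return cycles.astype(float) * step_nm
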
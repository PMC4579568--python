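"""Trigonometric deduction of stalk angles and stalkhead positions.

The motor flexes as a rigid body about a hinge at the stalk-stalkhead
junction, which sits close to the microtubule surface.  Because the
distance from the ring centre to that hinge is constant, the measured
perpendicular height of the ring centre above the MT surface determines
the stalk angle,

    theta = arcsin((ring_height - hinge_height) / ring_to_hinge),

and the stalk angle in turn predicts where the stalkhead binds the MT,
minus-end-ward of the ring:

    stalkhead_x = ring_x + ring_to_hinge * cos(theta).

Angles are in degrees at every interface (radians appear only inside the
formulas); axial positions are in nm, positive toward the MT minus end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "GeometryError",
    "MotorGeometry",
    "stalk_angle",
    "stalkhead_x",
    "dimer_separations",
    "measure_particle_table",
]


class GeometryError(ValueError):
    """Raised when a measurement is incompatible with the rigid-body model."""


@dataclass(frozen=True)
class MotorGeometry:
    """Rigid-body dimensions of one motor (nm).

    ``ring_to_hinge`` is the measured distance from the AAA+ ring centre to
    the stalk-stalkhead hinge; subtracting the ring (head) radius gives the
    ``lever_length`` used in the stiffness formulas, i.e. the distance from
    the hinge to the base of the stalk where the linker ends.
    ``hinge_height`` is the height of the hinge above the MT surface; it is
    not directly measurable in projection and is inferred from the mean ring
    height and mean stalk angle (14.4 - 18.8*sin 42 deg ~= 1.8 nm).
    """

    ring_to_hinge: float = 18.8
    head_radius: float = 6.5
    lever_length: float = 12.3
    hinge_height: float = 1.8

    def __post_init__(self) -> None:
        for name in ("ring_to_hinge", "head_radius", "lever_length", "hinge_height"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        expected = self.ring_to_hinge - self.head_radius
        if abs(self.lever_length - expected) > 1e-6:
            raise GeometryError(
                "lever_length must equal ring_to_hinge - head_radius "
                f"({expected:g} nm, got {self.lever_length:g} nm)"
            )


def _as_array(x: Any) -> tuple[np.ndarray, bool]:
    arr = np.asarray(x, dtype=float)
    return arr, arr.ndim == 0


def stalk_angle(
    ring_height: Any,
    geom: MotorGeometry | None = None,
    *,
    clamp_tol: float = 0.02,
    return_clamped: bool = False,
):
    """Stalk angle (degrees, in (0, 90]) from the ring-centre height.

    Measurement noise can push the arcsin argument marginally above 1; values
    in (1, 1 + clamp_tol] are clamped to 90 degrees and flagged, larger
    values raise :class:`GeometryError`.  Heights at or below the hinge also
    raise.  Accepts scalars or arrays.

    Returns the angle, or ``(angle, clamped)`` if ``return_clamped``.
    """
    geom = geom if geom is not None else MotorGeometry()
    h, scalar = _as_array(ring_height)
    arg = (h - geom.hinge_height) / geom.ring_to_hinge
    if np.any(arg <= 0):
        raise GeometryError("ring_height must exceed hinge_height")
    if np.any(arg > 1.0 + clamp_tol):
        raise GeometryError(
            "ring_height exceeds hinge_height + ring_to_hinge beyond the "
            f"clamp tolerance ({clamp_tol:g})"
        )
    clamped = arg > 1.0
    theta = np.degrees(np.arcsin(np.minimum(arg, 1.0)))
    if scalar:
        theta, clamped = float(theta), bool(clamped)
    if return_clamped:
        return theta, clamped
    return theta


def stalkhead_x(ring_x: Any, theta: Any, geom: MotorGeometry | None = None):
    """Predicted stalkhead axial position (nm) from the ring position.

    The stalkhead lies minus-end-ward of the ring by ``ring_to_hinge *
    cos(theta)``.  ``theta`` must be in (0, 90] degrees.
    """
    geom = geom if geom is not None else MotorGeometry()
    x, sx = _as_array(ring_x)
    th, st = _as_array(theta)
    if np.any(th <= 0) or np.any(th > 90):
        raise GeometryError("theta must lie in (0, 90] degrees")
    out = x + geom.ring_to_hinge * np.cos(np.radians(th))
    return float(out) if (sx and st) else out


def dimer_separations(leading: Any, trailing: Any) -> tuple[float, float]:
    """Stalkhead and ring separations (nm) of a role-assigned dimer.

    ``leading`` and ``trailing`` are mappings (dict, Series, dataclass with
    attributes) exposing ``stalkhead_x`` and ``ring_x``.  The stalkhead
    separation is non-negative by the role definition; the ring separation
    is signed and is negative exactly when the stalks cross.
    """

    def get(m: Any, key: str) -> float:
        if hasattr(m, "get"):
            v = m.get(key, None)
            if v is None:
                raise GeometryError(f"motor lacks '{key}'; assign roles first")
            return float(v)
        if hasattr(m, key):
            return float(getattr(m, key))
        raise GeometryError(f"motor lacks '{key}'; assign roles first")

    sh = get(leading, "stalkhead_x") - get(trailing, "stalkhead_x")
    if sh < 0:
        raise GeometryError(
            "leading stalkhead is behind trailing stalkhead; roles misassigned"
        )
    ring = get(leading, "ring_x") - get(trailing, "ring_x")
    return float(sh), float(ring)


def measure_particle_table(
    particles: pd.DataFrame,
    geom: MotorGeometry | None = None,
    *,
    clamp_tol: float = 0.02,
    on_invalid: str = "raise",
) -> pd.DataFrame:
    """Annotate a particle table with deduced stalk angle and stalkhead
    position.

    Adds ``theta_deg``, ``stalkhead_x_nm`` and ``clamped`` columns computed
    from ``ring_height_nm`` and ``axial_x_nm`` (the ring-centre axial
    position).  Returns a copy; row order is preserved.

    ``on_invalid`` controls rows whose height is outside the rigid-body
    range (at or below the hinge, or above hinge + ring_to_hinge beyond the
    clamp tolerance): ``"raise"`` (default) or ``"drop"`` — measurement
    noise makes a small fraction of real particles unmeasurable and an
    analysis pipeline silently has to discard them.
    """
    geom = geom if geom is not None else MotorGeometry()
    out = particles.copy()
    if on_invalid not in ("raise", "drop"):
        raise GeometryError("on_invalid must be 'raise' or 'drop'")
    if on_invalid == "drop":
        arg = (out["ring_height_nm"].to_numpy() - geom.hinge_height) / geom.ring_to_hinge
        out = out.loc[(arg > 0) & (arg <= 1.0 + clamp_tol)].reset_index(drop=True)
    theta, clamped = stalk_angle(
        out["ring_height_nm"].to_numpy(), geom,
        clamp_tol=clamp_tol, return_clamped=True,
    )
    out["theta_deg"] = theta
    out["stalkhead_x_nm"] = stalkhead_x(out["axial_x_nm"].to_numpy(), theta, geom)
    out["clamped"] = clamped
    return out
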
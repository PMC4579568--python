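"""Microtubule binding-site lattice.

A 14-protofilament, 3-start (14_3) GMPCPP-stabilised microtubule presents a
regular lattice of motor binding sites: tubulin dimers repeat every 8.3 nm
along a protofilament, adjacent protofilaments are staggered axially by
0.9 nm in a left-handed helix, and the two protofilaments flanking the
lattice seam are offset by a further ~4 nm.  Every allowed axial separation
between the track-binding stalkheads of a two-headed motor is therefore a
small integer combination of these three lengths.

All axial coordinates are in nm.  The sign convention, shared by every
module in this package, is positive toward the microtubule minus end, i.e.
the stepping direction of dynein.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LatticeError", "LatticeParams", "site_axial_offset", "separation_classes"]


class LatticeError(ValueError):
    """Raised for lattice parameters or site indices that are not physical."""


@dataclass(frozen=True)
class LatticeParams:
    """Geometry of the microtubule binding-site lattice.

    Parameters
    ----------
    axial_repeat
        Axial spacing of binding sites along one protofilament (nm).  One
        site per alpha/beta-tubulin dimer.
    pf_stagger
        Axial stagger between adjacent protofilaments (nm), left-handed.
    n_protofilaments
        Number of protofilaments around the microtubule.
    seam_extra_offset
        Additional axial offset across the lattice seam (nm).
    helix_start
        Helix start number (3 for the 14_3 lattice).  Recorded for
        provenance; the axial arithmetic does not use it.
    """

    axial_repeat: float = 8.3
    pf_stagger: float = 0.9
    n_protofilaments: int = 14
    seam_extra_offset: float = 4.0
    helix_start: int = 3

    def __post_init__(self) -> None:
        if self.axial_repeat <= 0:
            raise LatticeError("axial_repeat must be positive")
        if not 0 <= self.pf_stagger < self.axial_repeat:
            raise LatticeError("pf_stagger must lie in [0, axial_repeat)")
        if self.n_protofilaments < 10:
            raise LatticeError("n_protofilaments must be >= 10")


def site_axial_offset(
    dimer_steps: int,
    pf_steps: int,
    crosses_seam: bool = False,
    params: LatticeParams | None = None,
) -> float:
    """Axial offset (nm) between two binding sites on the lattice.

    ``dimer_steps`` counts tubulin-dimer repeats along a protofilament and
    ``pf_steps`` counts protofilament changes (each contributing one
    stagger).  If the path between the two sites crosses the lattice seam,
    the seam offset is added once.  Positive values point toward the
    microtubule minus end.
    """
    params = params if params is not None else LatticeParams()
    if abs(pf_steps) >= params.n_protofilaments:
        raise LatticeError(
            f"|pf_steps| = {abs(pf_steps)} must be < n_protofilaments = "
            f"{params.n_protofilaments}"
        )
    offset = dimer_steps * params.axial_repeat + pf_steps * params.pf_stagger
    if crosses_seam:
        offset += params.seam_extra_offset
    return float(offset)


def separation_classes(
    max_dimer_steps: int, params: LatticeParams | None = None
) -> np.ndarray:
    """Distinct stalkhead separations reachable on or between adjacent
    protofilaments, away from the seam.

    Enumerates ``dimer_steps`` in ``0..max_dimer_steps`` and ``pf_steps`` in
    {0, 1} and returns the sorted unique axial offsets (nm).  With the
    default lattice this yields the observed separation classes
    0.9, 8.3, 16.6 and 24.9 nm (plus their stagger companions).
    """
    params = params if params is not None else LatticeParams()
    if max_dimer_steps < 0:
        raise LatticeError("max_dimer_steps must be >= 0")
    offsets = {
        round(site_axial_offset(d, p, False, params), 9)
        for d in range(max_dimer_steps + 1)
        for p in (0, 1)
    }
    return np.array(sorted(offsets), dtype=float)
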
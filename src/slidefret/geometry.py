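"""Filament/duplex geometry and the distance -> FRET coupling.

The physical picture: a RecA filament assembled on a ssDNA overhang is a
rigid rod along which the register coordinate ``x`` (in nucleotides from
the ssDNA/dsDNA junction toward the free filament end) locates dyes and
the sliding duplex.  RecA stretches DNA to a rise of 5.1 A per nucleotide,
so an axial register separation of ``|x - x0|`` nt maps to
``d * |x - x0|`` Angstrom, combined in quadrature with a fixed lateral
dye offset ``r``:

    L = sqrt(r**2 + (d * |x - x0|)**2)

FRET efficiency then follows the Forster relation E = 1 / (1 + (L/R0)**6).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Rise per nucleotide along a RecA-stretched filament, Angstrom.
STRETCHED_RISE_A = 5.1
#: Rise per base pair of B-form dsDNA, Angstrom (3.4 A = 0.34 nm).
BDNA_RISE_A = 3.4
#: Stretching factor of RecA-bound DNA relative to B-form (5.1 / 3.4).
RECA_STRETCH = 1.5


@dataclass
class FilamentGeometry:
    """Lengths and label positions of the filament / duplex assembly.

    Parameters
    ----------
    filament_length : float
        Length of the RecA-coated ssDNA in nucleotides.
    duplex_length : float
        Length of the incoming dsDNA in base pairs.
    rise_per_residue : float
        Axial rise per nucleotide along the stretched filament, Angstrom.
    acceptor_positions : sequence of float
        Register coordinates (nt from the junction) of the acceptor dye(s)
        on the filament.  One entry for two-color, two for three-color.
    donor_position : float or None
        Position of the donor within the duplex, bp from the duplex end
        that leads toward the junction (0 = labeled at that end).  The
        default (None) labels the far end (``duplex_length``), which
        keeps the high-FRET configuration at the boundary of the sliding
        range for every filament length.
    lateral_offset_r : float
        Perpendicular dye offset, Angstrom (filament radius plus linkers).
    """

    filament_length: float
    duplex_length: float
    rise_per_residue: float = STRETCHED_RISE_A
    acceptor_positions: Sequence[float] = (0.0,)
    donor_position: Optional[float] = None
    lateral_offset_r: float = 20.0

    def __post_init__(self) -> None:
        if self.filament_length <= 0:
            raise ValueError("filament_length must be > 0")
        if self.duplex_length <= 0:
            raise ValueError("duplex_length must be > 0")
        if self.rise_per_residue <= 0:
            raise ValueError("rise_per_residue must be > 0")
        if self.lateral_offset_r < 0:
            raise ValueError("lateral_offset_r must be >= 0")
        if self.donor_position is None:
            self.donor_position = float(self.duplex_length)
        self.acceptor_positions = tuple(float(a) for a in self.acceptor_positions)
        if not self.acceptor_positions:
            raise ValueError("at least one acceptor position required")
        for a in self.acceptor_positions:
            if not 0 <= a <= self.filament_length:
                raise ValueError(
                    f"acceptor position {a} outside [0, {self.filament_length}]"
                )


@dataclass
class FretCoupling:
    """Static Forster coupling for one donor-acceptor pair."""

    forster_radius: float = 56.0  # Angstrom; Cy3/Cy5-like default

    def __post_init__(self) -> None:
        if self.forster_radius <= 0:
            raise ValueError("forster_radius must be > 0")


#: Typical far-red (Cy3/Cy7-like) pair, used as acceptor-2 default.
FAR_RED_COUPLING = FretCoupling(forster_radius=38.0)


def register_to_distance(x, x0, geometry: FilamentGeometry):
    """Dye separation (Angstrom) between register coordinates ``x`` and ``x0``.

    Symmetric in its two arguments and never smaller than the lateral
    offset ``r``.  Accepts scalars or arrays.
    """
    d = geometry.rise_per_residue
    r = geometry.lateral_offset_r
    axial = d * np.abs(np.asarray(x, dtype=float) - x0)
    return np.sqrt(r * r + axial * axial)


def fret_from_distance(L, coupling: FretCoupling):
    """Forster efficiency E = 1 / (1 + (L/R0)**6) at separation ``L`` (A)."""
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("distance must be >= 0")
    ratio6 = (L / coupling.forster_radius) ** 6
    out = 1.0 / (1.0 + ratio6)
    return float(out) if out.ndim == 0 else out


def diffusion_um2_to_bp2(d_um2: float, rise_nm: float = 0.34) -> float:
    """Convert a diffusion coefficient from um^2/s to bp^2/s.

    ``rise_nm`` is the length of one base pair in nm: 0.34 for B-form
    dsDNA (the convention behind the ~7700 bp^2/s figure), 0.51 for the
    stretched filament register.
    """
    if d_um2 < 0:
        raise ValueError("D must be >= 0")
    if rise_nm <= 0:
        raise ValueError("rise must be > 0")
    return d_um2 * 1e6 / rise_nm**2


def diffusion_bp2_to_um2(d_bp2: float, rise_nm: float = 0.34) -> float:
    """Inverse of :func:`diffusion_um2_to_bp2`."""
    if d_bp2 < 0:
        raise ValueError("D must be >= 0")
    if rise_nm <= 0:
        raise ValueError("rise must be > 0")
    return d_bp2 * rise_nm**2 / 1e6


def stretched_span(n: float, b_rise: float = BDNA_RISE_A,
                   stretch: float = RECA_STRETCH) -> float:
    """Physical span (Angstrom) of ``n`` nucleotides on the stretched filament.

    ``n * b_rise * stretch``; with the defaults one nucleotide spans
    3.4 A x 1.5 = 5.1 A.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    return n * b_rise * stretch
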
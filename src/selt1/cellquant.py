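"""Cell-level quantification arithmetic for in-cell NMR sample preparation.

Small closed-form calculators used to interpret the in-cell measurements:

* spherical cell and nuclear volumes from microscopy diameters;
* the nuclear share of cell volume and of total fluorescence signal;
* the interstitial-medium fraction of a cell pellet;
* sequential-wash carryover dilution (how much transfection medium remains
  around the cells after washing);
* denaturing-PAGE standard-curve fitting and the intracellular
  concentration of transfected DNA from the labelled fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CellGeometry",
    "WashProtocol",
    "GelStandard",
    "sphere_volume",
    "nuclear_volume_fraction",
    "nuclear_signal_fraction",
    "interstitial_fraction",
    "washout_concentration",
    "fit_standard_curve",
    "StandardCurveFit",
    "intracellular_concentration",
]


@dataclass(frozen=True)
class CellGeometry:
    """Microscopy-derived diameters (um) of cell and nucleus."""

    cell_diameter: float
    nuclear_diameter: float
    n_measured: int = 10

    def __post_init__(self):
        if not 0 < self.nuclear_diameter <= self.cell_diameter:
            raise ValueError("need 0 < nuclear_diameter <= cell_diameter")


@dataclass(frozen=True)
class WashProtocol:
    """Sequential-wash dilution protocol after electroporation.

    The pellet retains a fixed carryover volume of medium between washes:
    carryover = pellet_volume - cell_count * per_cell_volume. After each wash
    of volume V the retained concentration is multiplied by
    carryover / (V + carryover); the final supernatant after resuspension is
    diluted once more into (final_resuspension + carryover).
    """

    initial_conc: float          # uM
    pellet_volume: float         # mL
    cell_count: float
    per_cell_volume: float       # pL
    wash_volumes: tuple = ()     # mL each
    final_resuspension: float = 0.6  # mL

    def __post_init__(self):
        if min(self.initial_conc, self.pellet_volume, self.per_cell_volume,
               self.final_resuspension) <= 0 or self.cell_count < 0:
            raise ValueError("volumes and concentration must be positive")
        if any(v < 0 for v in self.wash_volumes):
            raise ValueError("wash volumes must be >= 0")
        if self.carryover <= 0:
            raise ValueError("cell volume exceeds pellet volume")

    @property
    def carryover(self) -> float:
        """Interstitial medium volume of the pellet (mL)."""
        return self.pellet_volume - self.cell_count * self.per_cell_volume * 1e-9


@dataclass(frozen=True)
class GelStandard:
    """Fluorescent standard-curve points from a denaturing PAGE.

    ``points`` are (quantity pmol, signal) pairs; ``label_ratio`` is the
    unlabelled:labelled multiplier (40 for the 2.5% labelled preparation);
    ``background`` is the autofluorescence signal already subtracted from
    sample lanes.
    """

    points: tuple
    label_fraction: float = 0.025
    label_ratio: float = 40.0
    background: float = 0.0

    def __post_init__(self):
        if len(self.points) < 3:
            raise ValueError("need >= 3 standard points")
        if any(q <= 0 for q, _ in self.points):
            raise ValueError("standard quantities must be positive")


def sphere_volume(diameter_um: float) -> float:
    """Volume of a sphere of the given diameter (um), in pL.

    (pi/6) d^3 um^3; 1 pL = 1000 um^3.
    """
    if diameter_um < 0:
        raise ValueError("diameter must be >= 0")
    return math.pi / 6.0 * diameter_um**3 / 1000.0


def nuclear_volume_fraction(geom: CellGeometry) -> float:
    """Nuclear share of the cell volume in percent: 100*(d_nuc/d_cell)^3."""
    return 100.0 * (geom.nuclear_diameter / geom.cell_diameter) ** 3


def nuclear_signal_fraction(conc_ratio_nuc: float, conc_ratio_cyt: float,
                            volume_fraction: float) -> float:
    """Nuclear share of total signal in percent.

    ``conc_ratio_nuc:conc_ratio_cyt`` is the nuclear:cytoplasmic
    concentration ratio (e.g. 65:35) and ``volume_fraction`` the nuclear
    volume share as a fraction in (0, 1).
    """
    if conc_ratio_nuc <= 0 or conc_ratio_cyt <= 0:
        raise ValueError("concentration ratio parts must be positive")
    if not 0 < volume_fraction < 1:
        raise ValueError("volume_fraction must be in (0, 1)")
    nuc = conc_ratio_nuc * volume_fraction
    cyt = conc_ratio_cyt * (1.0 - volume_fraction)
    return 100.0 * nuc / (nuc + cyt)


def interstitial_fraction(pellet_volume_ml: float, cell_count: float,
                          per_cell_volume_pl: float) -> float:
    """Percent of the pellet volume that is medium rather than cells."""
    cells_ml = cell_count * per_cell_volume_pl * 1e-9
    if cells_ml > pellet_volume_ml:
        raise ValueError("total cell volume exceeds the pellet volume")
    return 100.0 * (pellet_volume_ml - cells_ml) / pellet_volume_ml


def washout_concentration(protocol: WashProtocol) -> float:
    """Residual extracellular concentration (uM) after the wash protocol.

    Each wash dilutes the retained carryover into the wash volume; the final
    resuspension dilutes once more, and the reported value is the
    concentration in the final supernatant (resuspension + carryover).
    """
    conc = protocol.initial_conc
    carry = protocol.carryover
    for v in protocol.wash_volumes:
        conc *= carry / (v + carry)
    return conc * carry / (protocol.final_resuspension + carry)


@dataclass(frozen=True)
class StandardCurveFit:
    slope: float       # signal per pmol
    intercept: float
    r_squared: float
    n_used: int

    def quantity(self, signal: float) -> float:
        """Invert the curve: pmol for a background-subtracted signal."""
        return (signal - self.intercept) / self.slope


def fit_standard_curve(standard: GelStandard,
                       saturation_threshold: float | None = None) -> StandardCurveFit:
    """Ordinary least-squares line signal = slope*quantity + intercept.

    Points at or above ``saturation_threshold`` pmol are excluded first
    (detector saturation outside the linear range); at least three usable
    points must remain.
    """
    pts = [(q, s) for q, s in standard.points
           if saturation_threshold is None or q < saturation_threshold]
    if len(pts) < 3:
        raise ValueError("fewer than 3 usable standard points after "
                         "saturation exclusion")
    q = np.array([p[0] for p in pts])
    s = np.array([p[1] for p in pts])
    res = stats.linregress(q, s)
    return StandardCurveFit(slope=float(res.slope),
                            intercept=float(res.intercept),
                            r_squared=float(res.rvalue**2), n_used=len(pts))


def intracellular_concentration(labelled_quantity_pmol: float,
                                standard: GelStandard,
                                cell_count: float,
                                per_cell_volume_pl: float,
                                strict_total: bool = False) -> float:
    """Intracellular DNA concentration (uM) from the labelled quantity.

    The total DNA is the labelled quantity times the unlabelled:labelled
    ratio (x40 by default, matching the published convention; with
    ``strict_total`` the labelled share itself is included, x41), divided by
    the total cell volume. 1 pmol / 1 uL = 1 uM.
    """
    if labelled_quantity_pmol < 0:
        raise ValueError("labelled quantity must be >= 0")
    if cell_count <= 0 or per_cell_volume_pl <= 0:
        raise ValueError("cell count and volume must be positive")
    multiplier = standard.label_ratio + (1.0 if strict_total else 0.0)
    total_pmol = labelled_quantity_pmol * multiplier
    volume_ul = cell_count * per_cell_volume_pl * 1e-6
    return total_pmol / volume_ul
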
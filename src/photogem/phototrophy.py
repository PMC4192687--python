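"""Cell-geometry photon budget.

A rod-shaped cyanobacterium is idealised as a prolate spheroid; the
theoretical ceiling on photon uptake is the light flux through its
surface, per gram dry weight:

    bound = area(m^2) / dry_weight(g) * irradiance(mE m^-2 s^-1) * 3600 * f

with f an optional photoperiod fraction (default 1, i.e. continuous
illumination).  The result is in mE gDW^-1 h^-1 — numerically
commensurate with metabolic fluxes since 1 mE = 1 mmol photons.  The
budget is a plausibility ceiling for the photon exchange bounds; the
photoautotrophic simulation itself *minimizes* photon uptake, so
applying the bound is the caller's choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .model_core import ModelError

_UM2_TO_M2 = 1e-12
_NG_TO_G = 1e-9
_S_PER_H = 3600.0


@dataclass
class CellGeometry:
    """Spheroid cell dimensions and dry weight.

    length: major axis, um.  width: minor axis (both equatorial
    diameters), um.  dry_weight: ng per cell.
    """

    length: float
    width: float
    dry_weight: float

    def __post_init__(self) -> None:
        if not (self.length >= self.width > 0):
            raise ModelError(
                f"need length >= width > 0, got {self.length} x {self.width}")
        if self.dry_weight <= 0:
            raise ModelError(f"dry weight must be positive, got {self.dry_weight}")


@dataclass
class IrradianceSetting:
    """Incident light intensity, mE m^-2 s^-1, and photoperiod fraction."""

    irradiance: float
    photoperiod_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.irradiance < 0:
            raise ModelError(f"irradiance must be >= 0, got {self.irradiance}")
        if not (0 < self.photoperiod_fraction <= 1):
            raise ModelError(
                f"photoperiod fraction must be in (0, 1], got {self.photoperiod_fraction}")


#: Measured geometry of S. elongatus PCC7942 used in the autotrophic
#: growth simulation: 3.57 x 1.47 um, 3.87 ng dry weight per cell.
SYNECHOCOCCUS_GEOMETRY = CellGeometry(length=3.57, width=1.47, dry_weight=3.87)

#: Irradiance at which the highest growth rate was measured.
SYNECHOCOCCUS_IRRADIANCE = IrradianceSetting(irradiance=0.156)


def spheroid_surface_area(geometry: CellGeometry) -> float:
    """Exact prolate-spheroid surface area, um^2.

    With semi-major a = length/2 and semi-minor b = width/2 and
    eccentricity e = sqrt(1 - b^2/a^2):

        A = 2 pi b^2 (1 + a / (b e) * arcsin(e))

    The sphere limit (length = width) returns 4 pi r^2 exactly.
    """
    a = geometry.length / 2.0
    b = geometry.width / 2.0
    if a == b:
        return 4.0 * math.pi * a * a
    e = math.sqrt(1.0 - (b * b) / (a * a))
    return 2.0 * math.pi * b * b * (1.0 + a / (b * e) * math.asin(e))


def max_photon_uptake(geometry: CellGeometry, light: IrradianceSetting) -> float:
    """Theoretical maximum photon uptake, mE gDW^-1 h^-1.

    Linear in irradiance and photoperiod fraction, inversely
    proportional to dry weight.
    """
    area_m2 = spheroid_surface_area(geometry) * _UM2_TO_M2
    dw_g = geometry.dry_weight * _NG_TO_G
    return (area_m2 / dw_g) * light.irradiance * _S_PER_H * light.photoperiod_fraction


def photon_budget_report(geometry: CellGeometry, light: IrradianceSetting) -> dict:
    """Area, area per gDW and the uptake bound as a JSON-ready dict."""
    area_um2 = spheroid_surface_area(geometry)
    area_per_g = area_um2 * _UM2_TO_M2 / (geometry.dry_weight * _NG_TO_G)
    return {
        "surface_area_um2": area_um2,
        "surface_area_m2_per_gDW": area_per_g,
        "max_photon_uptake_mE_per_gDW_h": max_photon_uptake(geometry, light),
        "irradiance_mE_per_m2_s": light.irradiance,
        "photoperiod_fraction": light.photoperiod_fraction,
    }
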
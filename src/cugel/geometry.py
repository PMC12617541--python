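"""Coated copper element geometry and pH-dependent deformation.

The device is reduced to a cylindrical copper sleeve carrying an annular gel
coating, sitting in a closed, well-mixed fluid compartment. Raising the pH
deforms the coating anisotropically: a polyacid gel (PAAm) swells in both
directions; a polybasic gel (chitosan) shrinks, and its axial contraction
leaves a fraction of the copper surface directly exposed to the fluid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .swelling import DimensionalChange

__all__ = [
    "GelMaterial",
    "AdsorptionParams",
    "DeviceGeometry",
    "DeformedGeometry",
    "ConfigurationError",
    "deform",
    "sweep_thicknesses",
    "copper_area",
    "REFERENCE_PH",
]

#: All deformations are expressed relative to this pH.
REFERENCE_PH = "4"


class ConfigurationError(ValueError):
    """A material/geometry configuration is inconsistent or incomplete."""


@dataclass(frozen=True)
class AdsorptionParams:
    """Linear reversible Cu2+ sorption in the gel phase.

    ``partition`` is the dimensionless ratio of sorbed to free concentration
    at equilibrium (instantaneous linear isotherm; acts as a retardation
    factor 1 + partition on transport). ``capacity`` bounds the regime in
    which the linear isotherm is meaningful, mol per m3 of gel.
    """

    capacity: float      # mol/m3
    partition: float     # dimensionless

    def __post_init__(self) -> None:
        if self.capacity <= 0:
            raise ValueError("adsorption capacity must be positive")
        if self.partition < 0:
            raise ValueError("partition constant must be nonnegative")


@dataclass
class GelMaterial:
    """Per-material transport and deformation parameters.

    Attributes
    ----------
    name : str
    diffusivity_by_ph : dict
        pH label -> Cu2+ diffusion coefficient in the gel, m2/s.
    deformation_by_ph : dict
        pH label -> DimensionalChange relative to pH 4. The reference pH
        must map to (0, 0).
    adsorption : AdsorptionParams or None
        Linear sorption, active at the pH labels in ``adsorption_ph``.
    degradation_rate : float
        First-order mass-loss rate, 1/day (information only over the 8-h
        release horizon).
    """

    name: str
    diffusivity_by_ph: dict[str, float]
    deformation_by_ph: dict[str, DimensionalChange]
    adsorption: AdsorptionParams | None = None
    adsorption_ph: frozenset[str] = frozenset()
    degradation_rate: float = 0.0

    def __post_init__(self) -> None:
        self.diffusivity_by_ph = {str(k): float(v)
                                  for k, v in self.diffusivity_by_ph.items()}
        self.deformation_by_ph = {str(k): v
                                  for k, v in self.deformation_by_ph.items()}
        for ph, d in self.diffusivity_by_ph.items():
            if d <= 0:
                raise ConfigurationError(
                    f"{self.name}: diffusivity at pH {ph} must be positive")
        ref = self.deformation_by_ph.get(REFERENCE_PH)
        if ref is None or ref.axial_percent != 0 or ref.radial_percent != 0:
            raise ConfigurationError(
                f"{self.name}: deformation at reference pH {REFERENCE_PH} "
                "must be present and (0, 0)")
        self.adsorption_ph = frozenset(str(p) for p in self.adsorption_ph)

    def diffusivity(self, ph: str) -> float:
        try:
            return self.diffusivity_by_ph[str(ph)]
        except KeyError:
            raise ConfigurationError(
                f"{self.name}: no diffusivity for pH {ph}") from None

    def adsorbs_at(self, ph: str) -> bool:
        return self.adsorption is not None and str(ph) in self.adsorption_ph


@dataclass
class DeviceGeometry:
    """Copper sleeve with annular gel coating in a closed fluid compartment.

    All lengths in m, volume in m3. The sleeve lateral area 2*pi*r*L is the
    copper release area and must match the ReleaseSpec area the scenario
    uses (checked by the pipeline).
    """

    sleeve_radius: float
    sleeve_length: float
    gel_thickness_ph4: float
    fluid_volume: float

    SUPPORTED_THICKNESS_M = (0.5e-3, 3.0e-3)

    def __post_init__(self) -> None:
        for name in ("sleeve_radius", "sleeve_length",
                     "gel_thickness_ph4", "fluid_volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.SUPPORTED_THICKNESS_M
        if not lo <= self.gel_thickness_ph4 <= hi:
            raise ConfigurationError(
                f"gel_thickness_ph4={self.gel_thickness_ph4 * 1e3:.3g} mm "
                f"outside supported range [{lo * 1e3}, {hi * 1e3}] mm")


@dataclass(frozen=True)
class DeformedGeometry:
    """Geometry after applying a pH's equilibrium deformation.

    ``exposed_fraction`` is the part of the copper sleeve left uncovered
    when the gel's axial length falls below the sleeve length.
    """

    gel_thickness: float   # m
    gel_length: float      # m
    exposed_fraction: float
    ph: str
    sleeve_radius: float = field(default=0.0)
    sleeve_length: float = field(default=0.0)

    @property
    def covered_length(self) -> float:
        return min(self.gel_length, self.sleeve_length)


def deform(geom: DeviceGeometry, material: GelMaterial, ph: str) -> DeformedGeometry:
    """Apply a material's equilibrium deformation at a pH to the geometry.

    Thickness scales with the radial variation, length with the axial one;
    deformation is an instantaneous equilibrium state relative to the pH-4
    reference. Applies from the reference state only (not composable).
    """
    ph = str(ph)
    dc = material.deformation_by_ph.get(ph)
    if dc is None:
        raise ConfigurationError(f"{material.name}: no deformation entry for pH {ph}")
    radial_scale = 1.0 + dc.radial_percent / 100.0
    axial_scale = 1.0 + dc.axial_percent / 100.0
    if radial_scale <= 0 or axial_scale <= 0:
        raise ValueError(
            f"{material.name} at pH {ph}: deformation collapses the gel")
    gel_length = geom.sleeve_length * axial_scale
    exposed = max(0.0, 1.0 - gel_length / geom.sleeve_length)
    return DeformedGeometry(
        gel_thickness=geom.gel_thickness_ph4 * radial_scale,
        gel_length=gel_length,
        exposed_fraction=exposed,
        ph=ph,
        sleeve_radius=geom.sleeve_radius,
        sleeve_length=geom.sleeve_length,
    )


def sweep_thicknesses(min_mm: float, max_mm: float, pitch_mm: float) -> list[float]:
    """Inclusive arithmetic sequence of coating thicknesses, mm.

    The endpoint is included when (max - min) is an integer multiple of the
    pitch to within 1e-9.
    """
    if pitch_mm <= 0:
        raise ValueError(f"pitch must be positive, got {pitch_mm}")
    if min_mm > max_mm:
        raise ValueError(f"min ({min_mm}) must not exceed max ({max_mm})")
    n_steps = (max_mm - min_mm) / pitch_mm
    n = int(math.floor(n_steps + 1e-9))
    return [min_mm + i * pitch_mm for i in range(n + 1)]


def copper_area(geom: DeviceGeometry) -> float:
    """Lateral area of the copper sleeve, 2*pi*r*L (end caps ignored), m2."""
    return 2.0 * np.pi * geom.sleeve_radius * geom.sleeve_length
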
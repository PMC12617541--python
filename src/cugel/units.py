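"""Unit-safe copper-release arithmetic.

Connects the device-level release figure (micrograms of Cu per day) to the
molar surface flux used as the corrosion boundary condition, and converts
mole ledgers to the molar concentrations reported for the fluid compartment.

All computation is SI internally (m, s, mol, m3); user-facing quantities are
converted at the call boundary (ug/day in, mol/L out).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "COPPER_MOLAR_MASS",
    "CopperConstants",
    "ReleaseSpec",
    "rate_to_flux",
    "cumulative_injected",
    "moles_to_concentration",
]

#: Standard atomic weight of copper, g/mol.
COPPER_MOLAR_MASS = 63.546

SECONDS_PER_DAY = 86_400.0


@dataclass(frozen=True)
class CopperConstants:
    """Physical constants for copper. Immutable."""

    molar_mass: float = COPPER_MOLAR_MASS  # g/mol

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError("molar_mass must be positive")


def rate_to_flux(daily_release_ug: float, copper_area_m2: float,
                 molar_mass: float = COPPER_MOLAR_MASS) -> float:
    """Convert a daily mass release to a molar surface flux.

    Parameters
    ----------
    daily_release_ug : float
        Copper release rate in ug/day.
    copper_area_m2 : float
        Exposed copper surface area in m2.

    Returns
    -------
    float
        Outgoing ion flux J in mol/(m2 s). For the reference device
        (50 ug/day over 200 mm2) this is 4.55e-8 mol/(m2 s).
    """
    if daily_release_ug <= 0:
        raise ValueError(f"daily_release must be positive, got {daily_release_ug}")
    if copper_area_m2 <= 0:
        raise ValueError(f"copper_area must be positive, got {copper_area_m2}")
    mol_per_s = daily_release_ug * 1e-6 / molar_mass / SECONDS_PER_DAY
    return mol_per_s / copper_area_m2


def cumulative_injected(flux: float, copper_area_m2: float, duration_s: float) -> float:
    """Total moles injected by a constant surface flux over a duration.

    Pure product J * A * t; the mass-balance ledger of the transport solver
    is checked against this closed form.
    """
    for name, v in (("flux", flux), ("copper_area", copper_area_m2),
                    ("duration", duration_s)):
        if v < 0:
            raise ValueError(f"{name} must be nonnegative, got {v}")
    return flux * copper_area_m2 * duration_s


def moles_to_concentration(amount_mol: float, volume_m3: float) -> float:
    """Convert a mole amount in a well-mixed volume to molarity (mol/L)."""
    if volume_m3 <= 0:
        raise ValueError(f"volume must be positive, got {volume_m3}")
    if amount_mol < 0:
        raise ValueError(f"amount must be nonnegative, got {amount_mol}")
    return amount_mol / (volume_m3 * 1e3)


@dataclass
class ReleaseSpec:
    """Copper corrosion source: daily release, copper area, derived flux.

    The flux is the dependent quantity and is recomputed whenever either
    input changes; assigning to ``flux`` directly is rejected.

    Attributes
    ----------
    daily_release : float
        Average ion release, ug/day (device-level figure).
    copper_area : float
        Copper surface area, m2.
    flux : float
        Derived outgoing molar flux, mol/(m2 s); read-only.
    """

    daily_release: float  # ug/day
    copper_area: float    # m2
    _flux: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._recompute()

    def _recompute(self) -> None:
        object.__setattr__(
            self, "_flux", rate_to_flux(self.daily_release, self.copper_area))

    def __setattr__(self, name: str, value) -> None:
        if name == "flux":
            raise AttributeError("flux is derived; set daily_release or copper_area")
        object.__setattr__(self, name, value)
        if name in ("daily_release", "copper_area") and hasattr(self, "_flux"):
            self._recompute()

    @property
    def flux(self) -> float:
        """Outgoing molar flux J, mol/(m2 s)."""
        return self._flux

    def injected(self, duration_s: float) -> float:
        """Moles released over ``duration_s`` seconds."""
        return cumulative_injected(self.flux, self.copper_area, duration_s)
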
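"""Seeded generators emulating the wet-lab measurements.

Every pipeline stage can be exercised without experimental data: the
generators produce gel mass/caliper/assay readouts with the statistical
structure the analysis assumes — triplicates, plateau kinetics, per-material
equilibrium targets and replicate noise on the 24-h relative mass change.

Streams are independent: a single global seed fans out to named substreams,
so adding a generator does not perturb existing ones, and identical
configurations are byte-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .geometry import ConfigurationError
from .swelling import DimensionalChange, MassTimeSeries

__all__ = [
    "SyntheticConfig",
    "AssayCalibration",
    "gen_mass_series",
    "gen_caliper_series",
    "gen_degradation_series",
    "gen_cyclic_series",
    "gen_assay_readout",
    "invert_calibration",
]


@dataclass(frozen=True)
class AssayCalibration:
    """Affine colorimetric calibration: absorbance = slope * conc + intercept.

    Default slope gives ~0.45 AU at 30 uM, a typical mid-range reading for
    a plate-based copper assay; noise is additive Gaussian on absorbance.
    """

    slope: float = 1.5e4        # absorbance per M
    intercept: float = 0.05     # absorbance
    noise_sd: float = 0.005     # absorbance

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ConfigurationError("assay calibration slope must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("assay noise sd must be nonnegative")


def _default_swelling_targets() -> dict:
    # 24-h percent mass change at each pH relative to the pH-4 baseline.
    # pH-7 values are the reported triplicate means; pH 4 is near-neutral
    # for the polyacid gel and a mild gradual loss for chitosan.
    return {
        ("paam", "7"): 34.0,
        ("paam", "4"): 0.0,
        ("chitosan", "7"): -61.0,
        ("chitosan", "4"): -8.0,
    }


def _default_dimensional_targets() -> dict:
    return {
        "paam": DimensionalChange(axial_percent=27.6, radial_percent=14.1),
        "chitosan": DimensionalChange(axial_percent=-28.6, radial_percent=-18.1),
    }


def _default_degradation_targets() -> dict:
    # (first-order rate 1/day, total mass loss percent at plateau)
    return {
        "paam": (0.0, 0.0),
        "chitosan": (0.3, -30.0),
    }


def _default_noise_sd() -> dict:
    # SD of the 24-h swelling ratio across replicates, percentage points.
    return {"paam": 26.0, "chitosan": 8.0}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic measurement campaign.

    Defaults mirror the reported study conditions: triplicates, sampling at
    0/1/2/4/24 h, equilibrium swelling targets of +34% (PAAm) and -61%
    (chitosan) at pH 7 with replicate SDs of 26 and 8 percentage points,
    first-order swelling rate 0.75 1/h (95% completion near 4 h), cylinder
    mold 13 mm x 4 mm, and chitosan degradation plateauing near day 10.
    """

    seed: int = 0
    n_replicates: int = 3
    time_points_h: tuple = (0.0, 1.0, 2.0, 4.0, 24.0)
    swelling_rate_per_h: float = 0.75
    m0_mg: float = 531.0  # cylinder mold 13 mm x 4 mm at ~1 g/mL
    noise_sd_percent: dict = field(default_factory=_default_noise_sd)
    swelling_targets: dict = field(default_factory=_default_swelling_targets)
    dimensional_targets: dict = field(default_factory=_default_dimensional_targets)
    degradation_targets: dict = field(default_factory=_default_degradation_targets)
    degradation_days: tuple = (0, 1, 2, 3, 5, 7, 10, 14, 18, 21, 25)
    ref_height_mm: float = 4.0
    ref_diameter_mm: float = 13.0
    caliper_resolution_mm: float = 0.0   # 0 disables rounding; 0.05 typical
    cyclic_days: int = 4
    cyclic_drift_percent: float = 0.0
    assay_calibration: AssayCalibration = field(default_factory=AssayCalibration)

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        for mat, sd in self.noise_sd_percent.items():
            if sd < 0:
                raise ConfigurationError(f"noise sd for {mat} must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent generator for a named stream under the global seed."""
        key = zlib.crc32(stream.encode("utf8"))
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed) & 0x7FFFFFFF, key]))


def _swelling_target(cfg: SyntheticConfig, material: str, ph: str) -> float:
    key = (material.lower(), str(ph))
    try:
        return cfg.swelling_targets[key]
    except KeyError:
        raise ConfigurationError(
            f"no swelling target configured for {material} at pH {ph}") from None


def gen_mass_series(material: str, ph: str,
                    cfg: SyntheticConfig,
                    noise: bool = True) -> list[MassTimeSeries]:
    """Replicated gel-mass trajectories under one pH condition.

    Each replicate follows an exponential approach from the pH-4 baseline
    mass toward its own equilibrium; replicate noise perturbs the 24-h
    relative change (Gaussian, per-material SD), matching how the wet-lab
    campaign reports ratio mean +/- SD across triplicates.
    """
    target = _swelling_target(cfg, material, ph)
    sd = cfg.noise_sd_percent.get(material.lower(), 0.0) if noise else 0.0
    rng = cfg.rng(f"mass/{material.lower()}/{ph}")
    t = np.asarray(cfg.time_points_h, dtype=float)
    k = cfg.swelling_rate_per_h
    out = []
    for rep in range(cfg.n_replicates):
        ratio = target + (rng.normal(0.0, sd) if sd > 0 else 0.0)
        ratio = max(ratio, -95.0)  # a gel cannot lose all its mass
        m_inf = cfg.m0_mg * (1.0 + ratio / 100.0)
        masses = m_inf + (cfg.m0_mg - m_inf) * np.exp(-k * t)
        out.append(MassTimeSeries(t, masses, ph_label=str(ph),
                                  replicate_id=f"r{rep + 1}"))
    return out


def gen_caliper_series(material: str, cfg: SyntheticConfig
                       ) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """Per-replicate caliper readings: ((h4, d4), (h7, d7)) in mm.

    Noise-free defaults reproduce the anisotropic deformation targets
    exactly; setting ``caliper_resolution_mm`` emulates the 0.05 mm vernier
    quantization.
    """
    try:
        dc = cfg.dimensional_targets[material.lower()]
    except KeyError:
        raise ConfigurationError(
            f"no dimensional target configured for {material}") from None
    h4, d4 = cfg.ref_height_mm, cfg.ref_diameter_mm
    h7 = h4 * (1.0 + dc.axial_percent / 100.0)
    d7 = d4 * (1.0 + dc.radial_percent / 100.0)
    res = cfg.caliper_resolution_mm
    if res > 0:
        h4, d4, h7, d7 = (round(v / res) * res for v in (h4, d4, h7, d7))
    return [((h4, d4), (h7, d7)) for _ in range(cfg.n_replicates)]


def gen_degradation_series(material: str, cfg: SyntheticConfig,
                           noise_sd_percent: float = 0.0) -> MassTimeSeries:
    """25-day stability series at pH 4.

    Chitosan-like materials decay exponentially toward their plateau loss
    (default rate 0.3 1/day: 95% completion near day 10); stable materials
    stay constant. Optional multiplicative Gaussian noise per point.
    """
    try:
        rate, loss = cfg.degradation_targets[material.lower()]
    except KeyError:
        raise ConfigurationError(
            f"no degradation target configured for {material}") from None
    t = np.asarray(cfg.degradation_days, dtype=float)
    m_end = cfg.m0_mg * (1.0 + loss / 100.0)
    if rate > 0:
        masses = m_end + (cfg.m0_mg - m_end) * np.exp(-rate * t)
    else:
        masses = np.full_like(t, cfg.m0_mg)
    if noise_sd_percent > 0:
        rng = cfg.rng(f"degradation/{material.lower()}")
        masses = masses * (1.0 + rng.normal(0.0, noise_sd_percent / 100.0,
                                            masses.size))
    return MassTimeSeries(t, masses, ph_label="4", replicate_id="r1")


def gen_cyclic_series(material: str, cfg: SyntheticConfig) -> MassTimeSeries:
    """Daily alternating pH 4/7 series over ``cyclic_days`` days.

    Masses sit at the per-pH equilibrium each day; exactly periodic when
    ``cyclic_drift_percent`` is 0, otherwise each revisit of a pH state is
    inflated by the compounded drift (emulating incomplete reversibility).
    """
    m4 = cfg.m0_mg
    m7 = cfg.m0_mg * (1.0 + _swelling_target(cfg, material, "7") / 100.0)
    days = np.arange(cfg.cyclic_days + 1, dtype=float)
    phs, masses = [], []
    visits = {4.0: 0, 7.0: 0}
    for d in days:
        ph = 4.0 if int(d) % 2 == 0 else 7.0
        base = m4 if ph == 4.0 else m7
        masses.append(base * (1.0 + cfg.cyclic_drift_percent / 100.0)
                      ** visits[ph])
        phs.append(ph)
        visits[ph] += 1
    return MassTimeSeries(days, np.asarray(masses), ph_label="cyclic",
                          replicate_id="r1",
                          ph_schedule=np.asarray(phs))


def gen_assay_readout(true_conc_M: float, cfg: SyntheticConfig,
                      n: int = 1) -> np.ndarray:
    """Simulated colorimetric absorbances for a true Cu2+ concentration."""
    cal = cfg.assay_calibration
    clean = cal.slope * true_conc_M + cal.intercept
    if cal.noise_sd > 0:
        rng = cfg.rng("assay")
        return clean + rng.normal(0.0, cal.noise_sd, size=n)
    return np.full(n, clean)


def invert_calibration(absorbance, cfg: SyntheticConfig):
    """Exact affine inverse of the assay calibration: absorbance -> M."""
    cal = cfg.assay_calibration
    return (np.asarray(absorbance, dtype=float) - cal.intercept) / cal.slope
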
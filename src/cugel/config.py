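"""Structured configuration: packaged defaults, YAML loading, validation.

The single config file has blocks ``release``, ``geometry``, ``materials``,
``transport``, ``sweep``, ``threshold_M`` and ``synth``. Unknown keys are
rejected so typos fail loudly instead of silently using a default.
User-facing units are practical (ug/day, mm, mL, s); everything is
converted to SI on load.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .geometry import (AdsorptionParams, ConfigurationError, DeviceGeometry,
                       GelMaterial)
from .swelling import DimensionalChange
from .synthetic import SyntheticConfig
from .transport import TransportConfig
from .units import ReleaseSpec

__all__ = ["Config", "load_config", "default_config", "config_hash"]

_TOP_KEYS = {"release", "geometry", "materials", "transport", "sweep",
             "threshold_M", "synth"}


@dataclass
class Config:
    """Fully resolved run configuration (SI units internally)."""

    release: ReleaseSpec
    sleeve_radius: float        # m
    sleeve_length: float        # m
    gel_thickness: float        # m
    fluid_volume: float         # m3
    materials: dict[str, GelMaterial]
    transport: TransportConfig
    sweep_min_mm: float
    sweep_max_mm: float
    sweep_pitch_mm: float
    threshold_M: float
    synth: SyntheticConfig
    raw: dict = field(repr=False, default_factory=dict)

    def geometry(self, thickness_mm: float | None = None) -> DeviceGeometry:
        thickness = (self.gel_thickness if thickness_mm is None
                     else thickness_mm * 1e-3)
        return DeviceGeometry(
            sleeve_radius=self.sleeve_radius,
            sleeve_length=self.sleeve_length,
            gel_thickness_ph4=thickness,
            fluid_volume=self.fluid_volume,
        )


def _require_keys(block: dict, allowed: set[str], context: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in config block {context!r}")


def _build_material(name: str, block: dict) -> GelMaterial:
    _require_keys(block, {"diffusivity_m2_s", "deformation_percent",
                          "adsorption", "degradation_rate_per_day"},
                  f"materials.{name}")
    deform = {}
    for ph, pair in block.get("deformation_percent", {}).items():
        axial, radial = pair
        deform[str(ph)] = DimensionalChange(axial_percent=float(axial),
                                            radial_percent=float(radial))
    ads_block = block.get("adsorption")
    adsorption = None
    active_ph: frozenset[str] = frozenset()
    if ads_block is not None:
        _require_keys(ads_block, {"capacity_mol_m3", "partition", "active_ph"},
                      f"materials.{name}.adsorption")
        adsorption = AdsorptionParams(
            capacity=float(ads_block["capacity_mol_m3"]),
            partition=float(ads_block["partition"]))
        active_ph = frozenset(str(p) for p in ads_block.get("active_ph", []))
    return GelMaterial(
        name=name,
        diffusivity_by_ph={str(k): float(v)
                           for k, v in block["diffusivity_m2_s"].items()},
        deformation_by_ph=deform,
        adsorption=adsorption,
        adsorption_ph=active_ph,
        degradation_rate=float(block.get("degradation_rate_per_day", 0.0)),
    )


def _from_dict(data: dict) -> Config:
    _require_keys(data, _TOP_KEYS, "<top level>")
    rel = data["release"]
    _require_keys(rel, {"daily_release_ug_per_day", "copper_area_mm2"},
                  "release")
    geo = data["geometry"]
    _require_keys(geo, {"sleeve_radius_mm", "sleeve_length_mm",
                        "gel_thickness_mm", "fluid_volume_ml"}, "geometry")

    release = ReleaseSpec(
        daily_release=float(rel["daily_release_ug_per_day"]),
        copper_area=float(rel["copper_area_mm2"]) * 1e-6,
    )
    sleeve_radius = float(geo["sleeve_radius_mm"]) * 1e-3
    sleeve_length = float(geo["sleeve_length_mm"]) * 1e-3
    lateral = 2.0 * 3.141592653589793 * sleeve_radius * sleeve_length
    if abs(lateral - release.copper_area) / release.copper_area > 1e-6:
        raise ConfigurationError(
            f"sleeve lateral area {lateral * 1e6:.4f} mm2 does not match "
            f"release.copper_area_mm2 = {release.copper_area * 1e6:.4f}")

    tr = data.get("transport", {})
    _require_keys(tr, {"n_cells", "dt_s", "t_end_s", "scheme",
                       "conservation_tol", "output_every_s"}, "transport")
    transport = TransportConfig(
        n_cells=int(tr.get("n_cells", 100)),
        dt=float(tr.get("dt_s", 10.0)),
        t_end=float(tr.get("t_end_s", 28_800.0)),
        scheme=str(tr.get("scheme", "backward_euler")),
        conservation_tol=float(tr.get("conservation_tol", 1e-6)),
        output_every_s=float(tr.get("output_every_s", 1800.0)),
    )

    sweep = data.get("sweep", {})
    _require_keys(sweep, {"min_mm", "max_mm", "pitch_mm"}, "sweep")

    synth_block = dict(data.get("synth", {}))
    _require_keys(synth_block, {"seed", "n_replicates"}, "synth")
    synth = SyntheticConfig(seed=int(synth_block.get("seed", 0)),
                            n_replicates=int(synth_block.get("n_replicates", 3)))

    return Config(
        release=release,
        sleeve_radius=sleeve_radius,
        sleeve_length=sleeve_length,
        gel_thickness=float(geo["gel_thickness_mm"]) * 1e-3,
        fluid_volume=float(geo["fluid_volume_ml"]) * 1e-6,
        materials={name: _build_material(name, blk)
                   for name, blk in data.get("materials", {}).items()},
        transport=transport,
        sweep_min_mm=float(sweep.get("min_mm", 1.0)),
        sweep_max_mm=float(sweep.get("max_mm", 2.0)),
        sweep_pitch_mm=float(sweep.get("pitch_mm", 0.25)),
        threshold_M=float(data.get("threshold_M", 1e-6)),
        synth=synth,
        raw=data,
    )


def load_config(path: str | Path) -> Config:
    """Load and validate a YAML config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} is not a mapping")
    return _from_dict(data)


def default_config() -> Config:
    """The packaged device-default configuration (calibrated and frozen)."""
    text = resources.files("cugel.data").joinpath("defaults.yaml").read_text()
    return _from_dict(yaml.safe_load(text))


def config_hash(cfg: Config) -> str:
    """Stable hash of the raw config mapping, for report provenance."""
    canon = json.dumps(cfg.raw, sort_keys=True, separators=(",", ":"),
                       default=str)
    return hashlib.sha256(canon.encode("utf8")).hexdigest()[:16]
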
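"""Dose-assessment pipeline: deform -> solve -> compare to threshold.

Orchestrates the computational experiment: for each (material, pH, coating
thickness) the coating is deformed to its pH equilibrium, the radial
transport problem is solved over the 8-h horizon, and the final fluid
concentration is compared to the spermicidal threshold (1e-6 M, inclusive).
Results are emitted as a machine-readable report (CSV + JSON with config
provenance), byte-identical across reruns of an identical configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import Config, config_hash, default_config
from .geometry import ConfigurationError, deform
from .transport import ConcentrationState, mass_balance_residual, solve

__all__ = [
    "ScenarioSpec",
    "ReportRow",
    "ReleaseReport",
    "run_scenario",
    "run_sweep",
    "assess_dose",
    "write_report",
    "SPERMICIDAL_THRESHOLD_M",
]

log = logging.getLogger(__name__)

#: Efficacious spermicidal Cu2+ concentration, mol/L.
SPERMICIDAL_THRESHOLD_M = 1e-6


@dataclass
class ScenarioSpec:
    """One fully specified simulation: material, pH and coating thickness.

    Wraps the shared configuration; ``in_vitro=True`` swaps the closed
    7.5 mL cavity for the 10 mL bench buffer volume of the release test.
    """

    config: Config
    material: str
    ph: str
    thickness_mm: float
    in_vitro: bool = False

    def __post_init__(self) -> None:
        if self.material not in self.config.materials:
            raise ConfigurationError(
                f"unknown material {self.material!r}; have "
                f"{sorted(self.config.materials)}")
        self.ph = str(self.ph)
        if self.ph not in ("4", "7"):
            raise ConfigurationError(f"ph must be '4' or '7', got {self.ph!r}")

    @property
    def volume(self) -> float:
        return 10e-6 if self.in_vitro else self.config.fluid_volume


@dataclass
class ReportRow:
    material: str
    ph: str
    thickness_mm: float
    fluid_conc_8h_M: float
    above_threshold: bool
    residual: float


@dataclass
class ReleaseReport:
    rows: list[ReportRow] = field(default_factory=list)
    threshold_M: float = SPERMICIDAL_THRESHOLD_M
    config_hash: str = ""
    seed: int | None = None

    COLUMNS = ("material", "ph", "thickness_mm", "fluid_conc_8h_M",
               "above_threshold", "residual")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows],
                            columns=list(self.COLUMNS))


def run_scenario(spec: ScenarioSpec) -> ReportRow:
    """Simulate one scenario and report its 8-h fluid concentration."""
    cfg = spec.config
    material = cfg.materials[spec.material]
    geom = cfg.geometry(spec.thickness_mm)
    deformed = deform(geom, material, spec.ph)
    log.info("scenario %s pH %s %.2f mm: thickness -> %.3f mm, exposed %.3f",
             spec.material, spec.ph, spec.thickness_mm,
             deformed.gel_thickness * 1e3, deformed.exposed_fraction)
    states = solve(cfg.release, deformed, material, spec.volume, cfg.transport)
    final: ConcentrationState = states[-1]
    conc_M = final.fluid_molar
    return ReportRow(
        material=spec.material,
        ph=spec.ph,
        thickness_mm=spec.thickness_mm,
        fluid_conc_8h_M=conc_M,
        above_threshold=conc_M >= cfg.threshold_M,
        residual=mass_balance_residual(final, spec.volume),
    )


def run_sweep(config: Config, thicknesses_mm: list[float] | None = None,
              materials: list[str] | None = None,
              phs: tuple[str, ...] = ("4", "7")) -> ReleaseReport:
    """Full factorial sweep: materials x pH x thickness.

    With the packaged defaults this is 2 materials x 2 pH x 5 thicknesses
    = 20 rows. Any row failure aborts with the partial report attached to
    the exception for diagnostics.
    """
    from .geometry import sweep_thicknesses
    if thicknesses_mm is None:
        thicknesses_mm = sweep_thicknesses(
            config.sweep_min_mm, config.sweep_max_mm, config.sweep_pitch_mm)
    if not thicknesses_mm:
        raise ValueError("thickness list must be nonempty")
    if materials is None:
        materials = sorted(config.materials)
    report = ReleaseReport(threshold_M=config.threshold_M,
                           config_hash=config_hash(config))
    for mat in materials:
        for ph in phs:
            for th in thicknesses_mm:
                try:
                    report.rows.append(run_scenario(
                        ScenarioSpec(config, mat, ph, th)))
                except Exception as exc:
                    exc.partial_report = report  # type: ignore[attr-defined]
                    raise
    return report


def assess_dose(report: ReleaseReport,
                threshold_M: float = SPERMICIDAL_THRESHOLD_M) -> ReleaseReport:
    """Recompute threshold verdicts against a (possibly new) threshold.

    The comparison is inclusive (>=): a concentration exactly at the
    threshold counts as reaching the dose. Idempotent.
    """
    report.threshold_M = threshold_M
    for row in report.rows:
        row.above_threshold = row.fluid_conc_8h_M >= threshold_M
    return report


def write_report(report: ReleaseReport, path: str | Path,
                 config: Config | None = None) -> tuple[Path, Path]:
    """Write the report as ``<path>.csv`` and ``<path>.json``.

    The JSON payload carries the rows, threshold, config echo and
    provenance (package version, config hash, seed); no timestamp, so
    reruns of an identical configuration are byte-identical.
    """
    path = Path(path)
    csv_path = path.with_suffix(".csv")
    json_path = path.with_suffix(".json")
    report.to_frame().to_csv(csv_path, index=False)
    payload = {
        "rows": [vars(r) for r in report.rows],
        "threshold_M": report.threshold_M,
        "provenance": {
            "version": __version__,
            "config_hash": report.config_hash,
            "seed": report.seed,
        },
        "config": (config.raw if config is not None else None),
    }
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                                    default=str) + "\n")
    return csv_path, json_path


def paper_default_sweep() -> ReleaseReport:
    """Convenience: the default 20-row sweep on the packaged configuration."""
    return run_sweep(default_config())
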
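"""Analysis of gel mass/dimension time series.

Turns raw swelling, degradation and cyclic-pH measurements (real or
synthetic) into summary quantities: the swelling ratio (percent mass change
at pH 7 relative to the pH 4 baseline), first-order swelling kinetics and
plateau times, anisotropic dimensional variation, degradation summaries and
cyclic-reversibility drift.

The kinetic model is a single-rate exponential approach to equilibrium,
``m(t) = m_inf + (m0 - m_inf) exp(-k t)`` — the minimal description
consistent with a monotone approach to a plateau. Rate constants are
descriptive fit parameters, not mechanistic claims.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "MassTimeSeries",
    "SwellingResult",
    "DimensionalChange",
    "DegradationSummary",
    "InsufficientDataError",
    "FitError",
    "swelling_ratio",
    "fit_swelling_kinetics",
    "plateau_time",
    "dimensional_variation",
    "fit_degradation",
    "cyclic_reversibility",
    "read_mass_series_csv",
    "write_mass_series_csv",
]


class InsufficientDataError(ValueError):
    """Raised when a series has too few points or cycles for the analysis."""


class FitError(RuntimeError):
    """Raised when a least-squares fit fails to converge."""


@dataclass
class MassTimeSeries:
    """A gel mass trajectory for one replicate under one pH condition.

    Attributes
    ----------
    times : array of float
        Sampling times in hours (days for degradation series), strictly
        increasing, nonnegative.
    masses : array of float
        Gel masses in mg, strictly positive.
    ph_label : str
        ``"4"``, ``"7"`` or ``"cyclic"``.
    replicate_id : str
    ph_schedule : array of float or None
        For cyclic series: the pH each sample was taken at.
    """

    times: np.ndarray
    masses: np.ndarray
    ph_label: str
    replicate_id: str = "r1"
    ph_schedule: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.times.size != self.masses.size:
            raise ValueError("times and masses must have the same length")
        if self.times.size < 2:
            raise InsufficientDataError("series needs at least 2 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.times < 0):
            raise ValueError("times must be nonnegative")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        if self.ph_schedule is not None:
            self.ph_schedule = np.asarray(self.ph_schedule, dtype=float)
            if self.ph_schedule.size != self.times.size:
                raise ValueError("ph_schedule must match times in length")


@dataclass
class SwellingResult:
    """Fitted swelling kinetics and the derived equilibrium ratio."""

    ratio_percent: float
    m0: float            # mg
    m_inf: float         # mg
    rate_k: float        # 1/h
    plateau_time: float  # h (95% completion)
    fit_residual: float  # RMS relative residual, dimensionless


@dataclass(frozen=True)
class DimensionalChange:
    """Axial/radial percent variation at pH 7 relative to pH 4.

    Positive values encode swelling, negative shrinking. Each must exceed
    -100% (a gel cannot shrink past zero size).
    """

    axial_percent: float
    radial_percent: float

    def __post_init__(self) -> None:
        for name, v in (("axial_percent", self.axial_percent),
                        ("radial_percent", self.radial_percent)):
            if v <= -100:
                raise ValueError(f"{name} must exceed -100, got {v}")


@dataclass
class DegradationSummary:
    mass_loss_percent_day25: float
    plateau_day: float
    decay_rate: float  # 1/day


def swelling_ratio(mass_ph4_ref: float, mass_ph7: float) -> float:
    """Percent mass change at pH 7 relative to the pH 4 reference mass.

    ``100 * (m7 - m4) / m4``: +34% for a PAAm-like gel that gains a third
    of its mass, -61% for a chitosan-like gel that expels most of its water.
    """
    if mass_ph4_ref <= 0:
        raise ValueError(f"mass_ph4_ref must be positive, got {mass_ph4_ref}")
    if mass_ph7 <= 0:
        raise ValueError(f"mass_ph7 must be positive, got {mass_ph7}")
    return 100.0 * (mass_ph7 - mass_ph4_ref) / mass_ph4_ref


def _exp_approach(t, m_inf, m0, k):
    return m_inf + (m0 - m_inf) * np.exp(-k * t)


def _pooled_arrays(series: MassTimeSeries | Sequence[MassTimeSeries]):
    if isinstance(series, MassTimeSeries):
        series = [series]
    t = np.concatenate([s.times for s in series])
    m = np.concatenate([s.masses for s in series])
    order = np.argsort(t, kind="stable")
    return t[order], m[order]


def fit_swelling_kinetics(
    series: MassTimeSeries | Sequence[MassTimeSeries],
    plateau_fraction: float = 0.95,
) -> SwellingResult:
    """Fit ``m(t) = m_inf + (m0 - m_inf) exp(-k t)`` by least squares.

    Replicates may be passed as a sequence and are fitted jointly (pooled
    residuals), mirroring triplicate reporting as mean +/- SD. Deterministic
    given the data.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 pooled points.
    FitError
        Non-convergence of the optimizer.
    """
    t, m = _pooled_arrays(series)
    if t.size < 3:
        raise InsufficientDataError("kinetic fit needs at least 3 points")

    m0_guess = m[np.argmin(t)]
    minf_guess = m[np.argmax(t)]
    total = abs(minf_guess - m0_guess)
    # Near-constant series: the rate is unidentifiable; report equilibrium.
    if total < 1e-12 * max(abs(m0_guess), 1.0) or np.ptp(m) < 1e-12 * np.max(m):
        mean = float(np.mean(m))
        return SwellingResult(0.0, mean, mean, 0.0, 0.0, _rms_rel(m, mean))

    span = t[-1] - t[0] if t[-1] > t[0] else 1.0
    k_guess = 3.0 / max(span / 6.0, 1e-6)
    try:
        popt, _ = curve_fit(
            _exp_approach, t, m,
            p0=[minf_guess, m0_guess, min(k_guess, 10.0)],
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy non-convergence
        raise FitError(f"swelling kinetics fit failed: {exc}") from exc
    m_inf, m0, k = (float(v) for v in popt)
    if k <= 0:
        raise FitError(f"fit produced non-positive rate k={k}")
    resid = _rms_rel(m, _exp_approach(t, m_inf, m0, k))
    ratio = swelling_ratio(m0, m_inf)
    result = SwellingResult(ratio, m0, m_inf, k, 0.0, resid)
    result.plateau_time = plateau_time(result, plateau_fraction)
    return result


def _rms_rel(m, model) -> float:
    return float(np.sqrt(np.mean(((m - model) / np.mean(m)) ** 2)))


def plateau_time(result: SwellingResult, fraction: float = 0.95) -> float:
    """First time the fitted curve completes ``fraction`` of its mass change.

    Closed form ``-ln(1 - fraction) / k``; ~4 h for k = 0.75 1/h at the
    default 95% criterion. A constant series (k = 0) has plateau time 0.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if result.m0 == result.m_inf:
        return 0.0
    if result.rate_k <= 0:
        raise ValueError(f"degenerate kinetics: k={result.rate_k} <= 0")
    return float(-np.log(1.0 - fraction) / result.rate_k)


def dimensional_variation(
    dims_ph4: tuple[float, float], dims_ph7: tuple[float, float]
) -> DimensionalChange:
    """Percent variation of (length, diameter) at pH 7 relative to pH 4."""
    l4, d4 = dims_ph4
    l7, d7 = dims_ph7
    for name, v in (("length@pH4", l4), ("diameter@pH4", d4),
                    ("length@pH7", l7), ("diameter@pH7", d7)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return DimensionalChange(
        axial_percent=100.0 * (l7 - l4) / l4,
        radial_percent=100.0 * (d7 - d4) / d4,
    )


def fit_degradation(
    series: MassTimeSeries | Sequence[MassTimeSeries],
    near_constant_percent: float = 2.0,
) -> DegradationSummary:
    """Summarize a long-term (>= 10 day) mass-loss series.

    Fits the same exponential-approach model over days. Series whose total
    relative change is below ``near_constant_percent`` are classified as
    stable: decay rate 0, plateau day 0. The plateau day (95% completion)
    is capped at the end of the series.
    """
    t, m = _pooled_arrays(series)
    if t.size < 4:
        raise InsufficientDataError("degradation fit needs at least 4 points")
    if t[-1] - t[0] < 10:
        raise InsufficientDataError("degradation series must span >= 10 days")

    m0 = m[0]
    change_percent = 100.0 * (m[-1] - m0) / m0
    if abs(change_percent) < near_constant_percent:
        return DegradationSummary(0.0, 0.0, 0.0)

    fit = fit_swelling_kinetics(
        MassTimeSeries(t, m, ph_label="4", replicate_id="pooled"))
    loss_at_25 = 100.0 * (_exp_approach(min(25.0, t[-1]), fit.m_inf, fit.m0,
                                        fit.rate_k) - fit.m0) / fit.m0
    plateau = min(float(-np.log(0.05) / fit.rate_k), float(t[-1]))
    return DegradationSummary(float(loss_at_25), plateau, fit.rate_k)


def cyclic_reversibility(series: MassTimeSeries) -> float:
    """Maximum percent drift between revisits of the same pH state.

    For each pH level visited at least twice, computes the relative spread
    of the recorded masses across visits; returns the largest, in percent.
    0 means perfectly reversible swelling/deswelling.
    """
    if series.ph_schedule is None:
        raise ValueError("cyclic series requires a ph_schedule")
    levels = np.unique(series.ph_schedule)
    revisited = [lv for lv in levels
                 if np.sum(series.ph_schedule == lv) >= 2]
    if not revisited:
        raise InsufficientDataError(
            "need at least 2 visits to some pH state to assess reversibility")
    max_drift = 0.0
    for lv in revisited:
        m = series.masses[series.ph_schedule == lv]
        drift = 100.0 * (np.max(m) - np.min(m)) / np.min(m)
        max_drift = max(max_drift, float(drift))
    return max_drift


# ---------------------------------------------------------------------------
# CSV interface: columns time, mass_mg, ph, replicate (header required).

def write_mass_series_csv(series: Sequence[MassTimeSeries], path: str | Path) -> None:
    frames = []
    for s in series:
        ph = s.ph_schedule if s.ph_schedule is not None else [s.ph_label] * s.times.size
        frames.append(pd.DataFrame({
            "time": s.times, "mass_mg": s.masses,
            "ph": ph, "replicate": s.replicate_id,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_mass_series_csv(path: str | Path) -> list[MassTimeSeries]:
    df = pd.read_csv(path)
    required = {"time", "mass_mg", "ph", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"CSV missing required columns: {sorted(missing)}")
    out = []
    for rep, grp in df.groupby("replicate", sort=False):
        grp = grp.sort_values("time")
        phs = grp["ph"].astype(str).unique()
        cyclic = len(phs) > 1
        out.append(MassTimeSeries(
            times=grp["time"].to_numpy(float),
            masses=grp["mass_mg"].to_numpy(float),
            ph_label="cyclic" if cyclic else str(phs[0]),
            replicate_id=str(rep),
            ph_schedule=grp["ph"].to_numpy(float) if cyclic else None,
        ))
    return out
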
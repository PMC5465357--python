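"""Steady-state benthic fluxes from flow-through core incubations.

A sealed sediment core is continuously flushed with seawater; once the
effluent composition stops drifting (usually after ~3 days) the net
sediment-water exchange of a solute is

    Flux = mean(effluent - influent) * flow_rate / area

with the sign convention that negative flux = uptake by the sediment.
Fluxes are reported in mmol m-2 d-1, except N2O in umol m-2 d-1 (matching
the magnitudes typical of sediment N2O effluxes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .exceptions import (
    ConfigurationError,
    InsufficientDataError,
    InvalidValueError,
    NoSteadyStateError,
)

__all__ = [
    "IncubationSeries",
    "FluxRecord",
    "core_area",
    "detect_steady_state",
    "compute_flux",
    "DEFAULT_OUTER_DIAMETER_CM",
    "DEFAULT_WALL_THICKNESS_CM",
]

#: Core-liner geometry: 10 cm outer diameter, 1/8 inch wall.
DEFAULT_OUTER_DIAMETER_CM = 10.0
DEFAULT_WALL_THICKNESS_CM = 0.3175

#: Species whose fluxes are reported in umol m-2 d-1 instead of mmol m-2 d-1.
_MICROMOL_SPECIES = frozenset({"N2O"})

_ML_MIN_TO_L_DAY = 1440.0 / 1000.0  # 1 mL/min = 1.44 L/day


@dataclass(frozen=True)
class IncubationSeries:
    """Influent/effluent concentration time series for one core and species.

    times are days since the start of the incubation (strictly increasing);
    concentrations in uM; flow_rate in mL min-1 measured at each sampling
    point; geometry in cm.
    """

    core_id: str
    species: str
    times: Tuple[float, ...]
    influent_conc: Tuple[float, ...]
    effluent_conc: Tuple[float, ...]
    flow_rate: Tuple[float, ...]
    outer_diameter: float = DEFAULT_OUTER_DIAMETER_CM
    wall_thickness: float = DEFAULT_WALL_THICKNESS_CM

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("influent_conc", "effluent_conc", "flow_rate"):
            if len(getattr(self, name)) != n:
                raise InvalidValueError(f"{name} length differs from times")
        t = np.asarray(self.times, dtype=float)
        if n and not np.all(np.diff(t) > 0):
            raise InvalidValueError("times must be strictly increasing")
        for name, arr in (("influent_conc", self.influent_conc),
                          ("effluent_conc", self.effluent_conc)):
            a = np.asarray(arr, dtype=float)
            if a.size and (not np.all(np.isfinite(a)) or np.any(a < 0)):
                raise InvalidValueError(f"{name} must be finite and >= 0")
        r = np.asarray(self.flow_rate, dtype=float)
        if r.size and (not np.all(np.isfinite(r)) or np.any(r <= 0)):
            raise InvalidValueError("flow_rate must be finite and > 0")

    @property
    def delta_conc(self) -> np.ndarray:
        """Effluent minus influent concentration (uM) at each time point."""
        return (np.asarray(self.effluent_conc, dtype=float)
                - np.asarray(self.influent_conc, dtype=float))

    @property
    def area_m2(self) -> float:
        return core_area(self.outer_diameter, self.wall_thickness)


@dataclass(frozen=True)
class FluxRecord:
    """One steady-state flux estimate.

    Negative flux = uptake by the sediment.  ``units`` records the scale used
    (mmol m-2 d-1, or umol m-2 d-1 for N2O).
    """

    core_id: str
    species: str
    flux: float
    flux_sd: float
    steady_state_window: Tuple[float, float]
    n_points: int
    units: str = "mmol m-2 d-1"


def core_area(outer_diameter: float, wall_thickness: float) -> float:
    """Inner cross-sectional (sediment surface) area of a core liner, in m2.

    Arguments in cm; the inner diameter is OD - 2*wall.
    """
    if not (math.isfinite(outer_diameter) and math.isfinite(wall_thickness)):
        raise ConfigurationError("core geometry must be finite")
    inner = outer_diameter - 2.0 * wall_thickness
    if wall_thickness < 0 or inner <= 0:
        raise ConfigurationError(
            f"nonphysical core geometry: OD={outer_diameter} cm, "
            f"wall={wall_thickness} cm")
    radius_cm = inner / 2.0
    return math.pi * radius_cm ** 2 * 1e-4  # cm2 -> m2


def detect_steady_state(series: IncubationSeries, min_day: float = 3.0,
                        slope_tol: float = 0.05) -> Tuple[float, float]:
    """Largest trailing window in which effluent - influent has stopped drifting.

    Fits a straight line to delta = (effluent - influent) over each trailing
    window that starts at or after ``min_day``; the window qualifies when the
    fitted |slope| divided by a robust magnitude scale of delta (the larger of
    |mean| and RMS, floored to avoid 0/0 on null series) is below
    ``slope_tol`` (units: fraction per day).  Returns the earliest-starting —
    hence largest — qualifying window as (t_start, t_end).

    Raises :class:`NoSteadyStateError` when no window with >= 3 points
    qualifies; callers may then prescribe a window to
    :func:`compute_flux` explicitly.
    """
    t = np.asarray(series.times, dtype=float)
    idx = np.nonzero(t >= min_day)[0]
    if idx.size < 3:
        raise InsufficientDataError(
            f"need >= 3 points at or after day {min_day}, have {idx.size}")
    delta = series.delta_conc
    for start in idx[: idx.size - 2]:
        tw = t[start:]
        dw = delta[start:]
        slope = np.polyfit(tw, dw, 1)[0]
        scale = max(abs(dw.mean()), math.sqrt(float(np.mean(dw ** 2))), 1e-12)
        if abs(slope) / scale < slope_tol:
            return (float(tw[0]), float(tw[-1]))
    raise NoSteadyStateError(
        f"no trailing window after day {min_day} has relative trend "
        f"below {slope_tol}/day for {series.core_id}/{series.species}")


def compute_flux(series: IncubationSeries,
                 window: Optional[Tuple[float, float]] = None,
                 min_day: float = 3.0, slope_tol: float = 0.05) -> FluxRecord:
    """Steady-state mass flux for one core and species.

    flux = mean(delta_conc) * mean(flow) / area, converted to
    mmol m-2 d-1 (umol m-2 d-1 for N2O).  When ``window`` is omitted it is
    found by :func:`detect_steady_state`.

    The standard deviation propagates, to first order and assuming
    independence, the uncertainty of the windowed mean concentration
    difference and of the windowed mean flow rate (standard errors of the
    means; flow and concentration are measured by different instruments).
    """
    if window is None:
        window = detect_steady_state(series, min_day=min_day, slope_tol=slope_tol)
    t = np.asarray(series.times, dtype=float)
    lo, hi = window
    mask = (t >= lo) & (t <= hi)
    n = int(mask.sum())
    if n < 2:
        raise InsufficientDataError(
            f"steady-state window {window} contains {n} point(s); need >= 2")
    delta = series.delta_conc[mask]          # uM = umol/L
    flow = np.asarray(series.flow_rate, dtype=float)[mask]  # mL/min

    area = series.area_m2
    mean_d = float(delta.mean())
    mean_r = float(flow.mean()) * _ML_MIN_TO_L_DAY  # L/day
    sem_d = float(delta.std(ddof=1)) / math.sqrt(n)
    sem_r = float(flow.std(ddof=1)) * _ML_MIN_TO_L_DAY / math.sqrt(n)

    flux_umol = mean_d * mean_r / area  # umol m-2 d-1
    var = (mean_r * sem_d) ** 2 + (mean_d * sem_r) ** 2
    sd_umol = math.sqrt(var) / area

    if series.species in _MICROMOL_SPECIES:
        return FluxRecord(series.core_id, series.species, flux_umol, sd_umol,
                          (float(lo), float(hi)), n, units="umol m-2 d-1")
    return FluxRecord(series.core_id, series.species, flux_umol / 1000.0,
                      sd_umol / 1000.0, (float(lo), float(hi)), n)
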
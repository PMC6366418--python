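"""Initial-velocity extraction from well time courses.

The assay follows chromophore release at 405 nm; absorbance grows
linearly while substrate depletion is negligible.  The initial velocity
is the ordinary least-squares slope of absorbance over the 5-30 min
window, converted to umol/min by Beer-Lambert:

    v = slope / (epsilon * path_length) * well_volume * 1e6

with epsilon in M^-1 cm^-1, path length in cm and well volume in litres.
The conversion constants are assay configuration, not measured
quantities; analyses that only need velocity ratios (percent inhibition,
IC50) cancel them exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigError, InsufficientDataError
from .mechanisms import Condition

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import PlateTimeSeries

__all__ = [
    "ConversionConstants",
    "VelocityObservation",
    "SlopeWindow",
    "fit_slope",
    "slope_to_velocity",
    "extract_velocities",
]

#: Default slope window in minutes, endpoints inclusive.
DEFAULT_WINDOW = (5.0, 30.0)


@dataclass(frozen=True)
class ConversionConstants:
    """Beer-Lambert constants mapping absorbance slope to velocity.

    Defaults describe 2-chloro-nitrophenol read in a 200 uL well of a
    standard 96-well plate (path ~0.58 cm for that fill volume).
    """

    epsilon: float = 12900.0  # M^-1 cm^-1, molar absorptivity at 405 nm
    path_length: float = 0.58  # cm
    well_volume: float = 2.0e-4  # L (200 uL)

    def __post_init__(self) -> None:
        for name in ("epsilon", "path_length", "well_volume"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def slope_per_velocity(self) -> float:
        """AU/min of slope produced per umol/min of velocity."""
        return self.epsilon * self.path_length / (self.well_volume * 1e6)


@dataclass(frozen=True)
class VelocityObservation:
    """One initial velocity with its assay condition.

    ``v`` is the blank-corrected velocity in umol/min (clamped at 0);
    ``slope`` retains the raw fitted slope in AU/min.
    """

    cond: Condition
    replicate: int
    v: float
    slope: float
    r_squared: float
    well_id: Optional[str] = None


SlopeWindow = tuple[float, float]


def fit_slope(
    times: Sequence[float],
    absorbance: Sequence[float],
    window: SlopeWindow = DEFAULT_WINDOW,
) -> tuple[float, float, float]:
    """OLS line through the reads inside ``[t_lo, t_hi]`` (inclusive).

    Returns
    -------
    (slope, intercept, r_squared)
        Slope in AU/min, intercept in AU, coefficient of determination.
        A perfectly constant trace has slope 0 and r_squared 1 (the fit
        is exact).

    Raises
    ------
    InsufficientDataError
        If fewer than 3 reads fall inside the window.
    """
    t = np.asarray(times, dtype=float)
    a = np.asarray(absorbance, dtype=float)
    if t.shape != a.shape:
        raise ValueError("times and absorbance must have the same length")
    mask = (t >= window[0]) & (t <= window[1]) & np.isfinite(a)
    if mask.sum() < 3:
        raise InsufficientDataError(
            f"need >=3 finite reads in window {window}, got {int(mask.sum())}"
        )
    t, a = t[mask], a[mask]
    if np.ptp(a) == 0.0:
        # constant trace: exact horizontal fit
        return 0.0, float(a[0]), 1.0
    res = stats.linregress(t, a)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def slope_to_velocity(slope: float, cc: ConversionConstants) -> float:
    """Convert an absorbance slope (AU/min) to a velocity (umol/min)."""
    return slope / (cc.epsilon * cc.path_length) * cc.well_volume * 1e6


@dataclass
class ExtractionReport:
    """Velocities plus per-well failures from one plate."""

    observations: list[VelocityObservation]
    failures: dict[str, str] = field(default_factory=dict)


def extract_velocities(
    plate: "PlateTimeSeries",
    window: SlopeWindow = DEFAULT_WINDOW,
    cc: ConversionConstants = ConversionConstants(),
) -> ExtractionReport:
    """One velocity observation per well; failed wells are reported, not fatal.

    Replicate identity is preserved: downstream fitting uses individual
    observations, never per-condition means.  Negative fitted slopes are
    clamped to zero velocity with a warning (product absorbance cannot
    decrease under the model); the raw slope is kept.
    """
    obs: list[VelocityObservation] = []
    failures: dict[str, str] = {}
    for well in plate.wells:
        try:
            slope, _, r2 = fit_slope(plate.read_times, well.absorbance, window)
        except InsufficientDataError as exc:
            failures[well.well_id] = str(exc)
            continue
        v = slope_to_velocity(slope, cc)
        if v < 0:
            warnings.warn(
                f"negative slope in well {well.well_id} clamped to zero velocity",
                stacklevel=2,
            )
            v = 0.0
        obs.append(
            VelocityObservation(
                cond=well.cond,
                replicate=well.replicate,
                v=v,
                slope=slope,
                r_squared=r2,
                well_id=well.well_id,
            )
        )
    return ExtractionReport(observations=obs, failures=failures)
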
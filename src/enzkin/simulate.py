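"""Seeded synthetic microplate generator with known ground truth.

Emulates the chromogenic alpha-amylase assay: each well holds enzyme,
substrate at one of three concentrations and inhibitor at one rung of a
dilution ladder; absorbance at 405 nm grows linearly at a rate
proportional to the well's true initial velocity.  The generator is the
test bed for the whole pipeline — plates embed their ground-truth
mechanism and constants so recovery can be scored.

The signal model per well is

    A(t) = baseline + k * v(S, I) * t + eps(t),   eps ~ N(0, sd) i.i.d.

with ``k`` the Beer-Lambert slope-per-velocity factor shared with the
extractor, a per-well baseline drawn uniformly from a small range, and
additive Gaussian read noise.  Identical seed, design and truth give a
bit-identical plate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigError, UnknownCompoundError
from .mechanisms import Condition, KineticParameters, Mechanism, rate_law, validate_params
from .rates import ConversionConstants

__all__ = [
    "PlateDesign",
    "NoiseModel",
    "Well",
    "PlateTimeSeries",
    "simulate_plate",
    "protocol_design",
    "reference_truth",
    "REFERENCE_COMPOUNDS",
]

#: Substrate triple used throughout the assay protocol (mM).
PROTOCOL_SUBSTRATES = (0.25, 0.5, 1.0)


@dataclass(frozen=True)
class PlateDesign:
    """Factorial plate layout: substrates x inhibitor ladder x replicates."""

    substrate_levels: tuple[float, ...]
    inhibitor_levels: tuple[float, ...]
    replicates: int = 3
    read_times: tuple[float, ...] = tuple(float(t) for t in range(31))

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ConfigError(f"replicates must be >= 1, got {self.replicates}")
        times = np.asarray(self.read_times, dtype=float)
        if times.size < 2 or np.any(np.diff(times) <= 0):
            raise ConfigError("read_times must be strictly increasing")
        if times[0] > 5.0 or times[-1] < 30.0:
            raise ConfigError("read_times must span at least the 5-30 min window")
        if 0.0 not in self.inhibitor_levels:
            raise ConfigError("inhibitor_levels must include 0 (control wells)")
        if any(s <= 0 for s in self.substrate_levels):
            raise ConfigError("substrate levels must be > 0")
        if any(i < 0 for i in self.inhibitor_levels):
            raise ConfigError("inhibitor levels must be >= 0")

    @property
    def n_wells(self) -> int:
        return len(self.substrate_levels) * len(self.inhibitor_levels) * self.replicates


@dataclass(frozen=True)
class NoiseModel:
    """Plate-reader noise: additive Gaussian reads, uniform well baselines."""

    absorbance_sd: float = 0.002  # AU per read
    baseline_range: tuple[float, float] = (0.04, 0.06)  # AU
    seed: int = 0

    def __post_init__(self) -> None:
        if self.absorbance_sd < 0:
            raise ConfigError("absorbance_sd must be >= 0")
        if self.baseline_range[1] < self.baseline_range[0]:
            raise ConfigError("baseline_range must be (lo, hi) with lo <= hi")


@dataclass(frozen=True)
class Well:
    well_id: str
    cond: Condition
    replicate: int
    absorbance: np.ndarray  # AU, aligned to the plate's read_times


@dataclass
class PlateTimeSeries:
    """Per-well absorbance traces plus optional embedded ground truth."""

    read_times: np.ndarray  # minutes
    wells: list[Well]
    truth: Optional[tuple[Mechanism, KineticParameters]] = None
    design: Optional[PlateDesign] = field(default=None, repr=False)


def simulate_plate(
    design: PlateDesign,
    mech: Mechanism,
    truth: KineticParameters,
    noise: NoiseModel = NoiseModel(),
    conversion: ConversionConstants = ConversionConstants(),
) -> PlateTimeSeries:
    """Generate one plate under *mech* with constants *truth*.

    Wells are laid out deterministically (substrate-major, then
    inhibitor, then replicate), so the same seed always produces the
    same plate byte for byte.
    """
    validate_params(truth, mech)
    k = conversion.slope_per_velocity
    if not k > 0:
        raise ConfigError("conversion factor must be > 0")
    rng = np.random.default_rng(noise.seed)
    times = np.asarray(design.read_times, dtype=float)
    wells: list[Well] = []
    idx = 0
    for S in design.substrate_levels:
        for I in design.inhibitor_levels:
            v = float(rate_law(truth.vmax, truth.km, truth.kic, truth.kiu, S, I))
            for rep in range(1, design.replicates + 1):
                idx += 1
                baseline = rng.uniform(*noise.baseline_range)
                eps = (
                    rng.normal(0.0, noise.absorbance_sd, size=times.size)
                    if noise.absorbance_sd > 0
                    else np.zeros_like(times)
                )
                trace = baseline + k * v * times + eps
                wells.append(
                    Well(
                        well_id=f"W{idx:03d}",
                        cond=Condition(S=S, I=I),
                        replicate=rep,
                        absorbance=trace,
                    )
                )
    return PlateTimeSeries(read_times=times, wells=wells, truth=(mech, truth), design=design)


# ---------------------------------------------------------------------------
# Published assay protocol and reference constants
# ---------------------------------------------------------------------------

#: Reference inhibitors of porcine pancreatic alpha-amylase with their
#: published mechanism, kinetic constants and tested inhibitor range.
#: B4, C5 and D11 are flavonoid inhibitors (competitive); acarbose is the
#: positive-control drug (mixed-type).  Constants: Vmax umol/min, Km mM,
#: Kic/Kiu uM.
REFERENCE_COMPOUNDS: dict[str, dict] = {
    "B4": {
        "mechanism": Mechanism.COMPETITIVE,
        "params": KineticParameters(vmax=12.0, km=1.2, kic=132.0),
        "inhibitor_levels": (0.0, 25.0, 50.0, 100.0, 200.0),
    },
    "C5": {
        "mechanism": Mechanism.COMPETITIVE,
        "params": KineticParameters(vmax=10.5, km=1.0, kic=71.0),
        "inhibitor_levels": (0.0, 12.5, 25.0, 50.0, 100.0),
    },
    "D11": {
        "mechanism": Mechanism.COMPETITIVE,
        "params": KineticParameters(vmax=15.0, km=1.1, kic=21.0),
        "inhibitor_levels": (0.0, 12.5, 25.0, 50.0, 100.0),
    },
    "acarbose": {
        "mechanism": Mechanism.MIXED,
        "params": KineticParameters(vmax=12.0, km=0.9, kic=6.0, kiu=0.71),
        "inhibitor_levels": (0.0, 0.25, 0.5, 1.0, 2.0),
    },
}


def protocol_design(compound_label: str, replicates: int = 3) -> PlateDesign:
    """Plate design for one of the reference inhibitors.

    Substrates are always 0.25/0.5/1 mM; the inhibitor ladder is a
    two-fold dilution series spanning the published tested range
    (0-200 uM for B4, 0-100 uM for C5 and D11, 0-2 uM for acarbose),
    always including the uninhibited control.
    """
    try:
        entry = REFERENCE_COMPOUNDS[compound_label]
    except KeyError:
        raise UnknownCompoundError(
            f"unknown compound {compound_label!r}; known: {sorted(REFERENCE_COMPOUNDS)}"
        ) from None
    return PlateDesign(
        substrate_levels=PROTOCOL_SUBSTRATES,
        inhibitor_levels=entry["inhibitor_levels"],
        replicates=replicates,
    )


def reference_truth(compound_label: str) -> tuple[Mechanism, KineticParameters]:
    """Published (mechanism, constants) for a reference inhibitor."""
    try:
        entry = REFERENCE_COMPOUNDS[compound_label]
    except KeyError:
        raise UnknownCompoundError(f"unknown compound {compound_label!r}") from None
    return entry["mechanism"], entry["params"]
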
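"""End-to-end orchestration: plate -> velocities -> IC50 -> mechanism.

A run is described by a :class:`RunConfig` that either points at a
measured plate (time-series CSV + layout CSV) or asks for a simulated
plate with known ground truth.  ``run_pipeline`` then chains:

    read/simulate -> extract velocities -> dose-response (IC50)
        -> fit cascade -> mechanism selection -> jackknife errors

persisting every intermediate as CSV so each reported number can be
recomputed from the stage outputs alone.  Given the same config and
seed, report bodies are byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .dose_response import DoseResponseResult, estimate_ic50, percent_inhibition
from .errors import ConfigError, InsufficientDataError
from .fitting import FitResult, fit_cascade
from .io import (
    fits_to_frame,
    read_plate,
    write_plate,
    write_selection_report,
    write_velocities,
)
from .jackknife import JackknifeReport, jackknife_sd
from .mechanisms import KineticParameters, Mechanism
from .rates import ConversionConstants, extract_velocities
from .selection import SelectionResult, select_mechanism
from .simulate import NoiseModel, protocol_design, reference_truth, simulate_plate

__all__ = ["RunConfig", "RunReport", "run_pipeline", "render_report"]

log = logging.getLogger("enzkin")


@dataclass
class RunConfig:
    """One pipeline run: measured input XOR simulation block."""

    # measured input
    plate_csv: Optional[str] = None
    layout_csv: Optional[str] = None
    # simulation block (reference compound shortcut)
    compound: Optional[str] = None
    replicates: int = 3
    noise_sd: float = 0.002
    baseline_range: tuple[float, float] = (0.04, 0.06)
    # analysis settings
    window: tuple[float, float] = (5.0, 30.0)
    alpha: float = 0.05
    dose_substrate: float = 0.5  # mM; substrate level used for IC50
    ic50_four_param: bool = False
    conversion: ConversionConstants = field(default_factory=ConversionConstants)
    seed: int = 0
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        has_files = self.plate_csv is not None or self.layout_csv is not None
        if has_files and (self.plate_csv is None or self.layout_csv is None):
            raise ConfigError("plate_csv and layout_csv must be given together")
        if has_files == (self.compound is not None):
            raise ConfigError("exactly one of {plate files, simulation compound} required")
        if self.compound is not None and self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.window[1] <= self.window[0]:
            raise ConfigError("window must be (lo, hi) with lo < hi")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if "conversion" in doc:
            doc["conversion"] = ConversionConstants(**doc["conversion"])
        for key in ("window", "baseline_range"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def digest(self) -> str:
        d = asdict(self)
        return hashlib.sha1(yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class RunReport:
    compound: str
    dose_response: Optional[DoseResponseResult]
    selection: SelectionResult
    jackknife: JackknifeReport
    fits: list[FitResult]
    provenance: dict


def run_pipeline(cfg: RunConfig) -> RunReport:
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    with _stage("acquire plate"):
        if cfg.compound is not None:
            mech, truth = reference_truth(cfg.compound)
            design = protocol_design(cfg.compound, replicates=cfg.replicates)
            noise = NoiseModel(
                absorbance_sd=cfg.noise_sd,
                baseline_range=cfg.baseline_range,
                seed=cfg.seed,
            )
            plate = simulate_plate(design, mech, truth, noise, cfg.conversion)
            label = cfg.compound
            if outdir:
                write_plate(
                    plate, outdir / "plate.csv", outdir / "layout.csv", outdir / "truth.yaml"
                )
        else:
            plate = read_plate(cfg.plate_csv, cfg.layout_csv)
            label = Path(cfg.plate_csv).stem
        log.info("plate: %d wells, %d reads/well", len(plate.wells), plate.read_times.size)

    with _stage("extract velocities"):
        extraction = extract_velocities(plate, cfg.window, cfg.conversion)
        obs = extraction.observations
        log.info("velocities: %d wells ok, %d failed", len(obs), len(extraction.failures))
        if outdir:
            write_velocities(obs, outdir / "velocities.csv")

    with _stage("dose-response"):
        dose = _dose_response(obs, cfg, label)
        if dose is not None and outdir:
            _write_dose(dose, outdir / "dose_response.csv")

    with _stage("fit cascade"):
        fits = fit_cascade(obs, seed=cfg.seed)
        log.info("fits: %s", {f.mech.value: round(f.ssr, 6) for f in fits})

    with _stage("model selection"):
        selection = select_mechanism(fits, alpha=cfg.alpha)
        log.info("selected mechanism: %s", selection.chosen.value)

    with _stage("jackknife"):
        chosen_fit = next(f for f in fits if f.mech is selection.chosen)
        jk = jackknife_sd(obs, selection.chosen, full_fit=chosen_fit, seed=cfg.seed)

    if outdir:
        fits_to_frame(fits, jk).to_csv(outdir / "fits.csv", index=False)
        write_selection_report(selection, fits, outdir / "selection.csv", outdir / "f_tests.csv")

    report = RunReport(
        compound=label,
        dose_response=dose,
        selection=selection,
        jackknife=jk,
        fits=fits,
        provenance={"seed": cfg.seed, "config": cfg.digest(), "version": __version__},
    )
    if outdir:
        (outdir / "report.txt").write_text(render_report(report))
    return report


def _dose_response(obs, cfg: RunConfig, label: str) -> Optional[DoseResponseResult]:
    """Percent inhibition vs concentration at the IC50 substrate level."""
    at_s = [o for o in obs if o.cond.S == cfg.dose_substrate]
    controls = {o.replicate: o.v for o in at_s if o.cond.I == 0}
    conc, pct, reps = [], [], []
    for o in at_s:
        v0 = controls.get(o.replicate)
        if v0 is None or v0 <= 0:
            continue
        conc.append(o.cond.I)
        pct.append(percent_inhibition(o.v, v0))
        reps.append(o.replicate)
    try:
        return estimate_ic50(
            conc, pct, replicates=reps, compound=label, four_param=cfg.ic50_four_param
        )
    except InsufficientDataError as exc:
        log.warning("dose-response skipped: %s", exc)
        return None


def _write_dose(dose: DoseResponseResult, path: Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "compound": dose.compound,
                "reported_as": dose.reported_as,
                "ic50_uM": dose.ic50,
                "se": dose.ic50_se,
                "pct_at_top": dose.pct_at_top,
                "top_conc_uM": dose.top_conc,
            }
        ]
    ).to_csv(path, index=False)


def render_report(report: RunReport) -> str:
    """Deterministic plain-text summary (no timestamps in the body)."""
    lines = [f"compound: {report.compound}"]
    dose = report.dose_response
    if dose is not None:
        if dose.reported_as == "IC50":
            se = f" +/- {dose.ic50_se:.4g}" if dose.ic50_se is not None else ""
            lines.append(f"IC50: {dose.ic50:.4g}{se} uM (hill {dose.hill:.3g})")
        else:
            lines.append(
                f"inhibition at {dose.top_conc:g} uM: {dose.pct_at_top:.1f} % (below 50%)"
            )
    sel = report.selection
    lines.append(f"mechanism: {sel.chosen.value} (alpha {sel.alpha:g})")
    jk = report.jackknife
    chosen_fit = next(f for f in report.fits if f.mech is sel.chosen)
    p = chosen_fit.params.as_dict()
    shown = {"vmax": "Vmax (umol/min)", "km": "Km (mM)", "kic": "Kic (uM)", "kiu": "Kiu (uM)"}
    sd = dict(jk.sd)
    if "ki" in sd:
        sd["kic"] = sd["kiu"] = sd.pop("ki")
    for key, title in shown.items():
        if p[key] is not None:
            lines.append(f"  {title}: {p[key]:.4g} +/- {sd.get(key, float('nan')):.2g}")
    lines.append("AICc:")
    best = min(sel.aicc_table.values())
    for f in report.fits:
        score = sel.aicc_table[f.mech]
        lines.append(
            f"  {f.mech.value:>14s}  ssr {f.ssr:.4g}  aicc {score:.2f}  delta {score - best:.2f}"
        )
    lines.append(
        f"provenance: seed {report.provenance['seed']} config {report.provenance['config']} "
        f"version {report.provenance['version']}"
    )
    return "\n".join(lines) + "\n"


class _stage:
    """Context manager logging a stage name and wall time to stderr."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s ...", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is None:
            log.info("stage %s done in %.2fs", self.name, dt)
        else:
            log.error("stage %s failed after %.2fs: %s", self.name, dt, exc)
        return False
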
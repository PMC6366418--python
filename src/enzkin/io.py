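"""CSV input/output for plates, velocities, fits and reports.

Dialect: UTF-8, comma-separated, mandatory header row, '.' decimal,
no thousands separators, times in minutes as floats.

Plate data travel as a pair of files: a tidy time-series CSV
(``time_min, well_id, absorbance``) and a layout CSV mapping wells to
conditions (``well_id, substrate_mM, inhibitor_uM, replicate``).  An
optional truth sidecar (YAML key: value) records the generating
mechanism and constants of a simulated plate.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .errors import PlateParseError
from .fitting import FitResult
from .jackknife import JackknifeReport
from .mechanisms import Condition
from .rates import VelocityObservation
from .selection import SelectionResult
from .simulate import PlateTimeSeries, Well

__all__ = [
    "write_plate",
    "read_plate",
    "write_velocities",
    "read_velocities",
    "fits_to_frame",
    "write_selection_report",
]

PathLike = Union[str, Path]

PLATE_COLUMNS = ["time_min", "well_id", "absorbance"]
LAYOUT_COLUMNS = ["well_id", "substrate_mM", "inhibitor_uM", "replicate"]
VELOCITY_COLUMNS = [
    "substrate_mM", "inhibitor_uM", "replicate", "v_umol_min", "slope_AU_min", "r2", "well_id",
]


def write_plate(
    plate: PlateTimeSeries,
    plate_csv: PathLike,
    layout_csv: PathLike,
    truth_path: Optional[PathLike] = None,
) -> None:
    rows = [
        (t, w.well_id, a)
        for w in plate.wells
        for t, a in zip(plate.read_times, w.absorbance)
    ]
    pd.DataFrame(rows, columns=PLATE_COLUMNS).to_csv(plate_csv, index=False)
    layout = pd.DataFrame(
        [(w.well_id, w.cond.S, w.cond.I, w.replicate) for w in plate.wells],
        columns=LAYOUT_COLUMNS,
    )
    layout.to_csv(layout_csv, index=False)
    if truth_path is not None and plate.truth is not None:
        mech, params = plate.truth
        doc = {"mechanism": mech.value, **{k: v for k, v in params.as_dict().items() if v is not None}}
        Path(truth_path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_plate(plate_csv: PathLike, layout_csv: PathLike) -> PlateTimeSeries:
    """Join the tidy time-series CSV with its layout into a validated plate.

    Raises :class:`PlateParseError` on missing columns, duplicated
    (well, time) rows (naming the offending CSV rows), or any mismatch
    between the wells present in the two files.
    """
    plate_df = pd.read_csv(plate_csv, float_precision="round_trip")
    layout_df = pd.read_csv(layout_csv, float_precision="round_trip")
    _require_columns(plate_df, PLATE_COLUMNS, plate_csv)
    _require_columns(layout_df, LAYOUT_COLUMNS, layout_csv)

    dup = plate_df.duplicated(subset=["well_id", "time_min"], keep=False)
    if dup.any():
        rows = (plate_df.index[dup] + 2).tolist()  # 1-based, after header
        raise PlateParseError(f"duplicated (well_id, time_min) rows in {plate_csv}: rows {rows}")
    dup_layout = layout_df.duplicated(subset=["well_id"], keep=False)
    if dup_layout.any():
        rows = (layout_df.index[dup_layout] + 2).tolist()
        raise PlateParseError(f"duplicated well_id in {layout_csv}: rows {rows}")

    plate_wells = set(plate_df["well_id"])
    layout_wells = set(layout_df["well_id"])
    if plate_wells != layout_wells:
        only_plate = sorted(plate_wells - layout_wells)
        only_layout = sorted(layout_wells - plate_wells)
        raise PlateParseError(
            f"well mismatch between plate and layout: "
            f"only in plate {only_plate}, only in layout {only_layout}"
        )

    times = np.sort(plate_df["time_min"].unique())
    wells: list[Well] = []
    grouped = plate_df.sort_values("time_min").groupby("well_id", sort=True)
    meta = layout_df.set_index("well_id")
    for well_id, g in grouped:
        if not np.array_equal(g["time_min"].to_numpy(), times):
            raise PlateParseError(f"well {well_id} does not cover the common read times")
        row = meta.loc[well_id]
        wells.append(
            Well(
                well_id=str(well_id),
                cond=Condition(S=float(row["substrate_mM"]), I=float(row["inhibitor_uM"])),
                replicate=int(row["replicate"]),
                absorbance=g["absorbance"].to_numpy(dtype=float),
            )
        )
    return PlateTimeSeries(read_times=times.astype(float), wells=wells)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: PathLike) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise PlateParseError(f"missing columns in {path}: {missing}")


def write_velocities(obs: Sequence[VelocityObservation], path: PathLike) -> None:
    df = pd.DataFrame(
        [
            (o.cond.S, o.cond.I, o.replicate, o.v, o.slope, o.r_squared, o.well_id or "")
            for o in obs
        ],
        columns=VELOCITY_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_velocities(path: PathLike) -> list[VelocityObservation]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, VELOCITY_COLUMNS[:-1], path)
    return [
        VelocityObservation(
            cond=Condition(S=float(r.substrate_mM), I=float(r.inhibitor_uM)),
            replicate=int(r.replicate),
            v=float(r.v_umol_min),
            slope=float(r.slope_AU_min),
            r_squared=float(r.r2),
            well_id=str(getattr(r, "well_id", "")) or None,
        )
        for r in df.itertuples(index=False)
    ]


def fits_to_frame(
    fits: Sequence[FitResult], jk: Optional[JackknifeReport] = None
) -> pd.DataFrame:
    """Fits table in published-constants layout (one row per mechanism).

    With a jackknife report for the selected mechanism, ``*_sd`` columns
    carry its leave-one-out standard deviations on that row.
    """
    rows = []
    for f in fits:
        p = f.params.as_dict()
        row = {
            "mechanism": f.mech.value,
            "Vmax": p["vmax"],
            "Km": p["km"],
            "Kic": p["kic"],
            "Kiu": p["kiu"],
            "ssr": f.ssr,
            "n": f.n_obs,
            "k": f.k_params,
            "converged": f.converged,
            "Vmax_sd": np.nan,
            "Km_sd": np.nan,
            "Kic_sd": np.nan,
            "Kiu_sd": np.nan,
        }
        if jk is not None and f.mech is jk.mech:
            sd = dict(jk.sd)
            if "ki" in sd:  # shared noncompetitive constant fills both slots
                sd["kic"] = sd["kiu"] = sd.pop("ki")
            row.update(
                Vmax_sd=sd.get("vmax", np.nan),
                Km_sd=sd.get("km", np.nan),
                Kic_sd=sd.get("kic", np.nan),
                Kiu_sd=sd.get("kiu", np.nan),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def write_selection_report(
    selection: SelectionResult, fits: Sequence[FitResult], path: PathLike,
    f_table_path: Optional[PathLike] = None,
) -> None:
    scores = selection.aicc_table
    best = min(scores.values())
    df = pd.DataFrame(
        [
            {
                "mechanism": f.mech.value,
                "ssr": f.ssr,
                "aicc": scores[f.mech],
                "delta_aicc": scores[f.mech] - best,
                "chosen": f.mech is selection.chosen,
            }
            for f in fits
        ]
    )
    df.to_csv(path, index=False)
    if f_table_path is not None:
        ft = pd.DataFrame(
            [
                {
                    "simple": t.simple_mech.value,
                    "complex": t.complex_mech.value,
                    "f_stat": t.f_stat,
                    "df_num": t.df_num,
                    "df_den": t.df_den,
                    "p_value": t.p_value,
                    "prefer_complex": t.prefer_complex,
                }
                for t in selection.f_tests
            ]
        )
        ft.to_csv(f_table_path, index=False)
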
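"""Delimited-text I/O for peak tables, standards, metadata, and growth data.

All tables are tab-separated with a header row; headers are matched
case-insensitively and the decimal separator is '.'. Row-level problems
are collected and reported together with 1-based line numbers so a bad
export fails loudly and completely.

Peak table schema:
    run_id  injection  compound  rt_s  amplitude_mV  area_Vs
    d2H_raw_permil  [is_standard  sample_id  treatment  replicate]

Metadata schema:
    culture_id  experiment  treatment  level  replicate  d2H_water_permil
    [d2H_water_sd  culture_type  dilution_td_h]

Growth schema:
    culture_id  time_h  od600
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import GrowthCurve, PeakMeasurement, StandardDefinition
from .exceptions import SchemaError

__all__ = [
    "read_peak_table",
    "write_peak_table",
    "read_metadata",
    "read_growth",
    "write_growth_table",
    "read_standard_definitions",
    "write_standard_definitions",
]

PEAK_REQUIRED = [
    "run_id",
    "injection",
    "compound",
    "rt_s",
    "amplitude_mv",
    "area_vs",
    "d2h_raw_permil",
]
META_REQUIRED = ["culture_id", "experiment", "treatment", "level", "d2h_water_permil"]
GROWTH_REQUIRED = ["culture_id", "time_h", "od600"]


def _load(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s): {', '.join(missing)}")
    return df


def _numeric(df: pd.DataFrame, cols: Sequence[str], path_name: str) -> tuple[pd.DataFrame, list[str]]:
    errors = []
    for col in cols:
        if col not in df.columns:
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & converted.isna()
        for i in df.index[bad]:
            errors.append(
                f"{path_name} line {i + 2}: non-numeric value {df.at[i, col]!r} in column {col}"
            )
        df[col] = converted
    return df, errors


def read_peak_table(
    path: str | Path, is_standard: Optional[bool] = None
) -> list[PeakMeasurement]:
    """Read a peak table; optionally force the is_standard flag."""
    path = Path(path)
    df = _load(path, PEAK_REQUIRED)
    df, errors = _numeric(
        df, ["injection", "rt_s", "amplitude_mv", "area_vs", "d2h_raw_permil"], path.name
    )
    peaks: list[PeakMeasurement] = []
    for i, row in df.iterrows():
        try:
            std_flag = is_standard
            if std_flag is None:
                std_flag = str(row.get("is_standard", "")).strip().lower() in (
                    "1",
                    "true",
                    "yes",
                )
            rep = row.get("replicate")
            peaks.append(
                PeakMeasurement(
                    run_id=str(row["run_id"]),
                    injection=int(row["injection"]),
                    compound=str(row["compound"]),
                    amplitude=float(row["amplitude_mv"]),
                    rt_s=float(row["rt_s"]),
                    area_Vs=float(row["area_vs"]),
                    d2H_raw=float(row["d2h_raw_permil"]),
                    is_standard=bool(std_flag),
                    sample_id=None if pd.isna(row.get("sample_id")) else str(row.get("sample_id")),
                    treatment=None if pd.isna(row.get("treatment")) else str(row.get("treatment")),
                    replicate=None if rep is None or pd.isna(rep) else int(float(rep)),
                )
            )
        except (TypeError, ValueError) as exc:
            errors.append(f"{path.name} line {i + 2}: {exc}")
    if errors:
        raise SchemaError("peak table validation failed:\n  " + "\n  ".join(errors))
    return peaks


def write_peak_table(peaks: Iterable[PeakMeasurement], path: str | Path) -> None:
    rows = [
        {
            "run_id": p.run_id,
            "injection": p.injection,
            "compound": p.compound,
            "rt_s": p.rt_s,
            "amplitude_mV": p.amplitude,
            "area_Vs": p.area_Vs,
            "d2H_raw_permil": p.d2H_raw,
            "is_standard": p.is_standard,
            "sample_id": p.sample_id,
            "treatment": p.treatment,
            "replicate": p.replicate,
        }
        for p in peaks
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Per-culture metadata: treatment design, water δ²H, culture type."""
    path = Path(path)
    df = _load(path, META_REQUIRED)
    df, errors = _numeric(
        df, ["level", "replicate", "d2h_water_permil", "d2h_water_sd", "dilution_td_h"], path.name
    )
    if errors:
        raise SchemaError("metadata validation failed:\n  " + "\n  ".join(errors))
    if "culture_type" not in df.columns:
        df["culture_type"] = "batch"
    df["culture_type"] = df["culture_type"].fillna("batch")
    if "d2h_water_sd" not in df.columns:
        df["d2h_water_sd"] = np.nan
    return df


def read_growth(path: str | Path) -> dict[str, GrowthCurve]:
    """Read the long-format growth table into per-culture curves."""
    path = Path(path)
    df = _load(path, GROWTH_REQUIRED)
    df, errors = _numeric(df, ["time_h", "od600"], path.name)
    if errors:
        raise SchemaError("growth table validation failed:\n  " + "\n  ".join(errors))
    curves: dict[str, GrowthCurve] = {}
    for culture, sub in df.groupby("culture_id", sort=False):
        sub = sub.sort_values("time_h")
        try:
            curves[str(culture)] = GrowthCurve(
                culture_id=str(culture),
                times=sub["time_h"].to_numpy(float),
                od600=sub["od600"].to_numpy(float),
            )
        except ValueError as exc:
            raise SchemaError(f"{path.name}: {exc}") from exc
    return curves


def write_growth_table(curves: Iterable[GrowthCurve], path: str | Path) -> None:
    rows = []
    for c in curves:
        for t, od in zip(c.times, c.od600):
            rows.append({"culture_id": c.culture_id, "time_h": t, "od600": od})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_standard_definitions(path: str | Path) -> list[StandardDefinition]:
    """Two/three-column file: compound, accepted δ²H (‰ VSMOW)[, 1σ]."""
    path = Path(path)
    df = _load(path, ["compound", "accepted_d2h_permil"])
    df, errors = _numeric(df, ["accepted_d2h_permil", "accepted_sigma"], path.name)
    if errors:
        raise SchemaError("standards definitions validation failed:\n  " + "\n  ".join(errors))
    out = []
    for _, row in df.iterrows():
        sigma = row.get("accepted_sigma")
        out.append(
            StandardDefinition(
                compound=str(row["compound"]),
                accepted_d2H=float(row["accepted_d2h_permil"]),
                accepted_sigma=0.0 if sigma is None or pd.isna(sigma) else float(sigma),
            )
        )
    return out


def write_standard_definitions(
    defs: Iterable[StandardDefinition], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "compound": d.compound,
                "accepted_d2H_permil": d.accepted_d2H,
                "accepted_sigma": d.accepted_sigma,
            }
            for d in defs
        ]
    ).to_csv(path, sep="\t", index=False)
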
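"""Delimited-text I/O for alignment records, summaries and patient cohorts.

All tabular artefacts are plain CSV.  Writers may prepend ``#``-prefixed
comment lines carrying the seed and generator parameters; readers skip them.
Schema violations are reported with 1-based data row numbers.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .acquisition import AlignmentRecord
from .exceptions import SchemaError
from .margins import ConditionSummary, MarginResult
from .synthetic import PatientFractionRecord
from .workflow import ShiftTriplet

__all__ = [
    "ALIGNMENT_COLUMNS",
    "PATIENT_COLUMNS",
    "alignment_frame",
    "write_alignment_csv",
    "read_alignment_csv",
    "patient_frame",
    "write_patient_csv",
    "read_patient_csv",
    "summary_frame",
    "margin_frame",
    "render_summary_report",
    "render_margin_report",
]

ALIGNMENT_COLUMNS = [
    "protocol",
    "amplitude_mm",
    "rate_bpm",
    "repeat",
    "direction",
    "start_phase_s",
    "signed_error_mm",
    "abs_error_mm",
]

PATIENT_COLUMNS = [
    "patient_id",
    "fraction",
    "modality",
    "bone_lat_mm",
    "bone_long_mm",
    "bone_vert_mm",
    "gtv_lat_mm",
    "gtv_long_mm",
    "gtv_vert_mm",
]


def _header_comment(metadata: Mapping | None) -> str:
    if not metadata:
        return ""
    return "# " + json.dumps(dict(metadata), sort_keys=True) + "\n"


def alignment_frame(records: Iterable[AlignmentRecord]) -> pd.DataFrame:
    rows = [
        {
            "protocol": r.protocol,
            "amplitude_mm": r.amplitude_mm,
            "rate_bpm": r.rate_bpm,
            "repeat": r.repeat_index,
            "direction": r.direction,
            "start_phase_s": r.start_phase_s,
            "signed_error_mm": r.signed_error_mm,
            "abs_error_mm": r.abs_error_mm,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


def write_alignment_csv(
    records: Iterable[AlignmentRecord],
    path: str | Path,
    metadata: Mapping | None = None,
) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(_header_comment(metadata))
        alignment_frame(records).to_csv(fh, index=False, float_format="%.17g")
    return path


def _check_columns(df: pd.DataFrame, expected: list[str], what: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s): {missing}")


def read_alignment_csv(path: str | Path) -> list[AlignmentRecord]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    _check_columns(df, ALIGNMENT_COLUMNS, "alignment CSV")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            rec = AlignmentRecord(
                protocol=str(row.protocol),
                amplitude_mm=float(row.amplitude_mm),
                rate_bpm=float(row.rate_bpm),
                repeat_index=int(row.repeat),
                direction=str(row.direction),
                start_phase_s=float(row.start_phase_s),
                signed_error_mm=float(row.signed_error_mm),
            )
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"alignment CSV row {i}: {exc}") from exc
        if not np.isclose(rec.abs_error_mm, float(row.abs_error_mm)):
            raise SchemaError(
                f"alignment CSV row {i}: abs_error_mm is not |signed_error_mm|"
            )
        records.append(rec)
    return records


def patient_frame(records: Iterable[PatientFractionRecord]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": r.patient_id,
            "fraction": r.fraction_index,
            "modality": r.modality,
            "bone_lat_mm": r.bone.lateral_mm,
            "bone_long_mm": r.bone.longitudinal_mm,
            "bone_vert_mm": r.bone.vertical_mm,
            "gtv_lat_mm": r.gtv.lateral_mm,
            "gtv_long_mm": r.gtv.longitudinal_mm,
            "gtv_vert_mm": r.gtv.vertical_mm,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=PATIENT_COLUMNS)


def write_patient_csv(
    records: Iterable[PatientFractionRecord],
    path: str | Path,
    metadata: Mapping | None = None,
) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(_header_comment(metadata))
        patient_frame(records).to_csv(fh, index=False, float_format="%.17g")
    return path


def read_patient_csv(path: str | Path) -> list[PatientFractionRecord]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    _check_columns(df, PATIENT_COLUMNS, "patient CSV")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                PatientFractionRecord(
                    patient_id=str(row.patient_id),
                    fraction_index=int(row.fraction),
                    modality=str(row.modality),
                    bone=ShiftTriplet(
                        float(row.bone_lat_mm),
                        float(row.bone_long_mm),
                        float(row.bone_vert_mm),
                    ),
                    gtv=ShiftTriplet(
                        float(row.gtv_lat_mm),
                        float(row.gtv_long_mm),
                        float(row.gtv_vert_mm),
                    ),
                )
            )
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"patient CSV row {i}: {exc}") from exc
    return records


def summary_frame(summaries: Iterable[ConditionSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protocol": s.protocol,
                "amplitude_mm": s.amplitude_mm,
                "rate_bpm": s.rate_bpm,
                "n": s.n,
                "sigma_sys_mm": s.sigma_sys_mm,
                "sigma_rand_mm": s.sigma_rand_mm,
            }
            for s in summaries
        ]
    )


def margin_frame(results: Iterable[MarginResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protocol": r.protocol,
                "amplitude_mm": r.amplitude_mm,
                "rate_bpm": r.rate_bpm,
                "margin_mm": r.margin_mm,
                "margin_mm_exact": r.margin_mm_exact,
            }
            for r in results
        ]
    )


def _pivot(df: pd.DataFrame, value: str, fmt: str) -> str:
    """Amplitude rows x rate columns x protocol text table."""
    wide = df.pivot_table(
        index=["amplitude_mm", "protocol"],
        columns="rate_bpm",
        values=value,
        aggfunc="first",
        sort=True,
    )
    wide = wide[sorted(wide.columns, reverse=True)]  # high rate first
    wide.columns = [f"{c:g} BPM" for c in wide.columns]
    return wide.to_string(float_format=lambda x: fmt % x)


def render_summary_report(summaries: Iterable[ConditionSummary]) -> str:
    df = summary_frame(summaries)
    df["cell"] = df.apply(
        lambda r: f"{r.sigma_sys_mm:.1f} ({r.sigma_rand_mm:.2f})", axis=1
    )
    wide = df.pivot_table(
        index=["amplitude_mm", "protocol"],
        columns="rate_bpm",
        values="cell",
        aggfunc="first",
        sort=True,
    )
    wide = wide[sorted(wide.columns, reverse=True)]
    wide.columns = [f"{c:g} BPM" for c in wide.columns]
    return (
        "Per-condition systematic Sigma (random sigma) of longitudinal "
        "alignments, mm\n\n" + wide.to_string()
    )


def render_margin_report(results: Iterable[MarginResult]) -> str:
    df = margin_frame(results)
    body = _pivot(df, "margin_mm", "%.1f")
    maxima = df.groupby("protocol")["margin_mm"].max()
    lines = [f"  {p}: {m:.1f} mm" for p, m in maxima.items()]
    return (
        "Estimated PTV margins (mm), quadrature-baseline recipe\n\n"
        + body
        + "\n\nPer-protocol maximum margin:\n"
        + "\n".join(lines)
    )
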
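"""CSV / JSON interchange.

The on-disk formats mirror the workflow's spreadsheets:

* color tables: ``id,R,G,B`` (one row per sample);
* calibration tables: ``level,R,G,B`` (repeated rows are replicates);
* correction models: JSON with row-major ``M1``, ``M2``, fit metadata;
* screening reports: JSON with kept / rejected lists.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .chart import ChartEntry, ReferenceChart, ScreeningResult
from .correction import AffineColorCorrection, ColorPairSet
from .exceptions import EmptyInputError, JoinError

__all__ = [
    "read_color_table",
    "write_color_table",
    "read_chart",
    "write_chart",
    "read_pairs",
    "pairs_from_tables",
    "read_calibration_table",
    "save_model",
    "load_model",
    "write_screening_report",
]

_COLOR_COLUMNS = ["id", "R", "G", "B"]


def read_color_table(path, allow_duplicates: bool = False) -> pd.DataFrame:
    """Read an ``id,R,G,B`` CSV; validates header and channel ranges.

    ``allow_duplicates=True`` permits repeated ids (replicate measurements
    of the same sample, as in quantitation inputs).
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: empty file") from exc
    missing = [c for c in _COLOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; expected id,R,G,B")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: color table has no rows")
    rgb = df[["R", "G", "B"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(rgb)) or rgb.min() < 0 or rgb.max() > 255:
        raise ValueError(f"{path}: RGB values must be finite and within [0, 255]")
    df["id"] = df["id"].astype(str)
    if not allow_duplicates and df["id"].duplicated().any():
        dupes = sorted(df.loc[df["id"].duplicated(), "id"].unique())
        raise ValueError(f"{path}: duplicate ids {dupes}")
    return df[_COLOR_COLUMNS]


def write_color_table(path, ids, rgb) -> None:
    rgb = np.atleast_2d(np.asarray(rgb))
    pd.DataFrame(
        {"id": list(ids), "R": rgb[:, 0], "G": rgb[:, 1], "B": rgb[:, 2]}
    ).to_csv(path, index=False)


def read_chart(path, name: str | None = None) -> ReferenceChart:
    df = read_color_table(path)
    entries = [
        ChartEntry(row.id, (int(row.R), int(row.G), int(row.B)))
        for row in df.itertuples()
    ]
    return ReferenceChart(entries, name=name or Path(path).stem)


def write_chart(path, chart: ReferenceChart) -> None:
    write_color_table(path, chart.ids, chart.rgb_array.astype(int))


def pairs_from_tables(
    measured: pd.DataFrame, reference: pd.DataFrame, provenance: str = ""
) -> ColorPairSet:
    """Inner-join measured and reference tables on ``id``.

    Ids present on only one side are reported (not silently dropped).
    """
    m_ids, r_ids = set(measured["id"]), set(reference["id"])
    orphans_m = sorted(m_ids - r_ids)
    orphans_r = sorted(r_ids - m_ids)
    if orphans_m or orphans_r:
        raise JoinError(
            f"ids do not match: {len(orphans_m)} only in measured "
            f"{orphans_m[:5]}, {len(orphans_r)} only in reference {orphans_r[:5]}"
        )
    merged = measured.merge(reference, on="id", suffixes=("_m", "_r"))
    return ColorPairSet(
        ids=merged["id"].tolist(),
        measured=merged[["R_m", "G_m", "B_m"]].to_numpy(dtype=float),
        reference=merged[["R_r", "G_r", "B_r"]].to_numpy(dtype=float),
        provenance=provenance,
    )


def read_pairs(measured_path, reference_path) -> ColorPairSet:
    return pairs_from_tables(
        read_color_table(measured_path),
        read_color_table(reference_path),
        provenance=f"measured={measured_path} reference={reference_path}",
    )


def read_calibration_table(path) -> pd.DataFrame:
    """Read a ``level,R,G,B`` CSV (repeated levels are replicates)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: empty file") from exc
    needed = ["level", "R", "G", "B"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; expected level,R,G,B")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: calibration table has no rows")
    return df[needed].astype(float)


def save_model(path, model: AffineColorCorrection) -> None:
    Path(path).write_text(model.to_json() + "\n")


def load_model(path) -> AffineColorCorrection:
    return AffineColorCorrection.from_json(Path(path).read_text())


def write_screening_report(path, result: ScreeningResult, config: dict | None = None) -> None:
    payload = result.to_dict()
    if config:
        payload["config"] = config
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
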
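"""Plain-text interchange formats.

Chromatograms are two-column CSV (``time_min,absorbance_mau``) with
``#``-prefixed ``key: value`` metadata header lines; peak tables, the
common-peak matrix, fingerprints, similarity and precision reports are
ordinary CSV with documented headers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import Chromatogram, Peak, PeakTable
from .exceptions import EmptyDataError, NonMonotoneTimeError
from .fingerprint import CommonPeakMatrix, ReferenceFingerprint


def write_chromatogram_csv(chrom: Chromatogram, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for key, val in chrom.meta.items():
            fh.write(f"# {key}: {val}\n")
        fh.write("time_min,absorbance_mau\n")
        for t, y in zip(chrom.time_min, chrom.absorbance_mau):
            fh.write(f"{t:.9f},{y:.9f}\n")


def read_chromatogram_csv(path) -> Chromatogram:
    path = Path(path)
    meta: dict = {}
    times, values = [], []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, val = body.split(":", 1)
                    meta[key.strip()] = val.strip()
                continue
            if line.lower().startswith("time"):
                continue
            parts = line.split(",")
            try:
                t, y = float(parts[0]), float(parts[1])
            except (ValueError, IndexError) as err:
                raise ValueError(f"{path}: bad numeric row at line {lineno}") from err
            if times and t <= times[-1]:
                raise NonMonotoneTimeError(
                    f"{path}: non-increasing time at line {lineno}"
                )
            times.append(t)
            values.append(y)
    if not times:
        raise EmptyDataError(f"{path}: no data rows")
    return Chromatogram(np.array(times), np.array(values), meta)


def write_peak_table_csv(table: PeakTable, path) -> None:
    rows = [
        {"sample_id": table.sample_id, "group": table.group or "",
         "apex_rt_min": p.apex_rt_min, "left_rt_min": p.left_rt_min,
         "right_rt_min": p.right_rt_min, "height_mau": p.height,
         "area": p.area}
        for p in table
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_peak_table_csv(path) -> list[PeakTable]:
    df = pd.read_csv(path)
    if df.empty:
        raise EmptyDataError(f"{path}: no peaks")
    tables = []
    for sid, sub in df.groupby("sample_id", sort=False):
        group = sub["group"].iloc[0]
        group = None if (pd.isna(group) or group == "") else str(group)
        peaks = [
            Peak(r.apex_rt_min, r.left_rt_min, r.right_rt_min,
                 r.height_mau, r.area)
            for r in sub.itertuples()
        ]
        tables.append(PeakTable(str(sid), peaks, group))
    return tables


def write_peak_tables_csv(tables: list[PeakTable], path) -> None:
    frames = []
    for t in tables:
        frames.append(pd.DataFrame([
            {"sample_id": t.sample_id, "group": t.group or "",
             "apex_rt_min": p.apex_rt_min, "left_rt_min": p.left_rt_min,
             "right_rt_min": p.right_rt_min, "height_mau": p.height,
             "area": p.area} for p in t
        ]))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_matrix_csv(matrix: CommonPeakMatrix, path) -> None:
    out = matrix.areas.copy()
    out.insert(0, "group", matrix.groups.loc[out.index])
    out.index.name = "sample_id"
    out.to_csv(path)


def read_matrix_csv(path) -> CommonPeakMatrix:
    df = pd.read_csv(path, index_col="sample_id")
    if df.empty:
        raise EmptyDataError(f"{path}: empty matrix")
    groups = df["group"]
    areas = df.drop(columns=["group"])
    # consensus RTs are not stored in the matrix CSV; use ordinal placeholders
    return CommonPeakMatrix(areas, np.arange(1, areas.shape[1] + 1, dtype=float),
                            groups, 1.0)


def write_fingerprint_csv(fp: ReferenceFingerprint, path) -> None:
    pd.DataFrame({
        "peak_id": fp.peak_ids,
        "consensus_rt_min": fp.consensus_rts,
        "mean_area": fp.mean_areas,
    }).to_csv(path, index=False)


def write_ground_truth_csv(truth, path) -> None:
    truth.table.to_csv(path, index=False)
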
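"""Tab-separated readers/writers for the pipeline's tables.

The cell table is the central exchange format: one row per labeled cell
with identity, position (section index under the "first labeled section =
0 um" origin, region among UL/LL/CC), a cell-type label, and the 12
compartment intensities.  Validation is strict and reports the offending
line; unknown columns are preserved through the whole pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._schema import INTENSITY_COLUMNS, REGIONS, REQUIRED_COLUMNS


class CellTableError(ValueError):
    """Schema violation in a cell table, with the offending row named."""


def validate_cell_table(cells: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in cells.columns]
    if missing:
        raise CellTableError(f"missing required column(s): {missing}")
    for col in INTENSITY_COLUMNS:
        vals = pd.to_numeric(cells[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            raise CellTableError(
                f"non-numeric intensity in column {col!r} at row {int(bad.idxmax())}"
            )
        neg = vals < 0
        if neg.any():
            raise CellTableError(
                f"negative intensity in column {col!r} at row {int(neg.idxmax())}"
            )
    if (cells["section_index"].astype(int) < 0).any():
        row = int((cells["section_index"].astype(int) < 0).idxmax())
        raise CellTableError(f"negative section_index at row {row}")
    bad_region = ~cells["region"].isin(REGIONS)
    if bad_region.any():
        row = int(bad_region.idxmax())
        raise CellTableError(
            f"unknown region {cells['region'].iloc[row]!r} at row {row}"
        )
    dup = cells.duplicated(subset=["animal_id", "cell_id"])
    if dup.any():
        row = int(dup.idxmax())
        raise CellTableError(
            f"duplicate cell_id {cells['cell_id'].iloc[row]!r} within animal at row {row}"
        )


def read_cell_table(path) -> pd.DataFrame:
    """Read and validate a cell-table TSV; unknown columns are kept."""
    cells = pd.read_csv(
        path, sep="\t",
        dtype={"cell_id": str, "animal_id": str, "barcode": str},
        float_precision="round_trip",
    )
    validate_cell_table(cells)
    cells["section_index"] = cells["section_index"].astype(int)
    return cells


def write_cell_table(path, cells: pd.DataFrame) -> None:
    validate_cell_table(cells)
    # %.17g guarantees float64 round-trips bit-exactly through the TSV
    cells.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_clone_table(path) -> pd.DataFrame:
    clones = pd.read_csv(path, sep="\t", dtype={"barcode": str})
    required = {"clone_id", "barcode", "n_cells", "cell_ids"}
    missing = required - set(clones.columns)
    if missing:
        raise CellTableError(f"clone table missing column(s): {sorted(missing)}")
    return clones


def write_clone_table(path, clones: pd.DataFrame) -> None:
    clones.to_csv(path, sep="\t", index=False)


def write_ground_truth(path, truth) -> None:
    truth.assignments.to_csv(path, sep="\t", index=False)


def read_ground_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"cell_id": str})


def write_cohort_report(prefix, report: dict) -> list[str]:
    """Write a cohort report as TSVs plus a structured JSON summary.

    ``prefix`` is a path stem; returns the files written.
    """
    import json
    from pathlib import Path

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    for key in ("composition", "by_class", "by_uniformity", "size_vs_dispersion"):
        p = prefix.with_name(prefix.name + f"_{key}.tsv")
        report[key].to_csv(p, sep="\t", index=False)
        written.append(str(p))
    summary = {
        "n_clones": report["n_clones"],
        "n_cells": report["n_cells"],
        "composition": report["composition"].to_dict(orient="records"),
        "by_class": report["by_class"].replace({np.nan: None}).to_dict(orient="records"),
        "by_uniformity": report["by_uniformity"].replace({np.nan: None}).to_dict(orient="records"),
    }
    if "tests" in report:
        summary["tests"] = report["tests"]
    p = prefix.with_name(prefix.name + "_summary.json")
    p.write_text(json.dumps(summary, indent=2))
    written.append(str(p))
    return written
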
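"""Per-clone metrics and cohort-level summaries.

Rostro-caudal (R-C) dispersion is the anterior-posterior extent of a clone
across serial coronal sections.  Sections are 50 um thick and indexed from
the first section containing labeled cells (index 0 = "0 um"), increasing
caudally.  The convention is inclusive-span: a clone confined to one
section disperses 50 um (one section thickness), and a clone whose extreme
cells sit in sections 0 and 6 disperses 7 x 50 = 350 um.

Composition classes follow glial lineage logic: clones of one cell type are
uniform, and NG2-glia + oligodendrocyte clones also count as uniform
because NG2-glia act as oligodendrocyte precursors.  Mixed labels
(astrocyte+oligodendrocyte, astrocyte+NG2) additionally require the clone's
color code to have passed the rarity filter; multi-type clones with common
codes are reported as "ambiguous".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_SECTION_THICKNESS = 50.0

#: cell-type set -> composition class
_COMPOSITION = {
    frozenset({"astrocyte"}): "Ast",
    frozenset({"NG2"}): "NG2",
    frozenset({"oligodendrocyte"}): "OL",
    frozenset({"NG2", "oligodendrocyte"}): "NG2+OL",
    frozenset({"astrocyte", "NG2"}): "Ast+NG2",
    frozenset({"astrocyte", "oligodendrocyte"}): "Ast+OL",
}

UNIFORM_CLASSES = ("Ast", "NG2", "OL", "NG2+OL")
MIXED_CLASSES = ("Ast+NG2", "Ast+OL")
COMPOSITION_ORDER = UNIFORM_CLASSES + MIXED_CLASSES + ("ambiguous",)


@dataclass(frozen=True)
class SectionGeometry:
    """Serial-section geometry: thickness and the 0-um origin convention."""

    section_thickness: float = DEFAULT_SECTION_THICKNESS

    def __post_init__(self) -> None:
        if self.section_thickness <= 0:
            raise ValueError("section_thickness must be positive")


def rc_dispersion(section_indices, geometry: SectionGeometry | None = None) -> float:
    """Rostro-caudal dispersion of a clone, in um (inclusive-span).

    ``(max section - min section + 1) * thickness``: the total distance
    between the first and the last sibling cell, counting both end
    sections.
    """
    geometry = geometry or SectionGeometry()
    idx = np.asarray(section_indices, dtype=int)
    if idx.size == 0:
        raise ValueError("empty clone has no dispersion")
    return float((idx.max() - idx.min() + 1) * geometry.section_thickness)


def classify_composition(cell_types, rarity_eligible: bool = True) -> tuple[str, str]:
    """Composition class and uniformity of a clone.

    Returns ``(composition, uniformity)`` with uniformity in
    {"uniform", "mixed", "ambiguous"}.  Mixed labels require the clone to
    be rarity-eligible; otherwise a multi-type clone is "ambiguous".
    Single-type clones are uniform regardless of rarity.
    """
    types = frozenset(cell_types)
    if not types:
        raise ValueError("empty clone has no composition")
    unknown = types - {"astrocyte", "oligodendrocyte", "NG2"}
    if unknown:
        raise ValueError(f"unknown cell-type label(s): {sorted(unknown)}")
    comp = _COMPOSITION[types]
    if comp in UNIFORM_CLASSES:
        return comp, "uniform"
    if rarity_eligible:
        return comp, "mixed"
    return "ambiguous", "ambiguous"


def layer_spread(regions) -> str:
    """"restricted-LL" when every member sits in lower layers V-VI, else "spread"."""
    regions = list(regions)
    if not regions:
        raise ValueError("empty clone has no layer spread")
    if any(pd.isna(r) or r not in ("UL", "LL", "CC") for r in regions):
        raise ValueError("missing or unknown region label")
    return "restricted-LL" if all(r == "LL" for r in regions) else "spread"


def summarize_clones(
    cells: pd.DataFrame,
    clones: pd.DataFrame,
    geometry: SectionGeometry | None = None,
) -> pd.DataFrame:
    """Per-clone summary table from a cell table and a clone table.

    One row per clone: size, rc_dispersion (um), composition, uniformity,
    layer_spread, plus the QC flags carried over from clone calling.
    """
    geometry = geometry or SectionGeometry()
    cells = cells.set_index("cell_id")
    rows = []
    for clone in clones.itertuples(index=False):
        ids = clone.cell_ids.split(";")
        members = cells.loc[ids]
        comp, unif = classify_composition(members["cell_type"], bool(clone.rarity_eligible))
        rows.append(
            {
                "clone_id": clone.clone_id,
                "animal_id": clone.animal_id,
                "barcode": clone.barcode,
                "size": len(members),
                "rc_dispersion": rc_dispersion(members["section_index"], geometry),
                "composition": comp,
                "uniformity": unif,
                "layer_spread": layer_spread(members["region"]),
                "consistency_ok": bool(clone.consistency_ok),
                "rarity_eligible": bool(clone.rarity_eligible),
                "fragment": bool(clone.fragment),
            }
        )
    return pd.DataFrame.from_records(rows)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def composition_percentages(counts: dict[str, int] | pd.Series) -> pd.DataFrame:
    """Integer (half-up) percentages of clones per composition class.

    Matches the presentation convention of clonal-composition pie charts:
    26% for 12 of 46 clones, etc.
    """
    counts = pd.Series(counts, dtype=int)
    if counts.sum() == 0:
        raise ValueError("no clones to summarize")
    out = counts.rename_axis("composition").reset_index(name="n_clones")
    out["percent"] = [
        _round_half_up(100.0 * n / counts.sum()) for n in out["n_clones"]
    ]
    return out


def summarize_cohort(clone_summaries: pd.DataFrame, include_fragments: bool = False) -> dict:
    """Cohort-level report over per-clone summaries.

    Returns a dict with:

    * ``composition`` — per-class clone counts and integer percentages;
    * ``by_class`` / ``by_uniformity`` — mean, SD and SEM of clone size and
      R-C dispersion per composition class and for uniform vs mixed;
    * ``size_vs_dispersion`` — per-clone (size, dispersion) pairs;
    * ``n_clones``, ``n_cells``.

    Fragments (groups below the minimum clone size) are excluded unless
    ``include_fragments``.
    """
    if len(clone_summaries) == 0:
        raise ValueError("empty cohort")
    df = clone_summaries if include_fragments else clone_summaries[~clone_summaries["fragment"]]
    if len(df) == 0:
        raise ValueError("cohort contains only sub-minimum fragments")

    counts = (
        df["composition"].value_counts().reindex(
            [c for c in COMPOSITION_ORDER if c in df["composition"].values]
        )
    )
    report = {
        "n_clones": int(len(df)),
        "n_cells": int(df["size"].sum()),
        "composition": composition_percentages(counts),
        "by_class": _grouped_stats(df, "composition"),
        "by_uniformity": _grouped_stats(df[df["uniformity"] != "ambiguous"], "uniformity"),
        "size_vs_dispersion": df[["clone_id", "composition", "size", "rc_dispersion"]].copy(),
    }
    return report


def _grouped_stats(df: pd.DataFrame, key: str) -> pd.DataFrame:
    rows = []
    for name, grp in df.groupby(key, sort=True):
        n = len(grp)
        for metric in ("size", "rc_dispersion"):
            vals = grp[metric].to_numpy(dtype=float)
            sd = float(vals.std(ddof=1)) if n > 1 else float("nan")
            rows.append(
                {
                    key: name,
                    "metric": metric,
                    "n": n,
                    "mean": float(vals.mean()),
                    "sd": sd,
                    "sem": sd / np.sqrt(n) if n > 1 else float("nan"),
                }
            )
    return pd.DataFrame.from_records(rows)
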
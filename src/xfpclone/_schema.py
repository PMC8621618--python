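"""Shared column names, reporter ordering and categorical vocabularies.

The cell table is a pandas DataFrame with one row per labeled cell.  Twelve
intensity columns hold the six fluorescent-protein (XFP) channels measured in
each of two compartments, cytoplasm first then nucleus, in fixed digit order
(1 YFP, 2 mKO, 3 mCerulean, 4 mCherry, 5 mT-Sapphire, 6 EGFP).
"""

from __future__ import annotations

#: Digit -> XFP name, digit order is immutable (digit i = XFPS[i-1]).
XFPS: tuple[str, ...] = ("yfp", "mko", "mcerulean", "mcherry", "mtsapphire", "egfp")

COMPARTMENTS: tuple[str, str] = ("cyt", "nuc")

#: 12 intensity columns: cytoplasm block (digits 1-6) then nucleus block.
INTENSITY_COLUMNS: tuple[str, ...] = tuple(
    f"{xfp}_{comp}" for comp in COMPARTMENTS for xfp in XFPS
)

CELL_TYPES: tuple[str, ...] = ("astrocyte", "oligodendrocyte", "NG2", "unknown")

#: Cortical placement vocabulary: upper layers I-IV, lower layers V-VI,
#: corpus callosum.
REGIONS: tuple[str, str, str] = ("UL", "LL", "CC")

#: Progenitor fate classes, in the order of the default probability vector.
FATE_CLASSES: tuple[str, ...] = ("Ast", "NG2", "OL", "NG2+OL", "Ast+NG2", "Ast+OL")

#: Cell types constituting each fate class.
FATE_CLASS_TYPES: dict[str, tuple[str, ...]] = {
    "Ast": ("astrocyte",),
    "NG2": ("NG2",),
    "OL": ("oligodendrocyte",),
    "NG2+OL": ("NG2", "oligodendrocyte"),
    "Ast+NG2": ("astrocyte", "NG2"),
    "Ast+OL": ("astrocyte", "oligodendrocyte"),
}

REQUIRED_COLUMNS: tuple[str, ...] = (
    "cell_id",
    "animal_id",
    "section_index",
    "region",
    "cell_type",
) + INTENSITY_COLUMNS

OPTIONAL_COLUMNS: tuple[str, ...] = ("layer", "barcode", "x", "y")
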
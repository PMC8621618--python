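"""Presence calling and 12-digit cytoplasm/nucleus color codes.

Each labeled cell carries up to six fluorescent proteins (XFPs), each of
which may sit in the cytoplasm, the nucleus (H2B fusion), or both.  A cell's
color code is a 12-digit string: positions 1-6 describe the cytoplasm,
positions 7-12 the nucleus.  Within a block, position ``i`` holds the digit
``i`` when XFP ``i`` is present in that compartment and ``0`` otherwise,
with the fixed digit map 1=YFP, 2=mKO, 3=mCerulean, 4=mCherry,
5=mT-Sapphire, 6=EGFP.  A cell with YFP in the cytoplasm, mKO in the
nucleus and mCherry in both therefore reads ``100400 020400`` (the space is
presentation only; the canonical form is the bare 12 digits).

Presence is called by thresholding the measured compartment intensity;
at-threshold values count as present (``>=`` convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._schema import INTENSITY_COLUMNS, XFPS

#: Immutable digit -> XFP assignment (digit i maps to CHANNEL_MAP[i]).
CHANNEL_MAP: dict[int, str] = {i + 1: name for i, name in enumerate(XFPS)}

N_REPORTERS = 12

DEFAULT_PRESENCE_THRESHOLD = 40.0


@dataclass(frozen=True)
class PresenceCalls:
    """Boolean presence per reporter plus the intensities that produced them.

    ``calls`` and ``intensities`` are length-12 in column order
    (cytoplasm block then nucleus block, digit order within each block).
    """

    calls: tuple[bool, ...]
    intensities: tuple[float, ...]
    threshold: float

    def __post_init__(self) -> None:
        if len(self.calls) != N_REPORTERS or len(self.intensities) != N_REPORTERS:
            raise ValueError("PresenceCalls requires 12 reporters")


def call_presence(intensities, presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD) -> PresenceCalls:
    """Threshold 12 compartment intensities into boolean presence calls.

    Parameters
    ----------
    intensities : array-like of 12 non-negative floats
        Cytoplasm block (digits 1-6) then nucleus block.
    presence_threshold : float
        Intensity at or above which a reporter is called present.

    Raises
    ------
    ValueError
        If any intensity is negative or the length is not 12.
    """
    arr = np.asarray(intensities, dtype=float)
    if arr.shape != (N_REPORTERS,):
        raise ValueError(f"expected 12 intensities, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValueError("negative intensity in presence calling")
    calls = tuple(bool(v) for v in arr >= presence_threshold)
    return PresenceCalls(calls=calls, intensities=tuple(arr), threshold=presence_threshold)


def encode_barcode(calls: PresenceCalls | tuple[bool, ...]) -> str:
    """Encode presence calls into the canonical 12-digit color code.

    Raises ``ValueError`` on an all-false pattern (an unlabeled cell has no
    code).
    """
    flags = calls.calls if isinstance(calls, PresenceCalls) else tuple(calls)
    if len(flags) != N_REPORTERS:
        raise ValueError("expected 12 presence calls")
    if not any(flags):
        raise ValueError("unlabeled cell: all presence calls are false")
    digits = []
    for block in range(2):
        for i in range(6):
            digits.append(str(i + 1) if flags[block * 6 + i] else "0")
    return "".join(digits)


def decode_barcode(code: str) -> tuple[bool, ...]:
    """Invert :func:`encode_barcode`; returns the 12 presence booleans.

    Accepts the canonical 12-digit form or the spaced presentation form.
    Raises ``ValueError`` on malformed codes (wrong length, position ``i``
    holding a digit other than 0 or ``i``, or the all-zero pattern).
    """
    compact = code.replace(" ", "")
    if len(compact) != N_REPORTERS or not compact.isdigit():
        raise ValueError(f"malformed barcode {code!r}")
    flags = []
    for pos, ch in enumerate(compact):
        digit = pos % 6 + 1
        if ch == "0":
            flags.append(False)
        elif ch == str(digit):
            flags.append(True)
        else:
            raise ValueError(
                f"malformed barcode {code!r}: position {pos + 1} holds {ch}, "
                f"expected 0 or {digit}"
            )
    if not any(flags):
        raise ValueError("all-zero barcode denotes an unlabeled cell")
    return tuple(flags)


def format_barcode(code: str) -> str:
    """Presentation form with one space between the two 6-digit blocks."""
    compact = code.replace(" ", "")
    return f"{compact[:6]} {compact[6:]}"


class BarcodeEncoder(BaseEstimator, TransformerMixin):
    """Transformer adding presence calls and barcodes to a cell table.

    Stateless apart from parameters; ``fit`` only validates.  ``transform``
    returns a copy of the input DataFrame with one boolean column per
    reporter (``<xfp>_<compartment>_present``) and a ``barcode`` column.

    Parameters
    ----------
    presence_threshold : float, default 40
        Intensity at or above which a reporter is called present.
    """

    def __init__(self, presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD):
        self.presence_threshold = presence_threshold

    def fit(self, X: pd.DataFrame, y=None):
        self._validate(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self._validate(X)
        out = X.copy()
        inten = out[list(INTENSITY_COLUMNS)].to_numpy(dtype=float)
        present = inten >= self.presence_threshold
        if np.any(~present.any(axis=1)):
            bad = out.index[~present.any(axis=1)][0]
            raise ValueError(f"unlabeled cell at row {bad}: no reporter above threshold")
        for j, col in enumerate(INTENSITY_COLUMNS):
            out[f"{col}_present"] = present[:, j]
        digit_chars = np.array([str(i % 6 + 1) for i in range(N_REPORTERS)])
        codes = np.where(present, digit_chars, "0")
        out["barcode"] = ["".join(row) for row in codes]
        return out

    def _validate(self, X: pd.DataFrame) -> None:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("BarcodeEncoder expects a cell-table DataFrame")
        missing = [c for c in INTENSITY_COLUMNS if c not in X.columns]
        if missing:
            raise ValueError(f"cell table missing intensity columns: {missing}")
        if np.any(X[list(INTENSITY_COLUMNS)].to_numpy(dtype=float) < 0):
            raise ValueError("negative intensity in cell table")


def annotate_barcodes(cells: pd.DataFrame, presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD) -> pd.DataFrame:
    """Functional wrapper over :class:`BarcodeEncoder`."""
    return BarcodeEncoder(presence_threshold=presence_threshold).fit(cells).transform(cells)


def barcode_frequency(cells: pd.DataFrame) -> pd.DataFrame:
    """Frequency of each color code over all labeled cells in the table.

    Returns a DataFrame (barcode, count, fraction) sorted by descending
    count; fractions sum to 1 over the table.  The denominator is the full
    loaded dataset — the convention used when flagging codes rarer than 1%.
    """
    if len(cells) == 0:
        raise ValueError("empty cell table")
    if "barcode" not in cells.columns:
        raise ValueError("cell table has no barcode column; run annotate_barcodes first")
    counts = cells["barcode"].value_counts()
    freq = counts.rename_axis("barcode").reset_index(name="count")
    freq["fraction"] = freq["count"] / len(cells)
    return freq
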
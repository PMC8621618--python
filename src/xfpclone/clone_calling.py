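"""Group labeled cells into clones.

Sibling cells inherit their progenitor's reporter integrations, so cells
with the same 12-digit color code — the same XFPs in the same compartments —
are candidate siblings.  Two refinements guard against coincidental code
sharing between independent progenitors:

* **Intensity consistency.**  Copy number scales fluorescence, so true
  siblings show similar intensities.  Within a candidate group, cells whose
  per-reporter intensities differ by 80 units or more (on any reporter named
  in the barcode) cannot be siblings; inconsistent groups are split by
  single-linkage clustering with that per-reporter threshold.
* **Rarity filter.**  Only clones whose color code occurs in fewer than 1%
  of all labeled cells are eligible to be called mixed (multi-cell-type);
  commoner codes are too likely to collide between progenitors, so their
  multi-type groups are reported as "ambiguous" rather than mixed.

Clones never span animals: ``animal_id`` is a hard grouping key.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator

from ._schema import INTENSITY_COLUMNS
from .barcoding import annotate_barcodes, barcode_frequency, decode_barcode

DEFAULT_INTENSITY_TOLERANCE = 80.0
DEFAULT_RARITY_THRESHOLD = 0.01
MIN_CLONE_SIZE = 4


@dataclass
class CloneCallingParams:
    """Thresholds of the clone-calling rules.

    ``intensity_tolerance``: sibling intensities must differ by strictly
    less than this many units on every reporter present in the barcode.
    ``rarity_threshold``: a barcode is rare (mixed-eligible) when its
    cohort-wide fraction is strictly below this value.
    ``consistency_mode``: "pairwise" compares all member pairs;
    "mean" compares each member against the group mean.
    """

    intensity_tolerance: float = DEFAULT_INTENSITY_TOLERANCE
    rarity_threshold: float = DEFAULT_RARITY_THRESHOLD
    consistency_mode: str = "pairwise"
    min_clone_size: int = MIN_CLONE_SIZE

    def validate(self) -> None:
        if self.intensity_tolerance <= 0:
            raise ValueError("intensity_tolerance must be positive")
        if not 0.0 < self.rarity_threshold <= 1.0:
            raise ValueError("rarity_threshold must lie in (0, 1]")
        if self.consistency_mode not in ("pairwise", "mean"):
            raise ValueError("consistency_mode must be 'pairwise' or 'mean'")


def group_by_barcode(cells: pd.DataFrame) -> dict[tuple[str, str], pd.Index]:
    """One candidate group per (animal, barcode); returns row indices.

    All-zero barcodes (unlabeled cells) are excluded.  Groups are keyed and
    ordered by (animal_id, barcode) so the result is independent of the
    input row order.
    """
    if len(cells) == 0:
        return {}
    labeled = cells[cells["barcode"].str.strip("0") != ""]
    groups = {
        key: idx.sort_values()
        for key, idx in labeled.groupby(["animal_id", "barcode"], sort=True).groups.items()
    }
    return groups


def _present_columns(barcode: str) -> list[str]:
    flags = decode_barcode(barcode)
    return [col for col, f in zip(INTENSITY_COLUMNS, flags) if f]


def check_intensity_consistency(
    group: pd.DataFrame, params: CloneCallingParams | None = None
) -> tuple[bool, list[pd.Index]]:
    """Test a same-barcode group for sibling-grade intensity agreement.

    Consistent iff, for every reporter present in the barcode, the maximum
    pairwise member difference is strictly below the tolerance (80 units by
    default).  Inconsistent groups are split by single-linkage clustering on
    the per-present-reporter Chebyshev distance, cut at the tolerance.

    Returns ``(consistent, subgroups)`` where subgroups is a list of row
    Indexes (a single entry when consistent).
    """
    params = params or CloneCallingParams()
    params.validate()
    if len(group) == 0:
        raise ValueError("empty candidate group")
    barcode = group["barcode"].iloc[0]
    cols = _present_columns(barcode)
    X = group[cols].to_numpy(dtype=float)
    if len(group) == 1:
        return True, [group.index]

    if params.consistency_mode == "mean":
        dev = np.abs(X - X.mean(axis=0, keepdims=True)).max()
        # mean mode does not split; it only flags
        return bool(dev < params.intensity_tolerance), [group.index]

    dists = pdist(X, metric="chebyshev")
    if dists.max() < params.intensity_tolerance:
        return True, [group.index]
    Z = linkage(dists, method="single")
    # strict "< tolerance" linking: cut just below the tolerance
    labels = fcluster(Z, t=params.intensity_tolerance * (1 - 1e-12), criterion="distance")
    subgroups = [group.index[labels == lab] for lab in np.unique(labels)]
    return False, subgroups


def apply_rarity_filter(
    clones: pd.DataFrame, frequencies: pd.DataFrame, params: CloneCallingParams | None = None
) -> pd.DataFrame:
    """Flag each clone as rarity-eligible (barcode fraction < threshold)."""
    params = params or CloneCallingParams()
    params.validate()
    frac = frequencies.set_index("barcode")["fraction"]
    missing = set(clones["barcode"]) - set(frac.index)
    if missing:
        raise KeyError(f"barcodes missing from frequency table: {sorted(missing)[:5]}")
    out = clones.copy()
    out["rarity_eligible"] = (
        out["barcode"].map(frac).to_numpy() < params.rarity_threshold
    )
    return out


class CloneCaller(BaseEstimator):
    """Cluster-style estimator assigning labeled cells to clones.

    ``fit`` runs barcode grouping, the intensity-consistency split and the
    rarity flag on a cell table (barcodes are computed on the fly when the
    table lacks a ``barcode`` column).  Fitted attributes:

    ``labels_`` : ndarray of int, clone index per input row (-1 never occurs;
        every labeled cell is assigned).
    ``clones_`` : DataFrame with one row per clone: clone_id, animal_id,
        barcode, n_cells, consistency_ok, rarity_eligible, fragment,
        cell_ids (semicolon-joined).

    Parameters mirror :class:`CloneCallingParams`; groups smaller than
    ``min_clone_size`` are flagged ``fragment`` (excluded from cohort
    summaries downstream, never dropped here).
    """

    def __init__(
        self,
        intensity_tolerance: float = DEFAULT_INTENSITY_TOLERANCE,
        rarity_threshold: float = DEFAULT_RARITY_THRESHOLD,
        consistency_mode: str = "pairwise",
        min_clone_size: int = MIN_CLONE_SIZE,
        presence_threshold: float = 40.0,
    ):
        self.intensity_tolerance = intensity_tolerance
        self.rarity_threshold = rarity_threshold
        self.consistency_mode = consistency_mode
        self.min_clone_size = min_clone_size
        self.presence_threshold = presence_threshold

    def _params(self) -> CloneCallingParams:
        return CloneCallingParams(
            intensity_tolerance=self.intensity_tolerance,
            rarity_threshold=self.rarity_threshold,
            consistency_mode=self.consistency_mode,
            min_clone_size=self.min_clone_size,
        )

    def fit(self, X: pd.DataFrame, y=None):
        params = self._params()
        params.validate()
        if not isinstance(X, pd.DataFrame):
            raise TypeError("CloneCaller expects a cell-table DataFrame")
        cells = X if "barcode" in X.columns else annotate_barcodes(X, self.presence_threshold)
        if len(cells) == 0:
            self.labels_ = np.empty(0, dtype=int)
            self.clones_ = _empty_clone_table()
            return self

        freq = barcode_frequency(cells)
        groups = group_by_barcode(cells)
        labels = pd.Series(-1, index=cells.index, dtype=int)
        records = []
        clone_idx = 0
        for (animal, barcode), idx in groups.items():
            group = cells.loc[idx]
            consistent, subgroups = check_intensity_consistency(group, params)
            for sub in subgroups:
                sub = sub.sort_values()
                sub_cells = cells.loc[sub]
                # consistency of the emitted clone itself
                ok = bool(
                    check_intensity_consistency(sub_cells, params)[0]
                ) if not consistent else True
                labels.loc[sub] = clone_idx
                records.append(
                    {
                        "clone_id": f"{animal}_clone{clone_idx:04d}",
                        "animal_id": animal,
                        "barcode": barcode,
                        "n_cells": len(sub),
                        "consistency_ok": ok,
                        "fragment": len(sub) < params.min_clone_size,
                        "cell_ids": ";".join(sub_cells["cell_id"].astype(str)),
                    }
                )
                clone_idx += 1
        clones = pd.DataFrame.from_records(records)
        clones = apply_rarity_filter(clones, freq, params)
        self.labels_ = labels.to_numpy()
        self.clones_ = clones
        self.frequencies_ = freq
        return self

    def fit_predict(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X).labels_


def _empty_clone_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "clone_id", "animal_id", "barcode", "n_cells",
            "consistency_ok", "fragment", "cell_ids", "rarity_eligible",
        ]
    )


def call_clones(cells: pd.DataFrame, params: CloneCallingParams | None = None) -> pd.DataFrame:
    """Run the full clone-calling pipeline; returns the clone table.

    Thin functional wrapper over :class:`CloneCaller`.
    """
    params = params or CloneCallingParams()
    caller = CloneCaller(
        intensity_tolerance=params.intensity_tolerance,
        rarity_threshold=params.rarity_threshold,
        consistency_mode=params.consistency_mode,
        min_clone_size=params.min_clone_size,
    )
    return caller.fit(cells).clones_
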
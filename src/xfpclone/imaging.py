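"""Forward model and quantification for multichannel section images.

A section is a 2-D mosaic with six channels, one per XFP in digit order
(1 YFP, 2 mKO, 3 mCerulean, 4 mCherry, 5 mT-Sapphire, 6 EGFP).  Each cell
is rendered as a nuclear disk carrying the six nuclear intensities plus a
cytoplasmic annulus carrying the six cytoplasmic ones, with optional
additive Gaussian pixel noise.  Quantification inverts the model: detect
cells on the across-channel maximum, then average each compartment mask
per channel with per-channel background (image median) subtraction —
yielding the 12-value intensity vector the barcode stage consumes.

This stands in for the microscope + measurement-macro stage of a real
experiment; real morphology (astrocyte arbors, myelinating processes) is
deliberately out of scope, since only measurement correctness matters here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
from skimage import measure

from ._schema import INTENSITY_COLUMNS

N_CHANNELS = 6


@dataclass(frozen=True)
class CellRendering:
    """Concentric disk/annulus geometry for one rendered cell, in pixels."""

    nucleus_radius: float = 4.0
    cytoplasm_radius: float = 8.0

    def __post_init__(self) -> None:
        if not 0 < self.nucleus_radius < self.cytoplasm_radius:
            raise ValueError("need 0 < nucleus_radius < cytoplasm_radius")


@dataclass
class SectionImage:
    """A rendered (or loaded) section: H x W x 6 pixel array plus scale."""

    pixels: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != N_CHANNELS:
            raise ValueError("SectionImage requires an H x W x 6 array")
        if np.any(self.pixels < 0):
            raise ValueError("negative pixel intensities")


def _masks(shape, cx: float, cy: float, geometry: CellRendering):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    nucleus = r2 <= geometry.nucleus_radius**2
    annulus = (r2 <= geometry.cytoplasm_radius**2) & ~nucleus
    return nucleus, annulus


def render_section(
    cells: pd.DataFrame,
    shape: tuple[int, int] = (512, 512),
    geometry: CellRendering | None = None,
    noise_sd: float = 1.0,
    rng: np.random.Generator | None = None,
    allow_overlap: bool = False,
) -> SectionImage:
    """Render the cells of one section into a 6-channel image.

    ``cells`` must carry ``x``/``y`` pixel coordinates plus the 12 intensity
    columns.  Raises on out-of-bounds coordinates, and on overlapping cells
    unless ``allow_overlap``.
    """
    geometry = geometry or CellRendering()
    rng = rng or np.random.default_rng()
    img = np.zeros(shape + (N_CHANNELS,), dtype=float)

    xs = cells["x"].to_numpy(dtype=float) if len(cells) else np.empty(0)
    ys = cells["y"].to_numpy(dtype=float) if len(cells) else np.empty(0)
    if len(cells):
        r = geometry.cytoplasm_radius
        if np.any((xs < r) | (ys < r) | (xs > shape[1] - 1 - r) | (ys > shape[0] - 1 - r)):
            raise ValueError("cell coordinates out of image bounds")
        if not allow_overlap and len(cells) > 1:
            d2 = (xs[:, None] - xs[None, :]) ** 2 + (ys[:, None] - ys[None, :]) ** 2
            np.fill_diagonal(d2, np.inf)
            if d2.min() < (2 * r) ** 2:
                raise ValueError("overlapping cells; pass allow_overlap=True to permit")

    cyt_cols = list(INTENSITY_COLUMNS[:N_CHANNELS])
    nuc_cols = list(INTENSITY_COLUMNS[N_CHANNELS:])
    for i in range(len(cells)):
        nucleus, annulus = _masks(shape, xs[i], ys[i], geometry)
        row = cells.iloc[i]
        for c in range(N_CHANNELS):
            img[nucleus, c] += float(row[nuc_cols[c]])
            img[annulus, c] += float(row[cyt_cols[c]])
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
    np.maximum(img, 0.0, out=img)
    return SectionImage(pixels=img)


def detect_cells(
    image: SectionImage,
    noise_sd: float = 1.0,
    min_area: int = 5,
) -> np.ndarray:
    """Detect cell centroids on the across-channel maximum projection.

    Thresholds the projection at background (median) + 5 noise SD, labels
    connected components and returns an (n, 2) array of (x, y) centroids.
    Works for hollow cells (cytoplasm-only labeling) because the centroid
    of an annulus is its center.  Empty image yields an empty array.
    """
    proj = image.pixels.max(axis=2)
    thresh = np.median(proj) + 5.0 * noise_sd
    mask = proj > thresh
    labels = measure.label(mask)
    centroids = [
        (p.centroid[1], p.centroid[0])
        for p in measure.regionprops(labels)
        if p.area >= min_area
    ]
    return np.asarray(centroids, dtype=float).reshape(-1, 2)


def quantify_cell(
    image: SectionImage,
    centroid: tuple[float, float],
    geometry: CellRendering | None = None,
    background: np.ndarray | None = None,
) -> dict:
    """Measure the 12 compartment intensities of one detected cell.

    Nuclear value per channel = mean over the nucleus disk; cytoplasmic
    value = mean over the annulus; both background-subtracted (per-channel
    image median unless ``background`` is given) and floored at 0.
    Returns a dict keyed by the standard intensity column names plus
    ``border_flag`` set when the cytoplasm mask would leave the image
    (measured values are then unreliable, never silently cropped).
    """
    geometry = geometry or CellRendering()
    cx, cy = centroid
    h, w = image.pixels.shape[:2]
    r = geometry.cytoplasm_radius
    border = not (r <= cx <= w - 1 - r and r <= cy <= h - 1 - r)
    nucleus, annulus = _masks((h, w), cx, cy, geometry)
    if background is None:
        background = np.median(image.pixels.reshape(-1, N_CHANNELS), axis=0)
    out: dict = {"border_flag": border}
    for c in range(N_CHANNELS):
        chan = image.pixels[:, :, c]
        nuc = chan[nucleus].mean() - background[c] if nucleus.any() else 0.0
        cyt = chan[annulus].mean() - background[c] if annulus.any() else 0.0
        out[INTENSITY_COLUMNS[c]] = max(float(cyt), 0.0)
        out[INTENSITY_COLUMNS[N_CHANNELS + c]] = max(float(nuc), 0.0)
    return out


def quantify_section(
    image: SectionImage,
    geometry: CellRendering | None = None,
    noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Detect and measure every cell in a section.

    Returns a DataFrame with x, y, border_flag and the 12 intensity
    columns, one row per detection.
    """
    centroids = detect_cells(image, noise_sd=noise_sd)
    rows = []
    for cx, cy in centroids:
        rec = quantify_cell(image, (cx, cy), geometry)
        rec["x"], rec["y"] = cx, cy
        rows.append(rec)
    cols = ["x", "y", "border_flag", *INTENSITY_COLUMNS]
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)


def layout_positions(
    n: int,
    shape: tuple[int, int] = (512, 512),
    geometry: CellRendering | None = None,
    margin: float = 4.0,
) -> np.ndarray:
    """Non-overlapping grid layout: (n, 2) array of (x, y) pixel centers."""
    geometry = geometry or CellRendering()
    pitch = 2 * geometry.cytoplasm_radius + margin
    per_row = int((shape[1] - pitch) // pitch)
    if per_row < 1 or (n + per_row - 1) // per_row * pitch > shape[0] - pitch:
        raise ValueError("image too small for requested cell count")
    coords = [
        (pitch * (i % per_row + 1), pitch * (i // per_row + 1)) for i in range(n)
    ]
    return np.asarray(coords, dtype=float)


def write_section_tiff(path, image: SectionImage) -> None:
    """Write a section as a channel-first multichannel TIFF with pixel size."""
    arr = np.moveaxis(image.pixels, -1, 0).astype(np.float32)
    res = 1.0 / image.pixel_size_um
    tifffile.imwrite(
        path, arr, photometric="minisblack",
        resolution=(res, res), metadata={"axes": "CYX", "unit": "um"},
    )


def read_section_tiff(path, pixel_size_um: float = 1.0) -> SectionImage:
    """Read a channel-first multichannel TIFF written by this package."""
    arr = tifffile.imread(path)
    if arr.ndim != 3 or arr.shape[0] != N_CHANNELS:
        raise ValueError("expected a 6-channel CYX TIFF")
    return SectionImage(pixels=np.moveaxis(arr, 0, -1).astype(float), pixel_size_um=pixel_size_um)
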
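"""Per-well quantification of the three-channel lipophagy reporter.

The assay images carry a nuclear marker (BFP), the droplet reporter's
acid-quenchable channel (GFP) and its acid-stable channel (mCherry).
Quantification per well: count nuclei on BFP, segment the mCherry-positive
region, integrate GFP and mCherry over that region, and compute the
lipophagy score ``(mcherry_total - gfp_total) / cell_count``.

Thresholds are robust background statistics (median + k * MAD) computed on
the smoothed channel, which keeps segmentation stable on sparse-signal
wells. Pixels are half-open sets: a pixel is in the mask or not, with no
sub-pixel weighting. Row-major indexing, origin top-left.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label

CHANNEL_ORDER = ("BFP", "GFP", "mCherry")

EMPTY_MASK = "EMPTY_MASK"
NO_CELLS = "NO_CELLS"


class MissingChannelError(KeyError):
    """A required channel is absent from the image."""


class NoCellsError(ValueError):
    """Score requested for a well with zero counted cells."""


@dataclass
class WellImage:
    """Three-channel intensity raster for one well.

    All channels share one shape; intensities are finite and non-negative.
    """

    channels: dict[str, np.ndarray]
    row: int = 0
    col: int = 0
    plate_id: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("WellImage requires at least one channel")
        shapes = {c: a.shape for c, a in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for name, arr in self.channels.items():
            if arr.ndim != 2 or arr.size == 0:
                raise ValueError(f"channel {name!r} must be a non-empty 2D array")
            a = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(a)) or np.any(a < 0):
                raise ValueError(f"channel {name!r} has non-finite or negative values")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise MissingChannelError(
                f"channel {name!r} not in image (have {sorted(self.channels)})"
            ) from None


@dataclass
class SegmentationParams:
    """Robust-threshold segmentation parameters.

    Threshold for a channel is ``median + k * MAD`` of the smoothed pixel
    intensities, where MAD is the raw median absolute deviation.
    """

    k_nuc: float = 6.0
    k_mch: float = 4.0
    min_blob_area_px: int = 4
    smoothing_radius: float = 1.0

    def __post_init__(self) -> None:
        if self.k_nuc <= 0 or self.k_mch <= 0:
            raise ValueError("threshold multipliers must be positive")
        if self.min_blob_area_px < 1:
            raise ValueError("min_blob_area_px must be >= 1")
        if self.smoothing_radius < 0:
            raise ValueError("smoothing_radius must be >= 0")


@dataclass
class WellQuant:
    """Derived per-well quantities."""

    row: int
    col: int
    cell_count: int
    mcherry_area_px: int
    gfp_total: float
    mcherry_total: float
    lipophagy_score_raw: float
    flags: set[str] = field(default_factory=set)


def _smooth(channel: np.ndarray, radius: float) -> np.ndarray:
    img = np.asarray(channel, dtype=float)
    if radius > 0:
        img = ndimage.gaussian_filter(img, sigma=radius)
    return img


def _robust_threshold(img: np.ndarray, k: float) -> float:
    med = float(np.median(img))
    mad = float(np.median(np.abs(img - med)))
    return med + k * mad


def count_nuclei(image: WellImage, params: SegmentationParams | None = None) -> int:
    """Count nuclei as connected BFP components strictly above threshold.

    The BFP channel is smoothed, thresholded at ``median + k_nuc * MAD``,
    and connected components with area >= ``min_blob_area_px`` are counted.
    """
    params = params or SegmentationParams()
    img = _smooth(image.channel("BFP"), params.smoothing_radius)
    mask = img > _robust_threshold(img, params.k_nuc)
    labels, n = label(mask, return_num=True, connectivity=2)
    if n == 0:
        return 0
    areas = np.bincount(labels.ravel())[1:]
    return int(np.sum(areas >= params.min_blob_area_px))


def segment_mcherry_mask(
    image: WellImage, params: SegmentationParams | None = None
) -> np.ndarray:
    """Binary mask of mCherry-positive pixels.

    Pixels strictly above ``median + k_mch * MAD`` of the smoothed channel,
    with components smaller than ``min_blob_area_px`` removed.
    """
    params = params or SegmentationParams()
    img = _smooth(image.channel("mCherry"), params.smoothing_radius)
    mask = img > _robust_threshold(img, params.k_mch)
    if not mask.any():
        return mask
    labels, n = label(mask, return_num=True, connectivity=2)
    areas = np.bincount(labels.ravel())
    keep = areas >= params.min_blob_area_px
    keep[0] = False
    return keep[labels]


def integrate_fluorescence(
    image: WellImage, mask: np.ndarray
) -> tuple[float, float, int]:
    """Sum GFP and mCherry intensities over the mask.

    Returns ``(gfp_total, mcherry_total, area_px)``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape {image.shape}"
        )
    gfp = float(np.asarray(image.channel("GFP"), dtype=float)[mask].sum())
    mch = float(np.asarray(image.channel("mCherry"), dtype=float)[mask].sum())
    return gfp, mch, int(mask.sum())


def lipophagy_score(gfp_total: float, mcherry_total: float, cell_count: int) -> float:
    """``(mcherry_total - gfp_total) / cell_count``; may be negative."""
    if cell_count < 0:
        raise ValueError("cell_count must be >= 0")
    if cell_count == 0:
        raise NoCellsError("well has zero cells; score undefined")
    return (mcherry_total - gfp_total) / cell_count


def quantify_well(image: WellImage, params: SegmentationParams | None = None) -> WellQuant:
    """Full quantification for a single well image."""
    params = params or SegmentationParams()
    flags: set[str] = set()
    n_cells = count_nuclei(image, params)
    mask = segment_mcherry_mask(image, params)
    gfp_total, mch_total, area = integrate_fluorescence(image, mask)
    if area == 0:
        flags.add(EMPTY_MASK)
        gfp_total = mch_total = 0.0
    if n_cells == 0:
        flags.add(NO_CELLS)
        score = float("nan")
    elif area == 0:
        # a compound abolishing droplets is meaningful: score 0, flagged
        score = 0.0
    else:
        score = lipophagy_score(gfp_total, mch_total, n_cells)
    return WellQuant(
        row=image.row,
        col=image.col,
        cell_count=n_cells,
        mcherry_area_px=area,
        gfp_total=gfp_total,
        mcherry_total=mch_total,
        lipophagy_score_raw=score,
        flags=flags,
    )


def quantify_plate(
    images: Mapping[tuple[int, int], WellImage],
    layout,
    params: SegmentationParams | None = None,
) -> pd.DataFrame:
    """Quantify every non-empty layout well, row-major order.

    Parameters
    ----------
    images
        Mapping from ``(row, col)`` (0-based) to :class:`WellImage`, or a
        callable ``(row, col) -> WellImage`` rendering wells on demand
        (keeps one well in memory at a time).
    layout
        A :class:`~lipscreen.synthetic_data.PlateLayout`.

    Returns
    -------
    DataFrame with one row per non-empty well, columns
    ``plate, row, col, role, compound_id, cell_count, mcherry_area_px,
    gfp_total, mcherry_total, score_raw, flags``.
    """
    params = params or SegmentationParams()
    wells = layout.wells
    nonempty = wells[wells["role"] != "empty"].sort_values(["row", "col"])
    if callable(images) and not hasattr(images, "__getitem__"):
        get_image = images
    else:
        missing = [
            (int(r), int(c))
            for r, c in zip(nonempty["row"], nonempty["col"])
            if (int(r), int(c)) not in images
        ]
        if missing:
            raise FileNotFoundError(f"missing images for wells: {missing}")
        get_image = lambda key: images[key]  # noqa: E731
    records = []
    for rec in nonempty.itertuples(index=False):
        q = quantify_well(get_image((int(rec.row), int(rec.col))), params)
        records.append(
            {
                "plate": layout.plate_id,
                "row": int(rec.row),
                "col": int(rec.col),
                "role": rec.role,
                "compound_id": rec.compound_id,
                "cell_count": q.cell_count,
                "mcherry_area_px": q.mcherry_area_px,
                "gfp_total": q.gfp_total,
                "mcherry_total": q.mcherry_total,
                "score_raw": q.lipophagy_score_raw,
                "flags": ";".join(sorted(q.flags)),
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "plate", "row", "col", "role", "compound_id", "cell_count",
            "mcherry_area_px", "gfp_total", "mcherry_total", "score_raw", "flags",
        ],
    )


def write_quant_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_quant_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["flags"] = df["flags"].fillna("")
    df["compound_id"] = df["compound_id"].where(df["compound_id"].notna(), None)
    return df
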
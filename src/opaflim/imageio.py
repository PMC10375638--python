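"""FLIM data containers and file formats.

Histograms travel as two-column CSV (``time_ns,counts``), time-resolved
image stacks as multi-page TIFF (one page per time bin), ROI masks as
single-page signed-integer TIFF.  The mask convention is: 0 = background,
positive label = included ROI (a nucleus), negative label = excluded
sub-region of ROI ``|label|`` (a nucleolus, or pixels rejected by the
fast-lifetime filter).

Readers reject malformed input rather than coercing it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile

from .decay import BinGrid
from .exceptions import FormatError, InvalidInputError

__all__ = [
    "TCSPCHistogram",
    "FLIMImage",
    "ROIMask",
    "read_histogram_csv",
    "write_histogram_csv",
    "read_time_stack_tiff",
    "write_time_stack_tiff",
    "read_mask_tiff",
    "write_mask_tiff",
    "fast_lifetime_map",
    "exclude_low_lifetime_pixels",
    "pool_roi",
]


@dataclass(frozen=True)
class TCSPCHistogram:
    """Binned photon arrival counts for one ROI or one fit."""

    grid: BinGrid
    counts: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or len(counts) != self.grid.n_bins:
            raise InvalidInputError(
                f"counts length {counts.shape} does not match grid "
                f"n_bins={self.grid.n_bins}"
            )
        if np.any(counts < 0):
            raise InvalidInputError("counts must be nonnegative")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def total_photons(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class FLIMImage:
    """Per-pixel time-binned photon counts: array of shape (rows, cols, n_bins)."""

    grid: BinGrid
    counts: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 3 or counts.shape[2] != self.grid.n_bins:
            raise InvalidInputError(
                "counts must have shape (rows, cols, n_bins) matching the grid"
            )
        if np.any(counts < 0):
            raise InvalidInputError("counts must be nonnegative")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape[:2]


@dataclass(frozen=True)
class ROIMask:
    """Integer label image; see module docstring for the sign convention."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2 or not np.issubdtype(labels.dtype, np.integer):
            raise InvalidInputError("mask labels must be a 2-D integer image")
        object.__setattr__(self, "labels", labels.astype(np.int32))

    @property
    def roi_labels(self) -> np.ndarray:
        """Sorted positive ROI labels present (counting excluded sub-regions)."""
        return np.unique(np.abs(self.labels[self.labels != 0]))


# ---------------------------------------------------------------------------
# CSV histograms


def write_histogram_csv(hist: TCSPCHistogram, path) -> None:
    """Write a histogram as ``time_ns,counts`` with times at bin left edges."""
    times = hist.grid.edges_ns[:-1]
    pd.DataFrame({"time_ns": times, "counts": hist.counts}).to_csv(path, index=False)


def read_histogram_csv(path) -> TCSPCHistogram:
    """Read a ``time_ns,counts`` CSV; the time column must be uniform and increasing."""
    df = pd.read_csv(path)
    if list(df.columns) != ["time_ns", "counts"]:
        raise FormatError(
            f"{path}: expected header 'time_ns,counts', got {list(df.columns)}"
        )
    if df.isna().any().any():
        raise FormatError(f"{path}: missing values in histogram table")
    times = df["time_ns"].to_numpy(dtype=float)
    counts = df["counts"].to_numpy()
    if np.any(counts < 0):
        line = int(np.argmax(counts < 0)) + 2  # header is line 1
        raise FormatError(f"{path}: negative count at line {line}")
    if len(times) < 1:
        raise FormatError(f"{path}: empty histogram")
    if len(times) == 1:
        raise FormatError(f"{path}: cannot infer bin width from a single row")
    diffs = np.diff(times)
    if np.any(diffs <= 0):
        line = int(np.argmax(diffs <= 0)) + 3
        raise FormatError(f"{path}: time column not strictly increasing at line {line}")
    width = float(np.median(diffs))
    if np.max(np.abs(diffs - width)) > 1e-6 * width:
        line = int(np.argmax(np.abs(diffs - width) > 1e-6 * width)) + 3
        raise FormatError(f"{path}: nonuniform bin spacing at line {line}")
    grid = BinGrid(bin_width_ns=width, n_bins=len(times), origin_ns=float(times[0]))
    return TCSPCHistogram(grid=grid, counts=counts, source=str(path))


# ---------------------------------------------------------------------------
# TIFF stacks and masks

_META_KEY_WIDTH = "bin_width_ns"
_META_KEY_ORIGIN = "origin_ns"


def write_time_stack_tiff(image: FLIMImage, path) -> None:
    """Write a FLIM stack as multi-page TIFF, one page per time bin.

    The bin width and time origin are stored in the TIFF image description
    as JSON so the stack round-trips losslessly.
    """
    pages = np.moveaxis(image.counts, 2, 0)
    meta = dict(image.metadata)
    meta[_META_KEY_WIDTH] = image.grid.bin_width_ns
    meta[_META_KEY_ORIGIN] = image.grid.origin_ns
    tifffile.imwrite(path, pages.astype(np.uint32), description=json.dumps(meta))


def read_time_stack_tiff(path, bin_width_ns: float | None = None) -> FLIMImage:
    """Read a multi-page TIFF time stack.

    ``bin_width_ns`` overrides (or supplies, when absent) the metadata value.
    """
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description or ""
    meta: dict = {}
    if desc:
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
    if pages.ndim == 2:
        pages = pages[None, :, :]
    if pages.shape[0] == 1:
        warnings.warn("single-page stack: degenerate single-bin image", stacklevel=2)
    if not np.issubdtype(pages.dtype, np.integer):
        raise FormatError(f"{path}: pixel values must be integers, got {pages.dtype}")
    width = bin_width_ns if bin_width_ns is not None else meta.get(_META_KEY_WIDTH)
    if width is None:
        raise FormatError(
            f"{path}: no {_META_KEY_WIDTH} in TIFF metadata; pass bin_width_ns"
        )
    origin = float(meta.get(_META_KEY_ORIGIN, 0.0))
    grid = BinGrid(bin_width_ns=float(width), n_bins=pages.shape[0], origin_ns=origin)
    extra = {k: v for k, v in meta.items() if k not in (_META_KEY_WIDTH, _META_KEY_ORIGIN)}
    return FLIMImage(grid=grid, counts=np.moveaxis(pages, 0, 2), metadata=extra)


def write_mask_tiff(mask: ROIMask, path) -> None:
    tifffile.imwrite(path, mask.labels.astype(np.int32))


def read_mask_tiff(path) -> ROIMask:
    labels = tifffile.imread(path)
    if not np.issubdtype(labels.dtype, np.integer):
        raise FormatError(f"{path}: mask pixels must be integers, got {labels.dtype}")
    return ROIMask(labels=labels)


# ---------------------------------------------------------------------------
# pixel-level operations


def fast_lifetime_map(image: FLIMImage, origin_ns: float | None = None) -> np.ndarray:
    """Per-pixel mean photon arrival time relative to ``origin_ns`` (the
    "fast lifetime" display estimator).

    No truncation correction is applied: for a decay comparable to the
    window length the value underestimates the true lifetime.  Pixels with
    zero photons are NaN.  When ``origin_ns`` is omitted it defaults to the
    bin-center time of the global (image-summed) histogram maximum, a proxy
    for the IRF peak.
    """
    centers = image.grid.centers_ns
    if origin_ns is None:
        pooled = image.counts.sum(axis=(0, 1))
        origin_ns = float(centers[int(np.argmax(pooled))])
    edges = image.grid.edges_ns
    if not edges[0] <= origin_ns <= edges[-1]:
        raise InvalidInputError("origin_ns lies outside the time window")
    totals = image.counts.sum(axis=2).astype(float)
    weighted = image.counts.astype(float) @ centers
    with np.errstate(invalid="ignore", divide="ignore"):
        out = weighted / totals - origin_ns
    out[totals == 0] = np.nan
    return out


def exclude_low_lifetime_pixels(
    image: FLIMImage,
    mask: ROIMask,
    threshold_ns: float,
    origin_ns: float | None = None,
) -> ROIMask:
    """Flip included ROI pixels whose fast lifetime is below ``threshold_ns``
    to the negative of their label (excluded).

    Mirrors the practice of rejecting organelle pixels with anomalously
    short lifetimes (plastids) before pooling a nucleus histogram.
    """
    if not threshold_ns > 0:
        raise InvalidInputError("threshold_ns must be positive")
    if mask.labels.shape != image.shape:
        raise InvalidInputError("mask shape does not match image shape")
    fl = fast_lifetime_map(image, origin_ns=origin_ns)
    labels = mask.labels.copy()
    flip = (labels > 0) & np.isfinite(fl) & (fl < threshold_ns)
    labels[flip] = -labels[flip]
    return ROIMask(labels=labels)


def pool_roi(image: FLIMImage, mask: ROIMask, label: int) -> TCSPCHistogram:
    """Sum counts over pixels carrying ``label`` into one ROI histogram.

    Excluded pixels (label ``-label``) are omitted.  Raises if the label is
    absent from the mask entirely.
    """
    if label <= 0:
        raise InvalidInputError("ROI labels are positive integers")
    if mask.labels.shape != image.shape:
        raise InvalidInputError("mask shape does not match image shape")
    if not np.any(np.abs(mask.labels) == label):
        raise InvalidInputError(f"label {label} not present in mask")
    sel = mask.labels == label
    counts = image.counts[sel].sum(axis=0)
    source = f"{image.metadata.get('path', 'image')}:roi={label}"
    return TCSPCHistogram(grid=image.grid, counts=counts, source=source)
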
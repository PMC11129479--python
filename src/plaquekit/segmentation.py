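"""Channel thresholding, deposit labeling and calibrated geometry.

Converts raw fluorescence channels into binary masks and labeled deposits,
and measures areas (µm²), perimeters (µm) and analysis frames.  All
coordinates are 0-based with half-open bounds; areas are pixel counts scaled
by the squared pixel size.

The perimeter estimator traces the subpixel marching-squares contour of a
region and smooths the closed vertex chain with a periodic Gaussian
(``sigma`` = 2 vertices) before summing segment lengths.  Raw boundary-pixel
counting overestimates curved boundaries (staircase bias), while few-direction
Crofton estimators systematically shorten axis-aligned straight edges; the
smoothed contour removes the staircase wiggle without eroding straight runs,
so disks, squares and thin bars are all recovered within a few percent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from skimage import measure as _measure
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

__all__ = [
    "MultiChannelImage",
    "BinaryMask",
    "LabelMask",
    "RegionFrame",
    "threshold_channel",
    "label_components",
    "measure_area",
    "measure_perimeter",
    "define_frame",
    "nearest_label",
    "read_image",
    "write_image",
]


@dataclass
class MultiChannelImage:
    """Named 2D intensity channels sharing one pixel grid.

    ``channels`` maps channel name to a 2D array (row, col; origin top-left).
    ``pixel_size_um`` is the physical edge length of one pixel in µm.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not self.channels:
            raise ValueError("image must contain at least one channel")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels differ in shape: {shapes}")
        self.shape = next(iter(shapes))
        if self.shape[0] == 0 or self.shape[1] == 0:
            raise ValueError("zero-area image")

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


@dataclass
class BinaryMask:
    """Boolean foreground mask for one channel."""

    pixels: np.ndarray
    pixel_size_um: float
    source_channel: str = ""
    threshold: float | None = None  # provenance: realized threshold value

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def area_um2(self) -> float:
        return float(self.pixels.sum()) * self.pixel_size_um**2


@dataclass
class LabelMask:
    """Connected deposits labeled 1..n_labels (0 = background)."""

    pixels: np.ndarray
    n_labels: int
    pixel_size_um: float
    connectivity: int = 8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.min() < 0:
            raise ValueError("labels must be non-negative")

    def mask_of(self, label_id: int) -> np.ndarray:
        if not 1 <= label_id <= self.n_labels:
            raise KeyError(f"label {label_id} not in 1..{self.n_labels}")
        return self.pixels == label_id

    @property
    def labels(self) -> list[int]:
        return list(range(1, self.n_labels + 1))


@dataclass
class RegionFrame:
    """Half-open pixel bounds of one analysis frame (FOV)."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int
    pixel_size_um: float
    constant_size: bool = False

    def __post_init__(self) -> None:
        if self.row_max <= self.row_min or self.col_max <= self.col_min:
            raise ValueError("frame bounds must enclose a positive area")

    @property
    def frame_area_um2(self) -> float:
        npx = (self.row_max - self.row_min) * (self.col_max - self.col_min)
        return float(npx) * self.pixel_size_um**2

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.row_min, self.row_max), slice(self.col_min, self.col_max)

    def contains(self, row: float, col: float) -> bool:
        return (self.row_min <= row < self.row_max) and (self.col_min <= col < self.col_max)

    def as_mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.slices] = True
        return m


# ---------------------------------------------------------------------------
# operations


def threshold_channel(
    img: MultiChannelImage,
    channel: str,
    method: str = "otsu",
    smooth_sigma_px: float = 0.0,
) -> BinaryMask:
    """Binarize one channel; foreground where intensity > threshold.

    ``method`` is ``"otsu"`` or ``"fixed:<value>"``.  With
    ``smooth_sigma_px`` > 0 the channel is Gaussian-denoised before
    thresholding, which keeps Otsu from splitting the background noise when
    the foreground occupies only a small pixel fraction (sparse markers).
    A constant-intensity channel under Otsu yields an all-false mask plus a
    logged warning.
    """
    if channel not in img.channels:
        raise KeyError(f"channel {channel!r} not in {img.channel_names}")
    data = img.channels[channel]
    if smooth_sigma_px > 0:
        data = gaussian_filter(data.astype(float), smooth_sigma_px)
    if method == "otsu":
        lo, hi = data.min(), data.max()
        if lo == hi:
            warnings.warn(
                f"channel {channel!r} has constant intensity {lo}; "
                "Otsu threshold undefined, returning empty mask",
                stacklevel=2,
            )
            return BinaryMask(
                np.zeros(data.shape, bool), img.pixel_size_um, channel, float(lo)
            )
        thr = float(threshold_otsu(data))
    elif method.startswith("fixed:"):
        thr = float(method.split(":", 1)[1])
        raw = img.channels[channel]
        info = np.iinfo(raw.dtype) if np.issubdtype(raw.dtype, np.integer) else None
        if info is not None and not (info.min <= thr <= info.max):
            raise ValueError(f"fixed threshold {thr} outside dtype range of {data.dtype}")
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    logger.info("threshold_channel(%s, %s) -> %.4g", channel, method, thr)
    return BinaryMask(data > thr, img.pixel_size_um, channel, thr)


def label_components(
    mask: BinaryMask, connectivity: int = 8, min_area_um2: float | None = None
) -> LabelMask:
    """Label connected foreground components, dropping small specks.

    Components with area below ``min_area_um2`` (default 4 px²) are removed;
    survivors are relabeled 1..n in raster-scan order of their first pixel.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if min_area_um2 is None:
        min_area_um2 = 4.0 * mask.pixel_size_um**2
    skconn = 1 if connectivity == 4 else 2
    lab = _measure.label(mask.pixels, connectivity=skconn)
    n = lab.max()
    if n == 0:
        return LabelMask(lab, 0, mask.pixel_size_um, connectivity)
    areas = np.bincount(lab.ravel(), minlength=n + 1)
    px_area = mask.pixel_size_um**2
    keep = np.flatnonzero(areas * px_area >= min_area_um2)
    keep = keep[keep > 0]
    # raster-scan order of first pixel per label
    flat = lab.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    idx = np.flatnonzero(flat)
    # reversed so earlier indices overwrite later ones
    first[flat[idx[::-1]]] = idx[::-1]
    keep = keep[np.argsort(first[keep])]
    remap = np.zeros(n + 1, dtype=lab.dtype)
    remap[keep] = np.arange(1, len(keep) + 1)
    return LabelMask(remap[lab], int(len(keep)), mask.pixel_size_um, connectivity)


def measure_area(
    mask_or_label: BinaryMask | LabelMask, label_id: int | None = None
) -> float:
    """Area in µm² of a mask, or of one labeled deposit."""
    if isinstance(mask_or_label, LabelMask):
        if label_id is None:
            raise ValueError("label_id required for a LabelMask")
        npx = int(mask_or_label.mask_of(label_id).sum())
        return npx * mask_or_label.pixel_size_um**2
    if label_id is not None:
        raise ValueError("label_id only applies to a LabelMask")
    return mask_or_label.area_um2


def _smoothed_contour_perimeter(mask: np.ndarray, sigma: float = 2.0) -> float:
    """Total length (px) of the Gaussian-smoothed subpixel contour."""
    padded = np.pad(mask, 1).astype(float)
    total = 0.0
    for contour in _measure.find_contours(padded, 0.5):
        closed = np.allclose(contour[0], contour[-1])
        poly = contour[:-1] if closed else contour
        if len(poly) > 8:
            poly = gaussian_filter1d(poly, sigma, axis=0, mode="wrap")
        d = np.diff(np.vstack([poly, poly[:1]]), axis=0)
        total += float(np.hypot(d[:, 0], d[:, 1]).sum())
    return total


def measure_perimeter(
    mask_or_label: BinaryMask | LabelMask, label_id: int | None = None
) -> float:
    """Perimeter in µm of a mask, or of one labeled deposit."""
    if isinstance(mask_or_label, LabelMask):
        if label_id is None:
            raise ValueError("label_id required for a LabelMask")
        m = mask_or_label.mask_of(label_id)
    else:
        m = mask_or_label.pixels
    return _smoothed_contour_perimeter(m) * mask_or_label.pixel_size_um


def define_frame(
    label: LabelMask,
    label_id: int,
    margin_um: float = 0.0,
    constant_size_um: float | None = None,
) -> RegionFrame:
    """Analysis frame around one deposit.

    Default: the deposit bounding box expanded by ``margin_um`` per side,
    clipped to the image.  With ``constant_size_um``, a square frame of that
    side length centered on the deposit centroid (the constant-size FOV
    convention for per-region readouts).
    """
    m = label.mask_of(label_id)
    rows, cols = np.nonzero(m)
    h, w = label.pixels.shape
    px = label.pixel_size_um
    if constant_size_um is not None:
        side = max(1, int(round(constant_size_um / px)))
        cr, cc = rows.mean(), cols.mean()
        r0 = int(round(cr - side / 2))
        c0 = int(round(cc - side / 2))
        r0 = min(max(r0, 0), max(h - side, 0))
        c0 = min(max(c0, 0), max(w - side, 0))
        return RegionFrame(r0, min(r0 + side, h), c0, min(c0 + side, w), px, True)
    marg = int(round(margin_um / px))
    return RegionFrame(
        max(int(rows.min()) - marg, 0),
        min(int(rows.max()) + 1 + marg, h),
        max(int(cols.min()) - marg, 0),
        min(int(cols.max()) + 1 + marg, w),
        px,
    )


def nearest_label(label: LabelMask, point: tuple[float, float]) -> int:
    """Label whose centroid lies closest to ``point`` (row, col in px)."""
    if label.n_labels == 0:
        raise ValueError("label mask is empty")
    best, best_d = 0, np.inf
    for prop in _measure.regionprops(label.pixels):
        d = np.hypot(prop.centroid[0] - point[0], prop.centroid[1] - point[1])
        if d < best_d:
            best, best_d = prop.label, d
    return best


# ---------------------------------------------------------------------------
# TIFF round-trip


def write_image(path, img: MultiChannelImage) -> None:
    """Write channels as a multi-plane TIFF (plane order = channel order)."""
    stack = np.stack([img.channels[name] for name in img.channel_names])
    tifffile.imwrite(
        path, stack, photometric="minisblack", planarconfig="separate",
        metadata={"axes": "CYX"},
    )


def read_image(path, channel_names: list[str], pixel_size_um: float) -> MultiChannelImage:
    """Read a single- or multi-plane TIFF; plane order must match names."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape[0] != len(channel_names):
        raise ValueError(
            f"TIFF has {arr.shape[0]} planes but {len(channel_names)} names given"
        )
    return MultiChannelImage(dict(zip(channel_names, arr)), pixel_size_um)
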
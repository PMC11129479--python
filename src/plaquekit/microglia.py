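"""Microglial plaque-response metrics.

PAM (plaque-associated microglia) are operationalized as Hoechst⁺ nuclei
whose centroid lies inside the plaque frame and whose pixels overlap the
Iba1 mask; density is PAM count per µm² of plaque.  Interface coverage is
the fraction of the dense-core boundary within a Chebyshev contact radius of
Iba1 signal.  Per-FOV marker readouts (CD68-in-Iba1, internalized Aβ,
Clec7a overlap, Ki-67⁺ microglia) are mask-intersection areas and counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.measure import regionprops

from .segmentation import BinaryMask, LabelMask, RegionFrame

__all__ = [
    "PAMRecord",
    "FOVRecord",
    "count_pam",
    "pam_density",
    "interface_coverage",
    "colocalized_area",
    "internalized_fraction",
    "clec7a_overlap_percent",
    "count_ki67_microglia",
    "ki67_per_pam_density",
]


@dataclass
class PAMRecord:
    """Microglial response of one plaque."""

    plaque_id: int
    pam_count: int
    plaque_area_um2: float
    pam_density: float  # per µm² of plaque
    interface_coverage: float | None = None  # ThioS⁺ plaques only


@dataclass
class FOVRecord:
    """Constant-size field-of-view marker readouts."""

    fov_id: int
    region_tag: str = ""
    cd68_in_iba1_area_um2: float = 0.0
    internalized_abeta_fraction: float = 0.0
    clec7a_overlap_pct: float = 0.0
    nestin_area_um2: float = 0.0
    ki67_pos_count: int = 0
    ki67_per_pam_density: float = 0.0


def _check_geometry(*masks) -> None:
    shapes = {m.pixels.shape for m in masks}
    if len(shapes) != 1:
        raise ValueError(f"masks differ in shape: {shapes}")


def count_pam(
    frame: RegionFrame, iba1_mask: BinaryMask, nuclei_label: LabelMask
) -> int:
    """Number of Iba1⁺ nuclei whose centroid lies inside the frame."""
    _check_geometry(iba1_mask, nuclei_label)
    count = 0
    for prop in regionprops(nuclei_label.pixels):
        if not frame.contains(*prop.centroid):
            continue
        rr, cc = zip(*prop.coords)
        if iba1_mask.pixels[list(rr), list(cc)].any():
            count += 1
    return count


def pam_density(pam_count: int, plaque_area_um2: float) -> float:
    """PAM per µm² of plaque area."""
    if plaque_area_um2 <= 0:
        raise ValueError("plaque area must be positive")
    return pam_count / plaque_area_um2


def interface_coverage(
    core_label: LabelMask,
    core_id: int,
    iba1_mask: BinaryMask,
    contact_radius_px: int = 1,
) -> float:
    """Fraction of the core's outer boundary covered by Iba1 signal.

    Boundary pixels are the 8-connected outer boundary of the core; a pixel
    counts as covered when any Iba1 pixel lies within Chebyshev distance
    ``contact_radius_px``.
    """
    if contact_radius_px < 1:
        raise ValueError("contact_radius_px must be >= 1")
    _check_geometry(core_label, iba1_mask)
    core = core_label.mask_of(core_id)
    if not core.any():
        raise ValueError(f"core {core_id} is empty")
    square3 = np.ones((3, 3), bool)
    boundary = binary_dilation(core, square3) & ~core
    reach = binary_dilation(
        iba1_mask.pixels, np.ones((2 * contact_radius_px + 1,) * 2, bool)
    )
    total = int(boundary.sum())
    covered = int((boundary & reach).sum())
    return covered / total


def colocalized_area(marker_mask: BinaryMask, container_mask: BinaryMask) -> float:
    """Area (µm²) of marker signal inside the container mask."""
    _check_geometry(marker_mask, container_mask)
    npx = int((marker_mask.pixels & container_mask.pixels).sum())
    return npx * marker_mask.pixel_size_um**2


def internalized_fraction(abeta_mask: BinaryMask, iba1_mask: BinaryMask) -> float:
    """Aβ area inside microglia, normalized to total Iba1 area."""
    _check_geometry(abeta_mask, iba1_mask)
    iba1_px = int(iba1_mask.pixels.sum())
    if iba1_px == 0:
        raise ValueError("empty Iba1 mask")
    return int((abeta_mask.pixels & iba1_mask.pixels).sum()) / iba1_px


def clec7a_overlap_percent(clec7a_mask: BinaryMask, iba1_mask: BinaryMask) -> float:
    """Clec7a area overlapping Iba1 as a percentage of total Iba1 area."""
    return 100.0 * internalized_fraction(clec7a_mask, iba1_mask)


def count_ki67_microglia(
    fov: RegionFrame,
    iba1_mask: BinaryMask,
    nuclei_label: LabelMask,
    ki67_mask: BinaryMask,
    nucleus_pos_fraction: float = 0.3,
) -> int:
    """Iba1⁺ nuclei in the FOV whose Ki-67⁺ pixel fraction reaches threshold."""
    _check_geometry(iba1_mask, nuclei_label, ki67_mask)
    if not 0 < nucleus_pos_fraction <= 1:
        raise ValueError("nucleus_pos_fraction must lie in (0, 1]")
    count = 0
    for prop in regionprops(nuclei_label.pixels):
        if not fov.contains(*prop.centroid):
            continue
        rr = prop.coords[:, 0]
        cc = prop.coords[:, 1]
        if not iba1_mask.pixels[rr, cc].any():
            continue
        frac = ki67_mask.pixels[rr, cc].mean()
        if frac >= nucleus_pos_fraction:
            count += 1
    return count


def ki67_per_pam_density(ki67_count: int, mean_pam_density: float) -> float:
    """Ki-67⁺ microglia count normalized to the region's mean PAM density."""
    if mean_pam_density <= 0:
        raise ValueError("mean PAM density must be positive")
    return ki67_count / mean_pam_density
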
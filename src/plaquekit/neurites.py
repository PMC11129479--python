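"""LAMP1⁺ dystrophic-neurite (DN) readouts.

Regional DN burden (percentage of the brain frame occupied by LAMP1⁺
spheroids), per-neuritic-plaque DN area, and the diffuse-vs-compact split of
neuritic plaques (diffuse = ThioS⁻).  Spheroids are not morphologically
filtered beyond an optional minimum-area cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

from .segmentation import BinaryMask, LabelMask, RegionFrame, label_components

__all__ = [
    "DNRecord",
    "dn_burden",
    "dn_area_per_plaque",
    "classify_diffuse_fraction",
    "measure_dn_records",
]

DEFAULT_MIN_SPHEROID_AREA_UM2 = 2.0


@dataclass
class DNRecord:
    """Dystrophic-neurite readout of one neuritic plaque."""

    plaque_id: int
    dn_area_um2: float
    abeta_area_um2: float
    iba1_area_um2: float
    is_diffuse: bool  # ThioS⁻ neuritic plaque


def dn_burden(lamp1_mask: BinaryMask, region_frame_mask: BinaryMask) -> float:
    """LAMP1⁺ area as a percentage of the region frame."""
    frame_px = int(region_frame_mask.pixels.sum())
    if frame_px == 0:
        raise ValueError("empty region frame")
    overlap = int((lamp1_mask.pixels & region_frame_mask.pixels).sum())
    return 100.0 * overlap / frame_px


def _filtered(lamp1_mask: BinaryMask, min_spheroid_area_um2: float | None):
    if min_spheroid_area_um2 is None:
        return lamp1_mask.pixels
    lab = label_components(lamp1_mask, min_area_um2=min_spheroid_area_um2)
    return lab.pixels > 0


def dn_area_per_plaque(
    lamp1_mask: BinaryMask,
    plaque_frame: RegionFrame,
    min_spheroid_area_um2: float | None = DEFAULT_MIN_SPHEROID_AREA_UM2,
) -> float:
    """Total LAMP1⁺ spheroid area (µm²) clipped to one plaque frame."""
    px = _filtered(lamp1_mask, min_spheroid_area_um2)
    npx = int(px[plaque_frame.slices].sum())
    return npx * lamp1_mask.pixel_size_um**2


def classify_diffuse_fraction(records: list[DNRecord]) -> float:
    """Percentage of neuritic plaques that are diffuse (ThioS⁻)."""
    if not records:
        raise ValueError("no DN records")
    return 100.0 * sum(r.is_diffuse for r in records) / len(records)


def measure_dn_records(
    abeta_label: LabelMask,
    lamp1_mask: BinaryMask,
    iba1_mask: BinaryMask,
    thios_positive: dict[int, bool],
    frames: dict[int, RegionFrame],
    min_spheroid_area_um2: float | None = DEFAULT_MIN_SPHEROID_AREA_UM2,
) -> list[DNRecord]:
    """One :class:`DNRecord` per neuritic plaque.

    A neuritic plaque is any Aβ deposit with in-frame LAMP1 area > 0.
    ``thios_positive`` maps plaque id to its core classification and
    ``frames`` to its analysis frame.
    """
    px2 = abeta_label.pixel_size_um**2
    records = []
    for lab in abeta_label.labels:
        frame = frames[lab]
        dn_area = dn_area_per_plaque(lamp1_mask, frame, min_spheroid_area_um2)
        if dn_area <= 0:
            continue
        sl = frame.slices
        plaque = abeta_label.pixels == lab
        records.append(
            DNRecord(
                plaque_id=lab,
                dn_area_um2=dn_area,
                abeta_area_um2=float(plaque.sum()) * px2,
                iba1_area_um2=float(iba1_mask.pixels[sl].sum()) * px2,
                is_diffuse=not thios_positive[lab],
            )
        )
    return records
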
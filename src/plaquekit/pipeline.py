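"""Scene-level analysis: from a multi-channel image to metric records.

Chains thresholding, deposit labeling, plaque morphometry, PAM counting,
interface coverage and dystrophic-neurite measurement into one call, the way
the per-section quantification is run in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .microglia import PAMRecord, count_pam, interface_coverage, pam_density
from .morphometry import (
    DEFAULT_MIN_CORE_AREA_UM2,
    BurdenSummary,
    PlaqueRecord,
    measure_plaques,
    summarize_burden,
)
from .neurites import DNRecord, measure_dn_records
from .segmentation import (
    BinaryMask,
    LabelMask,
    MultiChannelImage,
    define_frame,
    label_components,
    threshold_channel,
)

__all__ = ["SceneAnalysis", "analyze_scene"]


@dataclass
class SceneAnalysis:
    """All per-scene records produced by one pipeline run."""

    plaques: list[PlaqueRecord]
    pam: list[PAMRecord]
    dn: list[DNRecord]
    burden: BurdenSummary
    labels: LabelMask
    masks: dict[str, BinaryMask] = field(default_factory=dict)


def analyze_scene(
    img: MultiChannelImage,
    min_deposit_area_um2: float = 10.0,
    min_core_area_um2: float = DEFAULT_MIN_CORE_AREA_UM2,
    frame_margin_um: float = 14.0,
    contact_radius_px: int = 1,
    smooth_sigma_px: float = 1.0,
    region_tag: str = "",
) -> SceneAnalysis:
    """Quantify one section image end to end.

    Requires ``abeta``, ``thios``, ``iba1`` and ``hoechst`` channels;
    ``lamp1`` enables the dystrophic-neurite records.  The per-plaque frame
    is the deposit bounding box expanded by ``frame_margin_um``, which must
    be generous enough to catch the plaque's microglial ring.
    """
    masks = {
        name: threshold_channel(img, name, smooth_sigma_px=smooth_sigma_px)
        for name in ("abeta", "thios", "iba1", "hoechst")
    }
    labels = label_components(masks["abeta"], min_area_um2=min_deposit_area_um2)
    plaques = measure_plaques(
        labels, masks["thios"], min_core_area_um2, region_tag=region_tag
    )
    nuclei = label_components(masks["hoechst"], min_area_um2=1.0)
    frames = {
        lid: define_frame(labels, lid, margin_um=frame_margin_um)
        for lid in labels.labels
    }

    pam_records = []
    core_labels = LabelMask(
        np.where(masks["thios"].pixels, labels.pixels, 0),
        labels.n_labels,
        labels.pixel_size_um,
    )
    for rec in plaques:
        lid = rec.plaque_id
        frame = frames[lid]
        n = count_pam(frame, masks["iba1"], nuclei)
        plaque_in_frame = np.zeros(labels.pixels.shape, bool)
        plaque_in_frame[frame.slices] = labels.pixels[frame.slices] == lid
        area = float(plaque_in_frame.sum()) * labels.pixel_size_um**2
        cov = None
        if rec.thios_positive and (core_labels.pixels == lid).any():
            cov = interface_coverage(
                core_labels, lid, masks["iba1"], contact_radius_px
            )
        pam_records.append(
            PAMRecord(
                plaque_id=lid,
                pam_count=n,
                plaque_area_um2=area,
                pam_density=pam_density(n, area) if area > 0 else 0.0,
                interface_coverage=cov,
            )
        )

    dn_records: list[DNRecord] = []
    if "lamp1" in img.channels:
        masks["lamp1"] = threshold_channel(img, "lamp1", smooth_sigma_px=smooth_sigma_px)
        thios_pos = {r.plaque_id: r.thios_positive for r in plaques}
        dn_records = measure_dn_records(
            labels, masks["lamp1"], masks["iba1"], thios_pos, frames
        )

    frame_mask = BinaryMask(
        np.ones(labels.pixels.shape, bool), labels.pixel_size_um, "frame"
    )
    burden = summarize_burden(
        masks["abeta"], frame_mask, labels, masks["thios"], plaques
    )
    return SceneAnalysis(plaques, pam_records, dn_records, burden, labels, masks)
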
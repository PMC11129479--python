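"""Seeded, ground-truthed synthetic inputs for the whole pipeline.

Scenes idealize amyloid pathology as concentric disks: a dense fibrillar
core (ThioS⁺) embedded in a diffuse antibody-detected halo, so the true
compaction ``C = core area / halo area = (r_core / r_halo)²`` is available in
closed form.  Microglia are drawn as Iba1⁺ soma disks with Hoechst⁺ nuclei;
the microglia–core interface is realised as an annular Iba1 band spanning a
contiguous arc of exactly ``2π·f`` around the core, which makes the
interface-coverage truth exact.  LAMP1⁺ dystrophic-neurite spheroids form a
ring at a fixed radial offset outside the deposit halo, so larger deposits
carry larger DN annuli (the per-plaque DN-area vs Aβ-area correlation seen
in neuritic plaques).

Proteomic tables follow a multiplicative log-normal noise model around
per-group means ``baseline · 2^effect``, and Y-maze arm sequences are a
first-order alternation process with a controllable alternation probability.

Every generator consumes one explicit seed and is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmentation import MultiChannelImage

__all__ = [
    "SceneParams",
    "PlaqueTruth",
    "MicrogliaTruth",
    "GroundTruth",
    "ProteomicsDesign",
    "PlacementError",
    "generate_scene",
    "generate_proteomics",
    "generate_arm_sequence",
]

MAX_PLACEMENT_ATTEMPTS = 10_000

DEFAULT_CHANNEL_INTENSITIES: dict[str, tuple[float, float]] = {
    # channel: (foreground mean, background mean), 16-bit counts
    "abeta": (8000.0, 400.0),
    "thios": (10000.0, 300.0),
    "iba1": (6000.0, 400.0),
    "hoechst": (9000.0, 350.0),
}


class PlacementError(RuntimeError):
    """Rejection sampling exhausted while placing scene objects."""


@dataclass
class SceneParams:
    """Geometry, density and intensity settings for one synthetic section.

    Defaults emulate a 63x confocal field (1024² px at 0.25 µm/px ≈ 256 µm
    square) over subiculum-like plaque density: cores of 4–10 µm radius in
    halos up to 20 µm, a handful of plaque-associated microglia per deposit
    and a moderate background microglial density.
    """

    image_height_px: int = 1024
    image_width_px: int = 1024
    pixel_size_um: float = 0.25
    n_plaques: int = 6
    core_radius_range_um: tuple[float, float] = (4.0, 10.0)
    halo_radius_range_um: tuple[float, float] = (8.0, 20.0)
    compaction_range: tuple[float, float] | None = None  # overrides core range
    thios_positive_fraction: float = 0.7
    pam_count_range: tuple[int, int] = (2, 6)
    interface_fraction_range: tuple[float, float] = (0.2, 0.8)
    microglia_soma_radius_um: float = 4.0
    nucleus_radius_um: float = 2.0
    background_microglia_density_per_mm2: float = 50.0
    ki67_fraction: float = 0.1
    dn_annulus: tuple[float, float] | None = None  # radial offsets from halo, µm
    channel_intensities: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_INTENSITIES)
    )
    noise_sigma: float = 0.0
    placement_clearance_px: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("zero-area image")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_plaques < 0:
            raise ValueError("n_plaques must be non-negative")
        for name in ("core_radius_range_um", "halo_radius_range_um"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must satisfy 0 < min <= max")
        if self.core_radius_range_um[0] > self.halo_radius_range_um[1]:
            raise ValueError("core radii must not exceed all halo radii")
        lo, hi = self.interface_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("interface fractions must lie in [0, 1]")
        if self.compaction_range is not None:
            lo, hi = self.compaction_range
            if not (0 < lo <= hi <= 1):
                raise ValueError("compaction_range must lie in (0, 1]")
        if not (0 <= self.thios_positive_fraction <= 1):
            raise ValueError("thios_positive_fraction must lie in [0, 1]")
        if self.pam_count_range[0] < 0 or self.pam_count_range[1] < self.pam_count_range[0]:
            raise ValueError("pam_count_range must satisfy 0 <= min <= max")
        if self.microglia_soma_radius_um <= 0 or self.nucleus_radius_um <= 0:
            raise ValueError("microglia radii must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.dn_annulus is not None:
            inner, outer = self.dn_annulus
            if inner < 0 or outer <= inner:
                raise ValueError("dn_annulus must satisfy 0 <= inner < outer")


@dataclass
class PlaqueTruth:
    """What was actually drawn for one deposit."""

    plaque_id: int
    center: tuple[float, float]  # (row, col) px
    core_radius_px: float
    halo_radius_px: float
    true_compaction: float  # core area / halo area
    thios_positive: bool
    pam_count: int
    interface_fraction: float
    dn_area_um2: float = 0.0


@dataclass
class MicrogliaTruth:
    soma_center: tuple[float, float]
    nucleus_center: tuple[float, float]
    is_pam: bool
    is_ki67: bool
    plaque_id: int | None = None


@dataclass
class GroundTruth:
    """Truth side of every recovered metric, plus pre-noise foreground masks."""

    plaques: list[PlaqueTruth]
    microglia: list[MicrogliaTruth]
    true_burden_fraction: float
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "true_burden_fraction": self.true_burden_fraction,
            "plaques": [vars(p) for p in self.plaques],
            "microglia": [vars(m) for m in self.microglia],
        }


def _disk(shape, center, radius):
    r0 = max(int(np.floor(center[0] - radius)) - 1, 0)
    r1 = min(int(np.ceil(center[0] + radius)) + 2, shape[0])
    c0 = max(int(np.floor(center[1] - radius)) - 1, 0)
    c1 = min(int(np.ceil(center[1] + radius)) + 2, shape[1])
    yy, xx = np.mgrid[r0:r1, c0:c1]
    sub = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
    out = np.zeros(shape, dtype=bool)
    out[r0:r1, c0:c1] = sub
    return out


def _arc_band(shape, center, r_inner, r_outer, theta0, arc_width):
    """Annulus pixels whose polar angle lies within [theta0, theta0+arc_width)."""
    r0 = max(int(np.floor(center[0] - r_outer)) - 1, 0)
    r1 = min(int(np.ceil(center[0] + r_outer)) + 2, shape[0])
    c0 = max(int(np.floor(center[1] - r_outer)) - 1, 0)
    c1 = min(int(np.ceil(center[1] + r_outer)) + 2, shape[1])
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy, dx = yy - center[0], xx - center[1]
    rr2 = dy**2 + dx**2
    ring = (rr2 >= r_inner**2) & (rr2 <= r_outer**2)
    ang = np.mod(np.arctan2(dy, dx) - theta0, 2 * np.pi)
    ring &= ang < arc_width
    out = np.zeros(shape, dtype=bool)
    out[r0:r1, c0:c1] = ring
    return out


def generate_scene(params: SceneParams) -> tuple[MultiChannelImage, GroundTruth]:
    """Render one multi-channel scene and its exact ground truth.

    Channels rendered: ``abeta`` (halo disks), ``thios`` (core disks of
    ThioS⁺ plaques), ``iba1`` (interface bands + somas), ``hoechst``
    (nuclei); ``ki67``, ``lamp1``, ``cd68`` and ``clec7a`` when configured
    via ``channel_intensities`` / ``ki67_fraction`` / ``dn_annulus``.
    Additive Gaussian noise (``noise_sigma``) is applied last and clipped to
    the 16-bit range.
    """
    rng = np.random.default_rng(params.seed)
    shape = (params.image_height_px, params.image_width_px)
    px = params.pixel_size_um
    soma_r = params.microglia_soma_radius_um / px
    nuc_r = params.nucleus_radius_um / px
    band_th = soma_r  # interface band thickness (px)

    # --- sample plaque geometry ------------------------------------------
    halos_um = rng.uniform(*params.halo_radius_range_um, size=params.n_plaques)
    if params.compaction_range is not None:
        comp = rng.uniform(*params.compaction_range, size=params.n_plaques)
        cores_um = halos_um * np.sqrt(comp)
    else:
        cores_um = rng.uniform(*params.core_radius_range_um, size=params.n_plaques)
        cores_um = np.minimum(cores_um, halos_um)
    thios_pos = rng.random(params.n_plaques) < params.thios_positive_fraction
    pam_counts = rng.integers(
        params.pam_count_range[0], params.pam_count_range[1] + 1, size=params.n_plaques
    )
    ifracs = rng.uniform(*params.interface_fraction_range, size=params.n_plaques)
    theta0s = rng.uniform(0, 2 * np.pi, size=params.n_plaques)

    dn_outer_um = params.dn_annulus[1] if params.dn_annulus else 0.0
    # exclusion radius: halo, microglial ring and DN ring must fit around a plaque
    ring_r = cores_um / px + band_th + 2 * soma_r + 3
    extent = np.maximum.reduce(
        [halos_um / px, ring_r, (halos_um + dn_outer_um) / px + 1]
    )

    centers: list[tuple[float, float]] = []
    for i in range(params.n_plaques):
        e = extent[i]
        if 2 * e >= min(shape):
            raise PlacementError(
                f"plaque {i} (extent {e:.1f} px) cannot fit inside a "
                f"{shape[0]}x{shape[1]} px image"
            )
        placed = False
        for _ in range(MAX_PLACEMENT_ATTEMPTS):
            r = rng.uniform(e, shape[0] - e)
            c = rng.uniform(e, shape[1] - e)
            if all(
                np.hypot(r - rc, c - cc)
                > e + extent[j] + params.placement_clearance_px
                for j, (rc, cc) in enumerate(centers)
            ):
                centers.append((r, c))
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place plaque {i} without halo/ring overlap after "
                f"{MAX_PLACEMENT_ATTEMPTS} attempts"
            )

    # --- render foreground masks -----------------------------------------
    masks = {name: np.zeros(shape, bool) for name in params.channel_intensities}
    plaques: list[PlaqueTruth] = []
    microglia: list[MicrogliaTruth] = []

    for i, (r, c) in enumerate(centers):
        core_px = cores_um[i] / px
        halo_px = halos_um[i] / px
        masks["abeta"] |= _disk(shape, (r, c), halo_px)
        if thios_pos[i]:
            masks["thios"] |= _disk(shape, (r, c), core_px)
        f = float(ifracs[i])
        if f > 0:
            band = _arc_band(
                shape, (r, c), core_px, core_px + band_th, theta0s[i], 2 * np.pi * f
            )
            masks["iba1"] |= band
            if "nestin" in masks:
                masks["nestin"] |= band

        # PAM somata just outside the band, inside the arc when separation
        # permits, else equally spaced on the full ring
        n_pam = int(pam_counts[i])
        ring = core_px + band_th + soma_r + 2
        min_sep = (2 * nuc_r + 3) / ring  # radians between nucleus centers
        arc = 2 * np.pi * f
        if n_pam > 0:
            if f > 0 and arc >= n_pam * min_sep:
                angles = theta0s[i] + (np.arange(n_pam) + 0.5) * arc / n_pam
            else:
                angles = theta0s[i] + np.arange(n_pam) * 2 * np.pi / n_pam
            for ang in angles:
                sc = (r + ring * np.sin(ang), c + ring * np.cos(ang))
                masks["iba1"] |= _disk(shape, sc, soma_r)
                masks["hoechst"] |= _disk(shape, sc, nuc_r)
                if "cd68" in masks:
                    masks["cd68"] |= _disk(shape, sc, soma_r / 2)
                if "clec7a" in masks:
                    masks["clec7a"] |= _disk(shape, sc, soma_r)
                is_ki = bool(rng.random() < params.ki67_fraction)
                if is_ki and "ki67" in masks:
                    masks["ki67"] |= _disk(shape, sc, nuc_r)
                microglia.append(MicrogliaTruth(sc, sc, True, is_ki, i))

        dn_area = 0.0
        if params.dn_annulus is not None and "lamp1" in masks:
            inner = halo_px + params.dn_annulus[0] / px
            outer = halo_px + params.dn_annulus[1] / px
            ann = _disk(shape, (r, c), outer) & ~_disk(shape, (r, c), inner)
            masks["lamp1"] |= ann
            dn_area = float(ann.sum()) * px**2

        plaques.append(
            PlaqueTruth(
                plaque_id=i,
                center=(r, c),
                core_radius_px=core_px,
                halo_radius_px=halo_px,
                true_compaction=float((cores_um[i] / halos_um[i]) ** 2),
                thios_positive=bool(thios_pos[i]),
                pam_count=n_pam,
                interface_fraction=f,
                dn_area_um2=dn_area,
            )
        )

    # --- background microglia --------------------------------------------
    area_mm2 = shape[0] * shape[1] * (px / 1000.0) ** 2
    n_bg = int(rng.poisson(params.background_microglia_density_per_mm2 * area_mm2))
    margin = soma_r + 1
    for _ in range(n_bg):
        for _ in range(MAX_PLACEMENT_ATTEMPTS):
            r = rng.uniform(margin, shape[0] - margin)
            c = rng.uniform(margin, shape[1] - margin)
            clear = all(
                np.hypot(r - rc, c - cc) > extent[j] + soma_r + 2
                for j, (rc, cc) in enumerate(centers)
            ) and all(
                np.hypot(r - m.soma_center[0], c - m.soma_center[1]) > 2 * soma_r + 2
                for m in microglia
                if not m.is_pam
            )
            if clear:
                masks["iba1"] |= _disk(shape, (r, c), soma_r)
                masks["hoechst"] |= _disk(shape, (r, c), nuc_r)
                is_ki = bool(rng.random() < params.ki67_fraction)
                if is_ki and "ki67" in masks:
                    masks["ki67"] |= _disk(shape, (r, c), nuc_r)
                microglia.append(MicrogliaTruth((r, c), (r, c), False, is_ki, None))
                break
        else:
            raise PlacementError(
                "could not place a background microglion without overlap"
            )

    # --- intensities and noise -------------------------------------------
    channels: dict[str, np.ndarray] = {}
    for name, (fg, bg) in params.channel_intensities.items():
        plane = np.full(shape, bg, dtype=np.float64)
        plane[masks[name]] = fg
        if params.noise_sigma > 0:
            plane += rng.normal(0.0, params.noise_sigma, size=shape)
        channels[name] = np.clip(np.round(plane), 0, 65535).astype(np.uint16)

    burden = float(masks["abeta"].sum()) / (shape[0] * shape[1])
    truth = GroundTruth(plaques, microglia, burden, masks)
    return MultiChannelImage(channels, px), truth


# ---------------------------------------------------------------------------
# proteomics


@dataclass
class ProteomicsDesign:
    """Design of a synthetic protein-abundance experiment.

    ``log2_effects`` holds one log₂ offset per protein and group relative to
    the common baseline (0 = no effect); the true log₂ fold change of a
    contrast A vs B is the difference of the two columns.  Noise is
    multiplicative log-normal with coefficient of variation ``cv`` and unit
    mean, so group means equal ``baseline_mean · 2^effect`` in expectation
    (exactly, for ``cv = 0``).
    """

    n_proteins: int
    groups: list[tuple[str, int]]  # (label, replicate count)
    log2_effects: np.ndarray | None = None  # (n_proteins, n_groups)
    baseline_mean: float = 1e6
    cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if any(n < 2 for _, n in self.groups):
            raise ValueError("every group needs at least 2 replicates")
        if self.log2_effects is None:
            self.log2_effects = np.zeros((self.n_proteins, len(self.groups)))
        self.log2_effects = np.asarray(self.log2_effects, dtype=float)
        if self.log2_effects.shape != (self.n_proteins, len(self.groups)):
            raise ValueError("log2_effects must be (n_proteins, n_groups)")


def generate_proteomics(design: ProteomicsDesign):
    """Proteins × samples abundance table with known group effects."""
    from .proteomics import AbundanceTable

    rng = np.random.default_rng(design.seed)
    sigma = np.sqrt(np.log1p(design.cv**2))
    cols, data, group_of = [], [], {}
    for g, (label, n_rep) in enumerate(design.groups):
        mean = design.baseline_mean * 2.0 ** design.log2_effects[:, g]
        for rep in range(n_rep):
            sample = f"{label}_{rep + 1}"
            cols.append(sample)
            group_of[sample] = label
            if sigma > 0:
                noise = rng.lognormal(-(sigma**2) / 2, sigma, size=design.n_proteins)
            else:
                noise = 1.0
            data.append(mean * noise)
    ids = [f"P{i + 1:05d}" for i in range(design.n_proteins)]
    values = pd.DataFrame(np.column_stack(data), index=ids, columns=cols)
    return AbundanceTable(values, group_of)


# ---------------------------------------------------------------------------
# Y-maze


def generate_arm_sequence(p_alternate: float, n_entries: int, seed: int = 0):
    """Arm-entry sequence over {1,2,3} with no immediate repeats.

    After the first two (random, distinct) entries, each new entry completes
    an alternation (arm distinct from the previous two) with probability
    ``p_alternate``, otherwise returns to the arm visited two entries ago.
    """
    from .stats import ArmSequence

    if not 0 <= p_alternate <= 1:
        raise ValueError("p_alternate must lie in [0, 1]")
    if n_entries < 3:
        raise ValueError("n_entries must be at least 3")
    rng = np.random.default_rng(seed)
    arms = {1, 2, 3}
    entries = [int(rng.integers(1, 4))]
    entries.append(int(rng.choice(sorted(arms - {entries[0]}))))
    for _ in range(n_entries - 2):
        prev2, prev1 = entries[-2], entries[-1]
        alternating = (arms - {prev1, prev2}).pop()
        if rng.random() < p_alternate:
            entries.append(alternating)
        else:
            entries.append(prev2)
    return ArmSequence(entries)
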
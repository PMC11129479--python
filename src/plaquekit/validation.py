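"""Property-based validation harness: parameter recovery and worked examples.

Each function runs one verifiable study on seeded synthetic data — parameter
recovery for the imaging metrics, calibration and power for the statistics —
and returns the measured quantities together with the problem size used.
``scripts/acceptance.py`` reports these numbers; the test suite asserts
their tolerances.
"""

from __future__ import annotations

import numpy as np

from .microglia import count_pam, interface_coverage, pam_density
from .morphometry import core_circularity, measure_plaques
from .pipeline import analyze_scene
from .proteomics import normalize_global_mean, pairwise_compare, select_candidates
from .proteomics import triangle_vertices, triplot_coordinates
from .segmentation import (
    BinaryMask,
    LabelMask,
    define_frame,
    label_components,
    measure_area,
    measure_perimeter,
    nearest_label,
    threshold_channel,
)
from .stats import GroupTable, alternation_index, holm_sidak, one_way_anova
from .synthetic import (
    ProteomicsDesign,
    SceneParams,
    _arc_band,
    _disk,
    generate_arm_sequence,
    generate_proteomics,
    generate_scene,
)

__all__ = [
    "compaction_recovery",
    "pam_counting_exactness",
    "interface_recovery",
    "circularity_benchmarks",
    "holm_sidak_check",
    "anova_checks",
    "proteomics_checks",
    "triplot_checks",
    "alternation_checks",
    "directional_cohort_study",
]

# noise_sigma = 10% of the dimmest foreground level (iba1 at 6000 counts)
TEN_PCT_FOREGROUND_SIGMA = 600.0


def _scene_params(seed: int, **overrides) -> SceneParams:
    base = dict(
        image_height_px=512,
        image_width_px=512,
        pixel_size_um=0.5,
        n_plaques=5,
        thios_positive_fraction=1.0,
        background_microglia_density_per_mm2=0.0,
        seed=seed,
    )
    base.update(overrides)
    return SceneParams(**base)


def compaction_recovery(seed: int = 0, n_scenes: int = 10) -> dict:
    """Recover per-plaque compaction from noisy scenes.

    True compaction uniform in [0.1, 0.9], additive noise at 10% of the
    foreground level; returns the mean absolute error over all plaques.
    """
    errors = []
    for k in range(n_scenes):
        params = _scene_params(
            seed * 1009 + k,
            compaction_range=(0.1, 0.9),
            noise_sigma=TEN_PCT_FOREGROUND_SIGMA,
        )
        img, truth = generate_scene(params)
        labels = label_components(threshold_channel(img, "abeta"), min_area_um2=10)
        recs = {r.plaque_id: r for r in
                measure_plaques(labels, threshold_channel(img, "thios"))}
        for t in truth.plaques:
            rec = recs[nearest_label(labels, t.center)]
            errors.append(abs(rec.compaction - t.true_compaction))
    return {"mae": float(np.mean(errors)), "n": len(errors)}


def pam_counting_exactness(seed: int = 0, n_scenes: int = 25) -> dict:
    """Count PAM on plaques carrying 0–8 well-separated microglia each.

    Returns the percentage of plaques counted exactly and the largest
    deviation between reported density and count/area.
    """
    exact = total = 0
    density_err = 0.0
    for k in range(n_scenes):
        params = _scene_params(
            seed * 2003 + k,
            image_height_px=640,
            image_width_px=640,
            n_plaques=4,
            pam_count_range=(0, 8),
            placement_clearance_px=64.0,
        )
        img, truth = generate_scene(params)
        iba1 = threshold_channel(img, "iba1")
        nuclei = label_components(threshold_channel(img, "hoechst"), min_area_um2=1)
        labels = label_components(threshold_channel(img, "abeta"), min_area_um2=10)
        for t in truth.plaques:
            lid = nearest_label(labels, t.center)
            frame = define_frame(
                labels, lid, margin_um=3 * params.microglia_soma_radius_um + 2
            )
            n = count_pam(frame, iba1, nuclei)
            area = measure_area(labels, lid)
            density_err = max(density_err, abs(pam_density(n, area) - n / area))
            total += 1
            exact += int(n == t.pam_count)
    return {
        "exact_pct": 100.0 * exact / total,
        "density_max_abs_err": density_err,
        "n": total,
    }


def interface_recovery(
    targets=(0.0, 0.25, 0.5, 0.75, 1.0), radius_px: int = 40
) -> dict:
    """Measure coverage of constructed cores with known arc fractions."""
    shape = (300, 300)
    center = (150.0, 150.0)
    core = LabelMask(_disk(shape, center, radius_px).astype(int), 1, 0.5)
    errors = {}
    for f in targets:
        if f > 0:
            iba1 = _arc_band(shape, center, radius_px, radius_px + 16, 0.7,
                             2 * np.pi * f)
        else:
            iba1 = np.zeros(shape, bool)
        measured = interface_coverage(core, 1, BinaryMask(iba1, 0.5))
        errors[f] = abs(measured - f)
    return {
        "max_abs_err": max(errors.values()),
        "per_target": errors,
        "n": len(targets),
    }


def circularity_benchmarks() -> dict:
    """Circularity of a rasterized disk (r=50), square (50²) and 3×60 bar."""
    def circ(mask):
        m = BinaryMask(mask, 1.0)
        return core_circularity(measure_area(m), measure_perimeter(m))

    yy, xx = np.mgrid[:111, :111]
    disk = (yy - 55) ** 2 + (xx - 55) ** 2 <= 50**2
    square = np.zeros((60, 60), bool)
    square[5:55, 5:55] = True
    bar = np.zeros((10, 70), bool)
    bar[3:6, 5:65] = True
    return {"disk_r50": circ(disk), "square_50": circ(square), "bar_3x60": circ(bar)}


def _holm_sidak_brute(p: np.ndarray) -> np.ndarray:
    """Step-down reference: explicit loop over the sorted p-values."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        stepped = 1.0 - (1.0 - p[idx]) ** (m - i)
        running = max(running, min(stepped, 1.0))
        adj[idx] = running
    return adj


def holm_sidak_check(seed: int = 0, n_vectors: int = 1000) -> dict:
    """Worked pair [0.01, 0.04] plus brute-force agreement on random vectors."""
    worked = holm_sidak([0.01, 0.04])
    rng = np.random.default_rng(seed + 17)
    max_dev = 0.0
    monotone = True
    for _ in range(n_vectors):
        p = rng.random(int(rng.integers(1, 15)))
        ours = np.array(holm_sidak(p))
        ref = _holm_sidak_brute(p)
        max_dev = max(max_dev, float(np.abs(ours - ref).max()))
        s = ours[np.argsort(p, kind="stable")]
        monotone &= bool(np.all(np.diff(s) >= -1e-12)) and bool(np.all(ours <= 1.0))
    return {
        "worked_first_adjusted": worked[0],
        "worked_second_adjusted": worked[1],
        "oracle_max_abs_dev": max_dev,
        "monotone_and_clipped": monotone,
        "n": n_vectors,
    }


def anova_checks(seed: int = 0, n_null_tables: int = 2000) -> dict:
    """Worked F example and the type-I rate under the global null.

    Null: 2,000 tables of 3 groups × n=10 standard-normal observations.
    """
    worked = one_way_anova(
        GroupTable("m", {"a": [1, 2, 3], "b": [2, 3, 4], "c": [3, 4, 5]})
    )
    rng = np.random.default_rng(seed + 29)
    rejections = 0
    for _ in range(n_null_tables):
        x = rng.standard_normal((3, 10))
        res = one_way_anova(GroupTable("m", {str(i): x[i] for i in range(3)}))
        rejections += int(res.p_value <= 0.05)
    return {
        "worked_F": worked.statistic,
        "worked_df1": worked.df[0],
        "worked_df2": worked.df[1],
        "type1_rate": rejections / n_null_tables,
        "n": n_null_tables,
    }


def proteomics_checks(seed: int = 0, n_power_seeds: int = 50) -> dict:
    """Null calibration, noise-free gate exactness and power at FC=3."""
    # global null: cv=0.2, n=5/group, 2000 proteins
    null_design = ProteomicsDesign(
        n_proteins=2000, groups=[("A", 5), ("B", 5)], cv=0.2, seed=seed + 41
    )
    results = pairwise_compare(
        normalize_global_mean(generate_proteomics(null_design)), "A", "B"
    )
    null_rate = float(np.mean([r.p_value <= 0.05 for r in results]))
    sel = select_candidates(results)
    joint_rate = (len(sel["increased"]) + len(sel["decreased"])) / len(results)

    # noise-free: flagged set must equal proteins with |log2fc| >= log2(1.5)
    rng = np.random.default_rng(seed + 43)
    lfc = np.zeros((300, 2))
    lfc[:150, 0] = rng.uniform(-2, 2, 150)
    table = generate_proteomics(
        ProteomicsDesign(300, [("A", 3), ("B", 3)], lfc, cv=0.0, seed=seed + 47)
    )
    res0 = pairwise_compare(table, "A", "B")
    sel0 = select_candidates(res0)
    flagged = {r.protein_id for r in sel0["increased"] + sel0["decreased"]}
    expected = {
        pid for pid, e in zip(table.protein_ids, lfc[:, 0])
        if abs(e) >= np.log2(1.5)
    }
    exact = flagged == expected

    # power: FC=3, cv=0.1, n=5/group across seeds
    lfc3 = np.zeros((100, 2))
    lfc3[:, 0] = np.log2(3.0)
    selected = total = 0
    for k in range(n_power_seeds):
        design = ProteomicsDesign(
            100, [("A", 5), ("B", 5)], lfc3, cv=0.1, seed=seed * 53 + k
        )
        r = pairwise_compare(generate_proteomics(design), "A", "B")
        selected += len(select_candidates(r)["increased"])
        total += 100
    return {
        "null_p05_rate": null_rate,
        "null_joint_gate_rate": joint_rate,
        "noise_free_gate_exact": bool(exact),
        "power_fc3_selection_rate": selected / total,
        "n": null_design.n_proteins,
    }


def triplot_checks() -> dict:
    """Centroid mapping, nearest-vertex association and label symmetry."""
    import pandas as pd

    from .proteomics import AbundanceTable

    def table(means):
        cols, groups = {}, {}
        for g, m in zip("ABC", means):
            for i in (1, 2):
                cols[f"{g}{i}"] = [float(m)]
                groups[f"{g}{i}"] = g
        return AbundanceTable(pd.DataFrame(cols, index=["P"]), groups)

    verts = triangle_vertices()
    centroid = verts.mean(axis=0)
    pt_eq = triplot_coordinates(table([1, 1, 1]), ("A", "B", "C"))[0]
    centroid_dist = float(np.hypot(*(np.array(pt_eq.xy) - centroid)))

    pt_up = triplot_coordinates(table([4, 1, 1]), ("A", "B", "C"))[0]
    d = [float(np.hypot(*(np.array(pt_up.xy) - v))) for v in verts]
    nearest_own_vertex = d[0] < d[1] and d[0] < d[2]

    base = triplot_coordinates(table([5, 2, 1]), ("A", "B", "C"))[0]
    swap = triplot_coordinates(table([5, 2, 1]), ("B", "A", "C"))[0]
    sym_dev = float(
        max(
            abs(swap.weights[0] - base.weights[1]),
            abs(swap.weights[1] - base.weights[0]),
            abs(swap.weights[2] - base.weights[2]),
        )
    )
    return {
        "centroid_distance": centroid_dist,
        "nearest_own_vertex": bool(nearest_own_vertex),
        "label_symmetry_dev": sym_dev,
        "n": 3,
    }


def alternation_checks(seed: int = 0) -> dict:
    """Worked sequences plus the generator at p_alternate = 0.5, n = 1000."""
    return {
        "perfect": alternation_index([1, 2, 3, 1, 2, 3]),
        "never": alternation_index([1, 2, 1, 2, 1]),
        "mixed": alternation_index([1, 2, 3, 2, 1, 3]),
        "p_half_empirical": alternation_index(
            generate_arm_sequence(0.5, 1000, seed=seed + 61)
        ),
        "n": 1000,
    }


COMPACT_COHORT = dict(
    compaction_range=(0.5, 0.8),
    pam_count_range=(5, 8),
    interface_fraction_range=(0.6, 0.9),
    dn_annulus=(1.0, 3.0),
)
DIFFUSE_COHORT = dict(
    compaction_range=(0.1, 0.3),
    pam_count_range=(1, 3),
    interface_fraction_range=(0.1, 0.3),
    dn_annulus=(2.0, 6.0),
)


def directional_cohort_study(seed: int = 0, n_per_group: int = 5) -> dict:
    """Two synthetic cohorts through the full pipeline.

    A compact-plaque/high-PAM cohort against a diffuse-plaque/low-PAM one
    (``n_per_group`` scenes each, one scene standing in for one animal);
    the group comparison must recover the injected ordering on compaction,
    PAM density, interface coverage and DN area.  Returns per-metric ANOVA
    p-values and direction flags.
    """
    lamp1 = {"lamp1": (7500.0, 350.0)}
    metrics: dict[str, dict[str, list[float]]] = {
        m: {"compact": [], "diffuse": []}
        for m in ("compaction", "pam_density", "interface_coverage", "dn_area")
    }
    for label, cohort in (("compact", COMPACT_COHORT), ("diffuse", DIFFUSE_COHORT)):
        for k in range(n_per_group):
            params = _scene_params(
                seed * 4001 + k + (0 if label == "compact" else 5_000),
                image_height_px=640,
                image_width_px=640,
                n_plaques=4,
                placement_clearance_px=64.0,
                noise_sigma=TEN_PCT_FOREGROUND_SIGMA,
                channel_intensities={
                    **SceneParams().channel_intensities, **lamp1
                },
                **cohort,
            )
            img, _ = generate_scene(params)
            analysis = analyze_scene(img, frame_margin_um=3 * 4.0 + 2)
            # per-scene (per-animal) means
            metrics["compaction"][label].append(
                float(np.mean([r.compaction for r in analysis.plaques]))
            )
            metrics["pam_density"][label].append(
                float(np.mean([r.pam_density for r in analysis.pam]))
            )
            cov = [r.interface_coverage for r in analysis.pam
                   if r.interface_coverage is not None]
            metrics["interface_coverage"][label].append(float(np.mean(cov)))
            metrics["dn_area"][label].append(
                float(np.mean([r.dn_area_um2 for r in analysis.dn]))
            )
    out = {"n": 2 * n_per_group}
    for name, groups in metrics.items():
        res = one_way_anova(GroupTable(name, groups))
        hi, lo = np.mean(groups["compact"]), np.mean(groups["diffuse"])
        expected_sign = -1.0 if name == "dn_area" else 1.0
        out[f"{name}_p"] = res.p_value
        out[f"{name}_direction_ok"] = bool((hi - lo) * expected_sign > 0)
    return out
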
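# plaquekit

Quantification of amyloid plaque pathology and the microglial response to it,
for fluorescence-microscopy studies of amyloidosis mouse models (e.g. 5XFAD).
The package turns multi-channel section images (anti-Aβ antibody, Thioflavin-S,
Iba1, Hoechst, and optional CD68 / Clec7a / Ki-67 / nestin / LAMP1 stains) into
per-deposit and per-region readouts, adds the matching proteomic three-way
comparison and behavioral/biochemical indices, and ships a seeded synthetic-data
generator with exact ground truth so that every metric is testable by parameter
recovery.

## What it computes

**Plaque morphometry** — per deposit and per region:

- Aβ burden `B = area(Aβ ∧ frame) / area(frame)`, deposit counts and the
  percentage of ThioS⁺ (dense-core) deposits;
- plaque compaction `C = A_ThioS / A_Aβ`, per deposit or summed over a region;
- dense-core circularity `S = 4πA/P²` (clipped to [0, 1]), with a
  smoothed-subpixel-contour perimeter estimator.

**Microglial response:**

- PAM (plaque-associated microglia) counts — Iba1⁺ Hoechst⁺ nuclei inside the
  plaque frame — and density `ρ = N_PAM / plaque area`;
- microglia–core interface coverage `f` — the fraction of the ThioS-core
  boundary within a contact radius of Iba1 signal;
- per-FOV colocalization readouts: CD68 area inside Iba1, internalized-Aβ
  fraction, Clec7a/Iba1 overlap %, nestin area, Ki-67⁺ microglia counts
  (optionally normalized to mean PAM density).

**Dystrophic neurites:** LAMP1⁺ spheroid burden as % of the region frame,
per-neuritic-plaque DN area, diffuse (ThioS⁻) vs compact plaque split.

**Proteomics:** global-mean normalization, per-protein Welch t on log₂
abundances with the joint gate (fold change ≥ 1.5, p ≤ 0.05), a barycentric
triangle projection summarizing three pairwise contrasts (equal levels map to
the centroid, group-elevated proteins move toward that group's vertex), and
per-protein Z-score matrices.

**Statistics and behavior:** D'Agostino–Pearson normality screen, one-way
ANOVA, Holm–Šidák step-down adjusted p-values, Pearson correlation; Aβ42/Aβ40
and ApoE/Aβ42 assay ratios and proteinase-K resistance %; the Y-maze
spontaneous-alternation index `AI = alternations / (entries − 2)`.

**Synthetic data:** `plaquekit.synthetic` draws scenes of concentric-disk
plaques (core within halo, so true compaction is `(r_core/r_halo)²` in closed
form), arc-band microglial interfaces with exact coverage fractions, separated
PAM somata with nuclei, and LAMP1 annuli; plus proteomic abundance tables with
known log₂ effects and arm-entry sequences with a set alternation probability.
Identical parameters + seed reproduce outputs byte for byte.

## Worked example

```python
from plaquekit.synthetic import SceneParams, generate_scene
from plaquekit.pipeline import analyze_scene

params = SceneParams(
    image_height_px=640, image_width_px=640, pixel_size_um=0.5,
    n_plaques=4, thios_positive_fraction=0.75, noise_sigma=600.0,
    dn_annulus=(2.0, 6.0),
    channel_intensities={
        "abeta": (8000.0, 400.0), "thios": (10000.0, 300.0),
        "iba1": (6000.0, 400.0), "hoechst": (9000.0, 350.0),
        "lamp1": (7500.0, 350.0),
    },
    seed=7,
)
img, truth = generate_scene(params)
analysis = analyze_scene(img, frame_margin_um=14.0)
```

Printing the records gives:

```
deposits: 4
Abeta burden: 0.0309 (truth 0.0309)
ThioS+ deposits: 75%
global compaction: 0.180
plaque 1: A_abeta= 1106.8 um2  C=0.243  S=1.00  PAM=3  rho=0.0027/um2  f=0.54
plaque 2: A_abeta=  941.5 um2  C=0.054  S=1.00  PAM=6  rho=0.0064/um2  f=0.82
plaque 3: A_abeta=  754.5 um2  C=0.000  S=nan   PAM=6  rho=0.0080/um2  f=-
plaque 4: A_abeta=  361.0 um2  C=0.693  S=1.00  PAM=4  rho=0.0111/um2  f=0.69
```

Reading: 3.1% of the frame is Aβ⁺; the generator drew the four plaques with
true compactions 0.242, 0.054, 0.140 and 0.696 — the pipeline recovers 0.243,
0.054, 0.000 (this deposit is ThioS⁻, so no core is detected) and 0.693, and
the interface coverages (0.53, 0.80, –, 0.68) come back as 0.54, 0.82, 0.69.
Deposit 3's extra microglion is a background cell whose soma wandered into the
analysis frame — exactly the kind of bystander a real frame picks up.

The same pipeline runs from the shell:

```bash
plaquekit simulate scene --config scene.yaml --seed 7 --out scene.tif --truth truth.json
plaquekit analyze --image scene.tif --pixel-size 0.5 \
    --channels abeta,thios,iba1,hoechst,lamp1 --out results/
plaquekit simulate ymaze --p-alt 0.5 --n 30 --seed 1 --out arms.csv
plaquekit stats report --metrics metrics.csv --out report/
```

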
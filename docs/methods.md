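# Methods

## Scope and model

plaquekit re-implements, as a reusable and testable pipeline, the bespoke
image-quantification, proteomic-comparison and statistical procedures used in
immunofluorescence studies of amyloid pathology: plaque burden and
compaction, plaque-associated microglia (PAM), the microglia–core interface,
dystrophic-neurite (DN) readouts, a three-way proteomic projection, assay
ratios and the Y-maze alternation index. Because the animal imaging and
LC–MS data behind such studies are not desk-reproducible, the package pairs
every metric with a seeded synthetic generator that knows the ground truth,
so correctness is established by parameter recovery and oracle equivalence
rather than by re-deriving published group means.

## Synthetic scenes

A scene is a 16-bit multi-channel 2D image plus a `GroundTruth` record of
everything drawn.

**Plaques** are concentric disks: a dense fibrillar core (radius `r_core`,
rendered in the ThioS channel when the plaque is ThioS⁺) inside a diffuse
antibody-detected halo (`r_halo`, Aβ channel). True compaction is therefore
`C = (r_core/r_halo)²` in closed form. `compaction_range` lets a study
sample `C` directly (core derived from halo); otherwise core and halo radii
are sampled independently from their ranges with `core ≤ halo` enforced.
Halos are placed by rejection sampling (at most 10,000 attempts, then an
explicit `PlacementError`) with non-overlap enforced on an exclusion radius
covering halo, microglial ring and DN annulus, plus a configurable
clearance (`placement_clearance_px`, default 2 px). Studies that measure
per-plaque quantities inside generous analysis frames raise the clearance
(64 px in the validation harness) so a frame can never capture a neighbor's
microglia.

**Microglia–core interface.** The interface truth is realised as an annular
Iba1 band of soma-radius thickness starting at the core boundary and
spanning a contiguous arc of exactly `2π·f`. PAM somata (with concentric
Hoechst⁺ nuclei) are placed just outside the band — inside the arc when the
nucleus-separation constraint permits, otherwise equally spaced on the full
ring. Placing the somata on the boundary itself (an alternative we
rejected) would add uncontrolled coverage beyond `f` and can force nucleus
collisions for high counts on short arcs; the band construction keeps both
the interface truth and PAM-count truth exact and independent.

**Dystrophic neurites** are LAMP1⁺ annuli spanning radial offsets
`dn_annulus = (inner, outer)` µm outside the halo. Anchoring the ring to the
deposit radius makes per-plaque DN area grow with deposit size, which is the
correlation structure (DN area vs Aβ area) the downstream Pearson harness
verifies.

**Intensities and noise.** Each channel has a foreground/background mean;
additive Gaussian noise (`noise_sigma`) is applied last and clipped to the
16-bit range. The validation studies use `noise_sigma = 600`, i.e. 10% of
the dimmest foreground level (Iba1 at 6,000 counts). One
`numpy.random.default_rng(seed)` stream drives each generate call; identical
parameters and seed give byte-identical output.

**Defaults.** 1024² px at 0.25 µm/px (a 63× confocal field of ~256 µm),
cores 4–10 µm, halos 8–20 µm, 2–6 PAM per plaque, interface fractions
0.2–0.8, 70% ThioS⁺ deposits, soma radius 4 µm, nucleus radius 2 µm,
50 background microglia/mm². These are a realistic subiculum-like plaque
field; validation studies shrink the canvas (512–640 px at 0.5 µm/px) to
keep run times in seconds without changing the geometry regime.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: microglial process morphology (somata are disks;
the interface band stands in for enveloping processes), point-spread-function
optics and autofluorescence, 3D structure (the artifact is strictly 2D,
matching analyses performed on single focal planes), irregular plaque
shapes, and staining variability between sections. Parameter recovery here
demonstrates that the measurement chain is unbiased on geometry it
understands, not that thresholds transfer to arbitrary real images.

## Segmentation choices

- **Thresholding** defaults to Otsu per channel with a `fixed:<value>`
  override; the realized threshold is logged and recorded on the mask. An
  optional Gaussian pre-smoothing (`smooth_sigma_px`; the scene pipeline
  uses 1 px) stops Otsu from splitting the background-noise histogram when
  foreground occupies a tiny pixel fraction (sparse markers such as Iba1 in
  low-coverage fields). A constant channel yields an empty mask plus a
  warning rather than an error.
- **Connectivity** is 8 by default; components below `min_area_um2`
  (default 4 px²) are dropped and survivors relabeled in raster-scan order.
- **Perimeter** is measured as the length of the marching-squares subpixel
  contour after periodic Gaussian smoothing (σ = 2 vertices) of the vertex
  chain. Boundary-pixel counting overestimates curved boundaries
  (staircase bias, inflating 4πA/P² errors), and few-direction Crofton
  estimators shorten axis-aligned straight edges by ~5%; the smoothed
  contour recovers a disk of radius 50 px to within 0.1% of 2πr, a 50-px
  square to within 3% of its true perimeter, and a 1×100 px bar to within
  4% of the analytic 202 px. Contours with ≤ 8 vertices (specks) are left
  unsmoothed; inner contours (holes) count toward the perimeter.
- **Circularity** `S = 4πA/P²` is clipped to [0, 1]; small rasterized disks
  can otherwise exceed 1 through perimeter underestimation.
- Areas are always pixel counts × `pixel_size_um²`; coordinates are 0-based
  with half-open frame bounds.

## Metric definitions and tie rules

- **ThioS⁺ classification** replaces the manual z-stack judgement with an
  explicit rule: a deposit is ThioS⁺ iff its in-plaque ThioS area is at
  least `min_core_area_um2` (default 5 µm²; ties count as positive). The
  per-plaque decision is logged.
- **Global compaction** sums ThioS and Aβ areas over deposits before
  dividing. Default includes all deposits; a `thios_positive` mode
  restricts both sums to cored plaques, mirroring per-deposit analyses
  that consider ThioS⁺ plaques only.
- **ThioS attribution:** ThioS pixels outside any Aβ deposit are reported
  (logged stray area), never silently dropped.
- **PAM** are nuclei whose centroid lies in the analysis frame and whose
  pixels overlap Iba1 by ≥ 1 px. The frame is the deposit bounding box
  expanded by a margin (the pipeline default 14 µm covers the microglial
  ring); density divides by the plaque area within the frame.
- **Interface coverage** takes the 8-connected outer boundary of the core
  and counts a boundary pixel as covered when any Iba1 pixel lies within
  Chebyshev distance `contact_radius_px` (default 1). Computed only for
  ThioS⁺ plaques.
- **Ki-67⁺ microglia**: an Iba1-overlapping nucleus counts when its
  Ki-67⁺ pixel fraction is ≥ 0.3 — an explicit stand-in for the manual
  "clear signal in the nucleus" call.
- **Neuritic plaque**: any deposit with in-frame LAMP1 area > 0; spheroids
  carry no shape filter beyond an optional minimum area (default 2 µm²).
  Diffuse = ThioS⁻.

## Proteomics

Normalization scales each sample by (grand mean of sample means)/(sample
mean), the simplest reading of global-mean normalization; all sample means
are equal afterwards and the operation is idempotent. (Scaling one sample
before normalizing changes the grand mean, so tables agree after
normalization only up to the common level — the invariance tests are stated
that way.) Differential abundance uses Welch's unequal-variance t on log₂
abundances; the identical-values degenerate case returns p = 1 with a note,
and proteins with missing or non-positive abundances are excluded with a
logged reason. The candidate gate is two-sided: fold change ≥ 1.5 (ratio
≥ 1.5 or ≤ 1/1.5) AND p ≤ 0.05, partitioned into increased/decreased. No
multiple-testing correction is applied by default (raw-p gating); the
Holm–Šidák routine is available to callers who want one.

The triangle projection assigns each protein barycentric weights
`w_g = m_g / Σ m_h` over the three normalized group means and places it at
`Σ w_g · vertex_g` in a unit-side equilateral triangle. A spreadsheet
line-intersection construction used informally for such plots is not
reproducible from its description; the barycentric form provably satisfies
the two properties that define the plot — equal levels map to the centroid,
and raising one group's level moves the point strictly toward that group's
vertex — and is label-permutation equivariant. Z-scores use the sample SD
(n−1); zero-variance rows are emitted as zeros with a note.

## Statistics

- D'Agostino–Pearson K² (χ², 2 df) requires n ≥ 20; smaller samples raise
  with guidance instead of returning an unreliable p.
- One-way ANOVA is computed from explicit SSB/SSW with df (k−1, N−k); the
  all-identical case is an error, and zero within-group variance with
  unequal means reports p = 0 with a note. scipy's `f_oneway` serves as the
  independent cross-check in tests.
- Holm–Šidák: sort ascending, adjusted p(i) = running max of
  `1 − (1 − p(j))^(m−j+1)`, clipped at 1, returned in input order. The
  family is the set of pairwise contrasts within one metric (e.g. the three
  genotype pairs), not all metrics pooled.
- Pairwise follow-up tests in the report are two-sided Welch t, adjusted
  within-metric; α = 0.05 throughout. Normality failures are reported, not
  auto-switched to nonparametric tests.
- Alternation index: overlapping windows of three entries, alternation =
  three distinct arms, maximum = entries − 2.
- The report carries a `unit_of_analysis` tag (default "animal"); callers
  aggregating per-plaque rows instead can set it, making the chosen unit
  explicit in the output.

## Validation studies and problem sizes

The harness in `plaquekit.validation` (reported by `scripts/acceptance.py`,
asserted in `tests/test_acceptance.py`) uses: 10 scenes × 5 plaques for
compaction recovery (C ~ U(0.1, 0.9), 10% foreground noise); 25 scenes × 4
plaques (0–8 PAM each, 64-px clearance) for PAM exactness; arc fractions
{0, ¼, ½, ¾, 1} on a 40-px core for interface recovery; 2,000 null tables
(3 × 10) for ANOVA calibration; 2,000 proteins (cv 0.2, n = 5/group) for the
proteomic null and 50 seeds × 100 proteins for power at FC = 3; and two
cohorts of 5 scenes for the directional end-to-end study (compact/high-PAM:
C ∈ [0.5, 0.8], 5–8 PAM, f ∈ [0.6, 0.9], thin DN annuli; diffuse/low-PAM:
C ∈ [0.1, 0.3], 1–3 PAM, f ∈ [0.1, 0.3], wide DN annuli). These sizes give
Monte-Carlo standard errors comfortably inside the asserted tolerances
while keeping the full harness under a minute on one CPU.

## Known limitations

- Otsu-based masks assume a bimodal intensity histogram; heavily skewed
  real-world backgrounds may need the fixed-threshold override.
- The automated analysis frame (bounding box + margin, or constant-size
  square) approximates manual per-plaque frame adjustment; frames of
  adjacent deposits can overlap in dense fields, and bystander microglia
  inside a frame are counted as PAM, as they would be manually.
- Overlapping halos merge into one deposit under connected-component
  labeling (documented behavior), so deposit counts depend on plaque
  density.
- The interface metric measures mask proximity, not cell identity: any
  Iba1 signal near the core boundary counts, whether or not it belongs to
  a plaque-associated cell.
- Proteomic comparisons assume log-normal-ish abundances; missing values
  are excluded per comparison, not imputed.
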
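# Methods

This note documents the models, algorithms and parameter choices behind
`granuvisc`, and what the synthetic benchmark does and does not demonstrate.

## Scientific setting

Mucin is stored in secretory granules of airway epithelial cells as a
condensed polymer matrix. A viscosity-sensitive fluorophore (a BODIPY-class
molecular rotor) that accumulates in granules reports the microviscosity of
that matrix through its fluorescence lifetime: intramolecular rotation is a
non-radiative decay channel whose rate drops in viscous media, so lifetime
grows with viscosity. FLIM (fluorescence lifetime imaging microscopy) with
TCSPC detection yields a per-pixel photon arrival-time histogram; fitting
these histograms, converting lifetimes to viscosities through a calibration,
segmenting granules and analysing the per-granule viscosity distribution
distinguishes healthy (non-CF) cells — one granule population near 521 cP —
from cystic-fibrosis cells — a dominant low-viscosity population near 164 cP
plus a minority population near 501 cP.

No raw imaging data are available for that experiment, so this package pairs
the analysis pipeline with a ground-truthed simulator whose population
parameters are set to the reported values. The benchmark is parameter
*recovery*: the pipeline must re-derive the generating populations from
photon-limited synthetic images.

## Synthetic data (`flim_synth`)

A scene phantom places circular granules in a frame; each granule carries one
true viscosity. Presets:

| preset | populations (mean cP, sd cP, weight) |
|---|---|
| `nonCF` | (521, 60, 1.0) |
| `CF` | (164, 40, 0.7), (501, 60, 0.3) |
| `nonrotor_control` | viscosities as `nonCF`, lifetime fixed at 3.5 ns |

The component means are the reported population centres; the sds and the
0.7/0.3 weights are package choices consistent with a clearly dominant
low-viscosity population (only "larger"/"smaller" is reported). Component
shapes are normal.

Geometry and acquisition defaults (all configurable):

- **Frame** 128×128 px, **50 granules per image**, **12 images per group** —
  matching the reported 10–12 analysed images per set and giving ≥ 500
  accepted granules per group.
- **Radii**: lognormal, median 4 px, σ_log = 0.3, clipped to [3, 10] px,
  shared by all presets (the size distributions of the two groups are
  reported similar). The 3 px floor keeps rasterised disks well above the
  circularity threshold. Disks are placed largest-first (robust packing) with
  ≥ 2 px clearance between independent granules; in crowded frames a disk may
  be shrunk by up to three 20% steps to find a slot.
- **Clusters**: with probability 0.25 a granule is placed *near-tangent*
  (1.2–1.6 px boundary gap) to an existing granule and shares its
  `cluster_id`. The small gap — rather than true tangency — keeps cluster
  members resolvable as separate 4-connected components, so the
  clustered-vs-individual comparison can run on accepted granules. Viscosity
  is assigned independently of cluster membership. Note that with p = 0.25 of
  *placements* being companions, the fraction of granules *in clusters* is
  ≈ 0.4–0.45 (companion + host both count).
- **Optics**: 256 bins × 0.1953125 ns = 50 ns window (20 MHz repetition),
  Gaussian IRF of 0.2 ns FWHM centred 1 ns into the window. Only the
  repetition rate is taken from the experiment; the rest are typical
  confocal-TCSPC values.
- **Photon budget**: 500 photons per granule pixel in expectation; background
  pixels receive 5% of that at a 40 cP background viscosity. These are
  desk-scale defaults chosen so per-pixel fits are informative (SD(τ̂) ≈ 0.2 ns
  at 4.6 ns) while a full 2×12-image study runs in minutes on one CPU.

Rendering: each pixel's arrival-time density is a single exponential at the
pixel's true lifetime convolved with the Gaussian IRF (an exponentially
modified Gaussian), integrated over bins via its closed-form CDF, normalised
over the window, and sampled with independent Poisson counts per bin.
Within-granule viscosity is homogeneous; heterogeneity enters only through
photon noise. Detector afterpulsing, dead time, pile-up, scanner distortion
and 3D structure are not modelled.

## Decay fitting (`decay_fit`)

The model is a sum of M exponential decays, I(t) = Σᵢ Aᵢ exp(−t/τᵢ),
optionally convolved with the Gaussian IRF, and always *bin-integrated* —
the fitter compares expected counts per bin, not point samples. Fitting uses
variable projection: for candidate lifetimes the amplitudes are the
nonnegative weighted-least-squares solution (closed form for M = 1, NNLS
otherwise), and only the lifetimes are optimised — a fixed logarithmic grid
(0.3–8 ns) supplies deterministic multi-starts, refined by bounded scalar
minimisation (M = 1) or Nelder-Mead (M ≥ 2). There is no randomness anywhere
in the fitter.

**Weighting.** Weights are model-based (Pearson): a first pass with
1/max(counts, 1) weights yields a provisional model, and the final pass
weights each bin by 1/max(model, 0.5). Purely data-based (Neyman) weights
were evaluated and rejected: at the photon budgets of pixel histograms they
overweight downward-fluctuating bins, biasing τ̂ low by >10% (4.09 ns fitted
for a 4.6 ns truth at 500 photons) and deflating the goodness-of-fit
statistic to ≈ 0.5. With model-based weights τ̂ is unbiased at these budgets.

**Goodness of fit.** χ²_red is the Pearson statistic over bins whose fitted
model predicts ≥ 1 expected count, divided by (bins − 2M). Its per-bin
expectation is exactly 1 for Poisson data at any count level; restricting to
informative bins avoids dilution by the empty tail of the 50 ns window.
Component selection takes the smallest M with χ²_red ≤ 1.2 (band around the
χ² ≈ 1 criterion), up to max_M = 2 by default (a bound + free dye can need
two components); if nothing qualifies the max_M fit is returned flagged.

**Lifetime images.** Pixels with ≥ 100 total counts (pooled, if spatial
binning is enabled) are fitted; others are NaN. The per-pixel summary uses
*intensity* (photon) weighting, Σ Aᵢτᵢ²/Σ Aᵢτᵢ: when selection occasionally
escalates to M = 2 on truly single-exponential pixels (≈ 10–15% by chance at
the 1.2 threshold), the spurious component carries amplitude but few photons,
so the photon-weighted mean stays unbiased where the amplitude-weighted mean
(Σ Aᵢτᵢ/Σ Aᵢ, the default of `mean_lifetime` itself) is dragged low.

## Calibration (`rotor_calibration`)

The lifetime-viscosity relation is the Förster-Hoffmann power law
τ = a·η^x, fitted as an OLS line in log-log space and restricted to
η ≥ 20 cP — below that the rotor's response flattens, and the domain
restriction is treated as the "modification" of the classical law. Points
below the domain are excluded from fits (and counted); conversions landing
outside [20, 1500] cP are clipped and flagged, and flagged granules are
excluded from population analysis.

Simulator default constants a = 0.4545 ns·cP⁻ˣ, x = 0.37 place the preset
viscosities inside the 2.5–5.0 ns lifetime range observed for the rotor in
cells (164 cP → 3.0 ns, 521 cP → 4.6 ns). They are declared package
defaults, not instrument-fitted values; the experiment's own constants are
not published in reusable form.

Glycerol-water standards use the Segur & Oberstar (1951) viscosity table
(20 and 30 °C columns, glycerol weight percent in 10% steps), with volume →
weight fraction conversion by component densities and log-linear
interpolation in composition and temperature (15–30 °C supported).

Quantum yields use the relative method against fluorescein in 0.1 M NaOH
(Q_ref = 0.95): Q = Q_ref·(n²/n_ref²)·(I/I_ref)·(1−10^(−A_ref))/(1−10^(−A)).
The absorptance factors are implemented with negative exponents — the
physically meaningful fraction of absorbed light — since positive exponents
would make the factor negative for any A > 0.

## Segmentation (`granule_segmentation`)

A desk-scale stand-in for the interactive Weka-style workflow: a fixed
feature stack (raw intensity, Gaussian blurs at σ = 1, 2, 4, 8 px, Sobel
gradient magnitude, Laplacian, 5-px local variance) feeds a random forest
(100 trees, fixed seed) trained on sparse granule/background labels — in the
pipeline these labels are sampled from the first image's ground truth, the
synthetic analogue of manual scribbles. Requirements: ≥ 50 labelled pixels
per class; a stratified 25% holdout reports pixel accuracy (≈ 1.0 on default
phantoms).

The predicted foreground is hole-filled and split into 4-connected
components. Components are rejected below 9 px² area or below 0.8
circularity (4πA/P²). Perimeter is skimage's weighted line-segment estimator
(`regionprops.perimeter`), which keeps ideal disks of radius 3–20 px at
circularity 0.91–0.99, while merged tangent pairs measure ≈ 0.5 and 1-px
lines ≈ 0.48 — both safely rejected. The Crofton estimator was considered
and set aside (0.83 for a radius-3 disk, uncomfortably close to the 0.8
threshold). Circularity can slightly exceed 1 for very small rasterised
shapes; the radius floor in the generator keeps accepted disks below ≈ 1.0.

Accepted components whose 1-px dilations intersect (Chebyshev gap ≤ 2 px)
are marked clustered and share a cluster id; rejected non-circular blobs
larger than twice the median accepted area are flagged as aggregate
candidates. Segmentation always operates on the intensity image; lifetime
enters only through per-granule summaries.

## Population analysis (`population_analysis`)

Each granule with ≥ 5 defined lifetime pixels is summarised by the mean of
its pixel lifetimes converted once through the calibration
("viscosity_of_mean", the default — the monotone transform of the granule's
aggregate decay, with fewer clipping artifacts); "mean_of_pixels" (per-pixel
conversion, then average) is retained for sensitivity analysis.

Pooled per-granule viscosities are modelled as a k-component univariate
Gaussian mixture (Gaussian on the cP scale, matching the symmetric fitted
curves of the original analysis). k = 1 is closed-form maximum likelihood
(exactly the sample mean and MLE sd); k ≥ 2 uses EM with 10 deterministic
seeded restarts. k is selected by BIC = −2 log L + (3k−1) ln n over
k = 1..3, ties toward fewer components. Standard errors of component means
come from the outer-product-of-scores estimate of the observed information
over the full parameter vector (exactly sd/√n at k = 1), with a flagged
200-replicate bootstrap fallback if that matrix is singular. Reported
"mean ± SE" mirrors the fitted-mean-uncertainty reading of the published
"521 ± 28 cP" notation; component sds are reported alongside. Group
comparisons (CF vs non-CF, clustered vs individual) report per-group
selected-k fits, nearest-mean-matched component differences with combined
SEs, and a two-sample Kolmogorov-Smirnov distance — descriptive only, no
p-values. Degenerate inputs (zero spread) return a flagged single component
with an sd floor.

## Pipeline and provenance (`pipeline_io`)

`run_pipeline` chains simulate → train classifier → fit lifetimes → segment
→ map viscosities → mixture analysis, with every stage's timing and warning
counters (sub-threshold pixels, rejected granules, excluded granules)
recorded in a run manifest, and a config hash plus seeds in the report. All
randomness derives from the single config seed, so two runs of one config
produce byte-identical reports. Coordinates are (row, col), 0-based. Stacks
are OME-TIFF (T axis = time bins) with a JSON sidecar; lifetime images are
3-plane float32 TIFFs; granule tables are CSV; reports are versioned JSON.
The `granuvisc` CLI (simulate / fit / calibrate / segment / analyze /
run-all) is a thin wrapper over these functions, as are the numbered scripts
under `analysis/`.

## Problem sizes and determinism

The default study — 2 groups × 12 images × 128×128 px × 256 bins, ≈ 2800
granule pixels fitted per image — runs in roughly 4–6 minutes per group on
one CPU; the per-pixel fit costs ~8 ms. Simulations in the test suite use
smaller frames (24–192 px) and fewer granules, sized to keep each check
informative at conventional statistical tolerances. Fitting is fully
deterministic; simulation and EM restarts are seeded. Floating-point
reductions follow NumPy's summation order, so integer artifacts are
bit-identical across runs and real-valued outputs are identical on a given
platform.

## What passing tests show — and what they do not

The benchmark demonstrates that the pipeline recovers granule-viscosity
populations from photon-limited TCSPC images under the stated noise model,
with correctly calibrated goodness of fit and unbiased lifetime estimation.
It does not validate: the rotor's chemical specificity or calibration
transfer to cells (the lifetime-responds-only-to-viscosity assumption is
documented, not tested); segmentation against real cellular clutter
(out-of-focus light, autofluorescence, irregular granule shapes); sub-granule
viscosity structure; or any instrument effect excluded from the noise model.
Real-data deviations from the single-exponential-per-pixel assumption would
surface as flagged fits and inflated χ²_red rather than silent bias.

## Known limitations

- The CF mixture weights (0.7/0.3) and component sds are package choices;
  only the component means are anchored to reported values.
- Granule placement shrinks radii slightly in crowded frames, so the
  realised radius distribution is marginally lighter-tailed than specified.
- The observed-information SEs are asymptotic; at n < ~100 granules per
  component they can be optimistic (the bootstrap fallback is available).
- No global (image-wide shared-lifetime) fitting, phasor analysis, measured
  IRF deconvolution, hierarchical replicate modelling, or vendor file formats
  (PT3/PTU).
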
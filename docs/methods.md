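# Methods

`cartopo` quantifies early osteoarthritic (OA) change of articular-cartilage
surfaces from confocal-style height maps, quantifies stained histological
sections, and compares experimental groups with rank statistics. This note
records the models, conventions, numerical choices and limitations.

## Surface model and wavelength estimator

A cartilage surface is a height map z(x, y) on a uniform grid (default
512×512 points, 1 µm lateral step; x is the medio-lateral, y the
antero-posterior axis). Local height variation is treated as a wave field.
The gradient (∂z/∂x, ∂z/∂y) is computed with central differences in the
interior and one-sided stencils at the borders; border samples of every scan
line are excluded from peak detection so one-sided-stencil artefacts never
seed a maximum.

The average wavelength per axis comes from the distances between successive
maxima of the **signed** derivative, scanned along every row (λx, on ∂z/∂x)
or column (λy, on ∂z/∂y):

* signed — maxima of |∇z| occur twice per period on a sinusoid and would
  halve every wavelength; signed maxima occur once per period, so the
  estimator equals the physical period on a pure sinusoid (verified to
  machine precision across the 8–28 µm operating band);
* maxima are strict local maxima; plateaus contribute their midpoint
  (rounded down);
* the normalisation is the mean over scan lines of the per-line mean
  spacing. Lines with fewer than two maxima contribute nothing; an axis with
  no spacings at all raises a typed `UndefinedWavelengthError` rather than
  returning a sentinel;
* an optional minimum-prominence floor suppresses roughness ripples. The
  faithful estimator (prominence 0) is the default of the low-level
  functions; the pipeline uses `"auto"` = 0.8 × the SD of the derivative
  grid, which sits between the prominence of roughness-level ripples and
  that of the dominant texture. On the default synthetic conditions (5%
  roughness) this leaves the recovered deformation ratio unbiased to
  ±0.01; prominence 0 underestimates wavelengths whenever noise plants
  spurious maxima near flat derivative crests.

## Deformation ratio

For an OA surface and its healthy contralateral reference,
ε_axis = (λ̄_axis^OA − λ̄_axis^Healthy) / λ̄_axis^Healthy. Negative values
indicate compression of the surface texture, positive values extension.
ε and the cohesion index below are reported as fractions (0.417, not
41.7%); the pipeline's `render_percent` option rescales the CSV output.

## Angular-sector decomposition and cohesion index

The 2D FFT of the surface is partitioned by the polar angle of each
frequency bin into a 0–90° and a 90–180° sector over the non-redundant
half-plane. Every bin is mapped to its conjugate representative
(ν_y > 0, or ν_y = 0 with ν_x ≥ 0) before the angle test, so conjugate
pairs land in the same sector and both inverse transforms are real.
Boundary convention: θ = 0° → first sector, θ = 90° → second; the DC bin
belongs to neither, making both reconstructions zero-mean and
s1 + s2 + mean(z) an exact partition (conservation holds to ~1e−16 of the
height range). Nyquist rows/columns follow the same angle rule.

Each sector reconstruction is sent through the same gradient → maxima →
mean-spacing estimator (the wavelengths measured are those of the gradient
of each direction-filtered morphology). A sector whose RMS is below 1e−9 of
the parent RMS carries no physical texture and raises
`UndefinedWavelengthError` instead of measuring numerical noise.

The cohesion index per axis is
I = |λ̄^{0⇒90} − λ̄^{90⇒180}| / λ_min, with λ_min the smaller of the two
sector means. The denominator is not pinned down by the defining prose;
the minimum keeps I dimensionless, ≥ 0, zero at perfect balance and
symmetric under relabelling the sectors, and it is carried in the result
object for audit. A cohesive, isotropic surface scores near zero; loss of
biaxial tension balance raises I.

## Synthetic surfaces

`generate_surface` sums a bank of 5 sinusoids per axis — one dominant
component at the base wavelength, four satellites at 20% amplitude with
wavelengths drawn at 3% fractional SD around it (clipped above Nyquist),
random phases — plus white Gaussian roughness. Defaults: 512×512 @ 1 µm,
base wavelengths 12 µm (x) and 15 µm (y) inside the documented 8–28 µm
band, amplitude 1 µm, roughness SD 0.05 µm. The roughness amplitude of real
cartilage is undocumented; the 1 µm amplitude and 5% roughness are the
package's own choice of a realistic microscale regime and are explicit
configuration.

`generate_pair` re-evaluates the same bank with every wavelength multiplied
by a stretch factor (equivalent to stretching the coordinate grid) and
reuses the healthy member's roughness realization, emulating contralateral
pairing: ε ground truth is exactly (stretch − 1) per axis, and with
stretch = 1 the pair is bit-identical. Sector imbalance multiplies the OA
member's Fourier coefficients in the [135°, 180°) angular half-quadrant by
(1 + imbalance). That half-quadrant is rich in high-|ν_x| content, so the
gain shortens the 90–180° sector's x-wavelength and raises I_x strictly
monotonically with the imbalance (checked per-seed in the tests); it was
chosen over [90°, 135°) whose amplification moves I_x the opposite way.

What the generator does **not** emulate: collagen fibril mechanics, confocal
optics (speckle, chromatic aberration), curvature of the joint surface, or
spatially structured (non-white) roughness. Passing tests demonstrate that
the estimators recover planted spectral structure, not that real cartilage
behaves like the model.

## Synthetic slides and histology quantification

`generate_slide` paints a centred rectangular "cartilage" region on a
near-black background (emulating black-background polarized acquisition),
plants raster-contiguous red/yellow/green blocks of exactly
round(fraction × mask area) pixels, and places non-overlapping flat dark
discs as cells in the uncoloured remainder (dart throwing; an infeasible
packing raises `PackingError` rather than silently truncating). Planted
fractions and counts are exact by construction.

Quantification mirrors the imaging workflow: segmentation on the white-light
image (Otsu threshold → largest connected component → hole filling, with a
user-mask bypass, since the real step is semi-automatic), AND-masking of the
polarized image, hue-band area fractions with defaults red [0°,20°)∪[340°,360°),
yellow [20°,70°), green [70°,160°) and a brightness floor of 0.15 so the
black background never counts as a colour. The colour thresholds of the
original workflow are not documented; these bands are configuration, not a
claim of equivalence. Cell counting offers the typed manual-count path
(operators averaged, then divided by cartilage area) and an automated
stand-in (Otsu within the mask, connected components, area gate 25–400% of
the expected cell area). Mankin-modified totals (0–14) from multiple
operators are validated and aggregated as mean and sample SD. Profile-line
intensity uses unit-spaced Bresenham sampling on the luminance image, no
sub-pixel interpolation, and is modality-agnostic.

## Statistics

All comparisons are rank-based: tie-corrected Kruskal–Wallis H with the
chi-square approximation (df = k − 1), and Dunn pairwise z-tests on the
pooled ranks with tie correction and Bonferroni adjustment (two-sided;
sidedness and α = 0.05 are configuration). The chi-square approximation is
deliberate: at complete separation of two tie-free groups of 3 it gives
p = 0.0495, the floor attainable at that sample size, which is the regime
this study design operates in; an exact-permutation alternative is
available. Degenerate data (all values identical) raises
`DegenerateDataError` — H is undefined under tie correction.

The pipeline's default analysis plan runs **planned two-group contrasts**
(deformation ratio between induction models; cohesion indices OA vs own
healthy control and OA vs OA; Mankin healthy vs each model and model vs
model) rather than one 4-group omnibus with corrected post-hoc tests: at
n = 3 per group a Bonferroni-corrected Dunn test cannot resolve a
single-group shift, while the two-group rank test reaches its 0.0495 floor
exactly when a planted effect produces complete separation. The omnibus +
Dunn machinery is exposed in the API for larger designs.

## Default synthetic study

Two induction models × 3 analyzable surface pairs (four topology groups of
3, mirroring the study's usable sample count), three histology groups of 4
slides. Planted effects: MIA stretch (1.353, 1.417) and MMT stretch
(1.213, 1.205) — magnitudes chosen to mirror the reported group-mean
deformation ratios — MMT-OA sector imbalance 0.6 (a clearly detectable
anisotropy level), and a fixed Mankin table in which both OA models separate
completely from healthy while overlapping each other (one MIA knee carries
the worst defect, total 8). Slide colour/cell statistics are identical
across groups, so cellularity and birefringence are summarised descriptively
without planted contrasts. The simulate stage records every planted contrast
in `simulate_truth.json`; the report audits flags against that list.

## Numerical and reproducibility choices

* All randomness flows from one integer seed per spec/run; sample seeds are
  drawn from the run seed through `numpy`'s Generator; reruns are
  bit-identical and the end-to-end CSVs byte-identical (fixed 6-significant-
  digit formatting).
* Central differences attenuate a sinusoid's derivative by sinc(2πh/λ)
  (≈ 2.6% at λ = 16 µm, h = 1 µm); maxima positions, and hence wavelengths,
  are unaffected.
* Surfaces are not detrended by default (an optional plane-removal flag
  exists); whether real acquisitions were levelled is unknown.
* Per-sample analysis failures are logged and skipped; a stage with partial
  failures exits with a distinct status and the report lists the skipped
  samples with reasons.

## Problem sizes used by tests and the acceptance script

Surface oracles use 512×512 grids (the documented acquisition size);
sector-conservation and isotropy properties use 128×128 grids, 10–20 seeds;
deformation-ratio and cohesion-monotonicity checks use 10 seeded pairs;
the null-calibration of the omnibus test uses 1000 simulations; cellularity
recovery uses 3 planted densities × 5 seeds on 400×400 px slides. These
sizes were chosen so every property is measured on the same scale as the
documented acquisition while each check completes in seconds.

## Known limitations

* The wavelength estimator is discretised to the sampling step; at 1 µm step
  and λ ≤ 28 µm the quantisation error is well under one step on average but
  individual noisy pairs can deviate by a few percent.
* The cohesion index of the synthetic surfaces has a non-zero baseline
  (axis-aligned sinusoid banks put their energy in one sector each, the
  isotropic roughness carries the rest), so absolute I values are not
  comparable with real-tissue values; only contrasts are meaningful.
* The automated cell detector assumes dark, well-separated, roughly
  disc-shaped cells; it stands in for manual counting and is swappable.
* Mankin scoring itself is not automated — the package captures and
  aggregates operator scores only.
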
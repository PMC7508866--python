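# cartopo

Microscale surface topology and quantitative histology of early-osteoarthritic
articular cartilage.

Early osteoarthritis (OA) is hard to quantify: histology distinguishes
induction models qualitatively, but cellularity and collagen birefringence
often show no significant group differences at 3–4 samples per group. This
package implements a surface-metrology approach that extracts two
quantitative markers from confocal-style height maps of the cartilage
surface, alongside the classical histological quantities and the
nonparametric statistics used to compare experimental groups (e.g. surgical
MMT vs chemical MIA OA induction in the rat knee, each against its healthy
contralateral control). Because no real acquisitions are distributed, a
first-class synthetic-data module generates surfaces and stained-slice
images with exact ground truth, so the whole pipeline is testable end to
end.

## The two surface markers

For a height map z(x, y) (512×512 points, 1 µm step; x medio-lateral,
y antero-posterior), the average wavelengths λx, λy are the mean distances
between successive maxima of the signed derivative ∂z/∂x along rows (resp.
∂z/∂y along columns).

**Deformation ratio** — OA surface vs healthy contralateral reference:

    ε_axis = (λ̄_axis^OA − λ̄_axis^Healthy) / λ̄_axis^Healthy

negative ε = compression of the surface texture, positive = extension.

**Cohesion index** — the 2D spectrum is split by polar angle into 0–90° and
90–180° sectors, each inverse-transformed and re-measured:

    I_axis = | λ̄_axis^{0⇒90°} − λ̄_axis^{90⇒180°} | / λ_axis,min

I ≈ 0 for a cohesive, isotropic collagen network; anisotropic tension
raises it.

Histology quantification covers cartilage segmentation + AND-masking,
red/yellow/green birefringence area fractions, cellularity (cells/mm²),
Mankin-modified score aggregation (0–14, multi-operator mean ± SD) and
profile-line intensity. Group comparison uses tie-corrected Kruskal–Wallis
with Dunn/Bonferroni post-hoc tests at α = 0.05.

## Worked example

```python
from cartopo import (SurfaceSpec, PairSpec, generate_pair, surface_wavelengths,
                     deformation_ratio, sector_wavelengths, cohesion_index)

spec = SurfaceSpec(base_wavelength_x=12.0, base_wavelength_y=15.0,
                   noise_sd=0.05, seed=42)
pair = generate_pair(PairSpec(healthy=spec, stretch_y=1.417, sector_imbalance=0.6))

wl_h = surface_wavelengths(pair.healthy, "auto")
wl_o = surface_wavelengths(pair.oa, "auto")
eps = deformation_ratio(wl_o, wl_h)
I_h = cohesion_index(sector_wavelengths(pair.healthy, "auto"))
I_o = cohesion_index(sector_wavelengths(pair.oa, "auto"))

print(f"healthy: lambda_x = {wl_h.lambda_x:.2f} um, lambda_y = {wl_h.lambda_y:.2f} um")
print(f"OA:      lambda_x = {wl_o.lambda_x:.2f} um, lambda_y = {wl_o.lambda_y:.2f} um")
print(f"deformation ratio: eps_x = {eps.eps_x:.3f}, eps_y = {eps.eps_y:.3f}")
print(f"cohesion index:    healthy I_x = {I_h.I_x:.3f}, OA I_x = {I_o.I_x:.3f}")
```

prints

```
healthy: lambda_x = 11.99 um, lambda_y = 14.99 um
OA:      lambda_x = 11.99 um, lambda_y = 21.20 um
deformation ratio: eps_x = 0.000, eps_y = 0.414
cohesion index:    healthy I_x = 1.705, OA I_x = 1.830
```

The planted antero-posterior stretch of 1.417 is recovered as ε_y ≈ 0.414
(ground truth 0.417) while the unstretched medio-lateral axis stays at 0;
the planted spectral-sector imbalance raises the OA member's cohesion index
above its healthy twin's.

The same study runs end to end from the command line:

```sh
cartopo run --out study --seed 1
```

which simulates 2 induction models × 3 surface pairs plus 3 histology
groups of 4 slides, analyzes them, and writes `study/report.md` with
"mean (SD)" tables per variable (e.g. for seed 1: ε_x MIA 0.334 (0.041) vs
MMT 0.210 (0.005)), the planned Kruskal–Wallis contrasts with significance
flags, and an audit that the flagged contrasts are exactly the ones the
generator planted. Stages can also be run separately
(`simulate`, `topology`, `histology`, `stats`, `report`); reruns from the
same seed are byte-identical.

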
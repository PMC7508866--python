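"""Synthetic data with known ground truth.

Three generators feed the downstream stages:

* ``generate_surface`` — a confocal-style height map built from a small bank
  of sinusoids per axis (one dominant component at the requested base
  wavelength plus weaker satellites drawn tightly around it, random phases)
  with additive white Gaussian roughness. The dominant inter-maxima spacing
  of the signed derivative equals the base wavelength, so the wavelength
  estimator has an analytic oracle.

* ``generate_pair`` — a healthy surface and an osteoarthritic twin derived
  from the *same* sinusoid bank with every wavelength multiplied by a stretch
  factor (a coordinate-grid stretch), sharing the healthy member's roughness
  realization. The deformation ratio therefore has an exact ground truth of
  (stretch − 1) per axis. An optional sector imbalance amplifies the Fourier
  coefficients of the OA member in the [135°, 180°) angular half-quadrant by
  (1 + imbalance), which monotonically unbalances the two spectral sectors
  and raises the cohesion index.

* ``generate_slide`` — a stained-slice image with a rectangular cartilage
  region on a dark background, planted red/yellow/green pixel areas of exact
  known fractions, and non-overlapping disc "cells", so colour fractions,
  counts and cellularity are all recoverable by construction.

All randomness flows from the integer seed of each spec; no global state.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import NyquistError, PackingError, ValidationError
from .heightmap import HeightMap

__all__ = [
    "SurfaceSpec",
    "PairSpec",
    "SlideSpec",
    "PairResult",
    "SlideResult",
    "generate_surface",
    "generate_pair",
    "generate_slide",
    "apply_sector_gain",
]

# Flat colours used on synthetic slides (R, G, B). Hues: red ≈ 0°,
# yellow ≈ 53°, green ≈ 120°, tissue ≈ 266° (outside every band),
# cells ≈ 240° but dark; background is near-black.
SLIDE_COLORS = {
    "background": (15, 15, 15),
    "tissue": (170, 140, 210),
    "red": (200, 40, 40),
    "yellow": (210, 190, 40),
    "green": (60, 180, 60),
    "cell": (30, 30, 90),
}


@dataclass(frozen=True)
class SurfaceSpec:
    """Parameters of one synthetic height map.

    Defaults emulate the study conditions: 512×512 points at 1 µm step with
    dominant wavelengths inside the 8–28 µm band. ``amplitude`` (µm) is a
    free parameter of the generator (real cartilage roughness amplitude is
    not documented); 1 µm is used as a realistic microscale default.
    ``phase_jitter`` scales the random phases in [0, 1]; ``noise_sd`` is the
    white-roughness SD in µm.
    """

    n_rows: int = 512
    n_cols: int = 512
    step: float = 1.0
    base_wavelength_x: float = 12.0
    base_wavelength_y: float = 15.0
    amplitude: float = 1.0
    phase_jitter: float = 1.0
    noise_sd: float = 0.05
    n_components: int = 5
    wavelength_spread: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.n_rows < 16 or self.n_cols < 16:
            raise ValidationError("surface must be at least 16x16 points")
        if not (self.step > 0):
            raise ValidationError("step must be > 0")
        for lam in (self.base_wavelength_x, self.base_wavelength_y):
            if lam < 2 * self.step:
                raise NyquistError(
                    f"wavelength {lam} µm below Nyquist limit 2·step = {2 * self.step} µm"
                )
        if not (self.amplitude > 0):
            raise ValidationError("amplitude must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not (0 <= self.phase_jitter <= 1):
            raise ValidationError("phase_jitter must lie in [0, 1]")
        if self.n_components < 1:
            raise ValidationError("need at least one sinusoid per axis")


@dataclass(frozen=True)
class PairSpec:
    """A healthy surface and the stretch/imbalance transform of its OA twin."""

    healthy: SurfaceSpec = field(default_factory=SurfaceSpec)
    stretch_x: float = 1.0
    stretch_y: float = 1.0
    sector_imbalance: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.stretch_x <= 0 or self.stretch_y <= 0:
            raise ValidationError("stretch factors must be > 0")
        if not (0 <= self.sector_imbalance <= 1):
            raise ValidationError("sector_imbalance must lie in [0, 1]")


@dataclass(frozen=True)
class SlideSpec:
    """Parameters of one synthetic stained-slice image."""

    width: int = 400
    height: int = 400
    pixel_size: float = 1.0
    n_cells: int = 60
    cell_radius: float = 5.0
    mask_fraction: float = 0.5
    color_fractions: tuple[float, float, float] = (0.2, 0.3, 0.3)
    background_intensity: int = 15
    seed: int = 0

    def __post_init__(self):
        if self.width < 16 or self.height < 16:
            raise ValidationError("slide must be at least 16x16 px")
        if not (self.pixel_size > 0):
            raise ValidationError("pixel_size must be > 0")
        if self.n_cells < 0:
            raise ValidationError("n_cells must be >= 0")
        if not (0 < self.mask_fraction <= 1):
            raise ValidationError("mask_fraction must lie in (0, 1]")
        if any(not (0 <= f <= 1) for f in self.color_fractions):
            raise ValidationError("color fractions must lie in [0, 1]")
        if sum(self.color_fractions) > 1:
            raise ValidationError("color fractions must sum to <= 1")
        if not (self.cell_radius > 0):
            raise ValidationError("cell_radius must be > 0")


@dataclass
class PairResult:
    healthy: HeightMap
    oa: HeightMap
    truth: dict


@dataclass
class SlideResult:
    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray  # (H, W) bool
    truth: dict


def _draw_bank(spec: SurfaceSpec, rng: np.random.Generator):
    """Component wavelengths, amplitudes and phases for both axes.

    Component 0 is the dominant sinusoid at the base wavelength with the full
    amplitude; satellites carry 20% of it and wavelengths drawn from a
    Gaussian of fractional SD ``wavelength_spread``, clipped above Nyquist.
    """
    bank = {}
    for axis, base in (("x", spec.base_wavelength_x), ("y", spec.base_wavelength_y)):
        lam = np.empty(spec.n_components)
        lam[0] = base
        lam[1:] = base * (1.0 + spec.wavelength_spread * rng.standard_normal(spec.n_components - 1))
        lam = np.clip(lam, 2.0 * spec.step, None)
        amp = np.full(spec.n_components, 0.2 * spec.amplitude)
        amp[0] = spec.amplitude
        phase = spec.phase_jitter * rng.uniform(0.0, 2.0 * np.pi, spec.n_components)
        bank[axis] = (lam, amp, phase)
    return bank


def _eval_bank(bank, spec: SurfaceSpec, stretch_x: float = 1.0, stretch_y: float = 1.0):
    """Evaluate the sinusoid bank; a stretch multiplies every wavelength."""
    x = np.arange(spec.n_cols) * spec.step
    y = np.arange(spec.n_rows) * spec.step
    lam_x, amp_x, ph_x = bank["x"]
    lam_y, amp_y, ph_y = bank["y"]
    if np.any(lam_x * stretch_x < 2 * spec.step) or np.any(lam_y * stretch_y < 2 * spec.step):
        raise NyquistError("stretched wavelength falls below the Nyquist limit")
    zx = (amp_x[:, None] * np.sin(2 * np.pi * x[None, :] / (lam_x[:, None] * stretch_x)
                                  + ph_x[:, None])).sum(axis=0)
    zy = (amp_y[:, None] * np.sin(2 * np.pi * y[None, :] / (lam_y[:, None] * stretch_y)
                                  + ph_y[:, None])).sum(axis=0)
    return zy[:, None] + zx[None, :]


def generate_surface(spec: SurfaceSpec) -> HeightMap:
    """One synthetic height map; bit-identical for identical specs."""
    rng = np.random.default_rng(spec.seed)
    bank = _draw_bank(spec, rng)
    z = _eval_bank(bank, spec)
    if spec.noise_sd > 0:
        z = z + rng.normal(0.0, spec.noise_sd, size=z.shape)
    return HeightMap(z, step=spec.step)


def _sector_gain_mask(shape, theta_lo: float, theta_hi: float) -> np.ndarray:
    n_rows, n_cols = shape
    fy = np.fft.fftfreq(n_rows)[:, None]
    fx = np.fft.fftfreq(n_cols)[None, :]
    flip = (fy < 0) | ((fy == 0) & (fx < 0))
    rx = np.where(flip, -fx, fx)
    ry = np.where(flip, -fy, fy)
    theta = np.degrees(np.arctan2(ry, rx))
    dc = (fx == 0) & (fy == 0)
    return (theta >= theta_lo) & (theta < theta_hi) & ~dc


def apply_sector_gain(
    hm: HeightMap, gain: float, theta_lo: float = 135.0, theta_hi: float = 180.0
) -> HeightMap:
    """Multiply the Fourier coefficients of one angular band by ``gain``.

    The band is specified by the representative polar angle of each conjugate
    pair, so the filtered surface stays real. The default half-quadrant
    [135°, 180°) sits inside the 90–180° sector and is rich in high-|νx|
    content: amplifying it shortens that sector's x-wavelength and thereby
    raises the cohesion index I_x monotonically with the gain.
    """
    F = np.fft.fft2(hm.heights)
    band = _sector_gain_mask(hm.heights.shape, theta_lo, theta_hi)
    F = np.where(band, F * gain, F)
    return HeightMap(np.fft.ifft2(F).real, step=hm.step, axis_convention=hm.axis_convention)


def generate_pair(pair: PairSpec) -> PairResult:
    """Healthy/OA surface pair with exact stretch and imbalance ground truth.

    The OA member re-evaluates the healthy member's sinusoid bank with every
    wavelength multiplied by the stretch factor and reuses the same roughness
    realization (contralateral pairing), so with stretch = 1 and imbalance = 0
    the two members are bit-identical.
    """
    spec = pair.healthy
    if pair.seed is not None:
        spec = dataclasses.replace(spec, seed=pair.seed)

    rng_h = np.random.default_rng(spec.seed)
    bank = _draw_bank(spec, rng_h)
    noise = (
        rng_h.normal(0.0, spec.noise_sd, size=(spec.n_rows, spec.n_cols))
        if spec.noise_sd > 0
        else 0.0
    )
    healthy = HeightMap(_eval_bank(bank, spec) + noise, step=spec.step)
    oa = HeightMap(
        _eval_bank(bank, spec, pair.stretch_x, pair.stretch_y) + noise, step=spec.step
    )
    if pair.sector_imbalance > 0:
        oa = apply_sector_gain(oa, 1.0 + pair.sector_imbalance)
    truth = {
        "stretch_x": pair.stretch_x,
        "stretch_y": pair.stretch_y,
        "eps_x_true": pair.stretch_x - 1.0,
        "eps_y_true": pair.stretch_y - 1.0,
        "sector_imbalance": pair.sector_imbalance,
        "base_wavelength_x": spec.base_wavelength_x,
        "base_wavelength_y": spec.base_wavelength_y,
        "seed": spec.seed,
    }
    return PairResult(healthy=healthy, oa=oa, truth=truth)


def _place_cells(
    region: np.ndarray, r_px: int, n_cells: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Non-overlapping disc centres inside ``region`` by dart throwing."""
    rows, cols = np.nonzero(region)
    if rows.size == 0 and n_cells > 0:
        raise PackingError("no free area to place cells")
    centres: list[tuple[int, int]] = []
    min_d2 = (2 * r_px + 2) ** 2
    h, w = region.shape
    attempts_per_cell = 2000
    for _ in range(n_cells):
        placed = False
        for _ in range(attempts_per_cell):
            k = rng.integers(rows.size)
            r, c = int(rows[k]), int(cols[k])
            if r - r_px < 0 or r + r_px >= h or c - r_px < 0 or c + r_px >= w:
                continue
            # disc must lie fully inside the free region
            rr, cc = np.ogrid[-r_px : r_px + 1, -r_px : r_px + 1]
            disc = rr**2 + cc**2 <= r_px**2
            if not region[r - r_px : r + r_px + 1, c - r_px : c + r_px + 1][disc].all():
                continue
            if all((r - pr) ** 2 + (c - pc) ** 2 >= min_d2 for pr, pc in centres):
                centres.append((r, c))
                placed = True
                break
        if not placed:
            raise PackingError(
                f"could not place {n_cells} non-overlapping cells "
                f"(placed {len(centres)}) — region too small"
            )
    return centres


def generate_slide(spec: SlideSpec) -> SlideResult:
    """Synthetic stained slice: rectangular cartilage region, exact colour areas, disc cells.

    The cartilage mask is a centred rectangle of ~``mask_fraction`` of the
    frame. Colour areas are painted as raster-contiguous blocks of exactly
    ``round(fraction × mask_area)`` pixels, so planted fractions are exact to
    one pixel. Cells are flat dark discs placed without overlap in the
    uncoloured remainder of the mask (they never disturb the colour counts).
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    img = np.zeros((H, W, 3), dtype=np.uint8)
    bg = spec.background_intensity
    img[:] = (bg, bg, bg)

    # centred rectangle with ~mask_fraction of the frame area
    area = spec.mask_fraction * H * W
    mh = min(H, max(8, int(round(np.sqrt(area * H / W)))))
    mw = min(W, max(8, int(round(area / mh))))
    r0, c0 = (H - mh) // 2, (W - mw) // 2
    mask = np.zeros((H, W), dtype=bool)
    mask[r0 : r0 + mh, c0 : c0 + mw] = True
    mask_px = int(mask.sum())

    img[mask] = SLIDE_COLORS["tissue"]

    # exact colour blocks in raster order within the mask
    flat_idx = np.flatnonzero(mask.ravel())
    counts = [int(round(f * mask_px)) for f in spec.color_fractions]
    if sum(counts) > mask_px:
        raise ValidationError("colour fractions exceed the mask area")
    pos = 0
    flat_img = img.reshape(-1, 3)
    for count, name in zip(counts, ("red", "yellow", "green")):
        flat_img[flat_idx[pos : pos + count]] = SLIDE_COLORS[name]
        pos += count

    # cells go in the uncoloured remainder, kept clear of the colour blocks
    free = np.zeros((H, W), dtype=bool)
    free.ravel()[flat_idx[pos:]] = True
    r_px = max(1, int(round(spec.cell_radius / spec.pixel_size)))
    centres = _place_cells(free, r_px, spec.n_cells, rng)
    for r, c in centres:
        rr, cc = np.ogrid[-r_px : r_px + 1, -r_px : r_px + 1]
        disc = rr**2 + cc**2 <= r_px**2
        img[r - r_px : r + r_px + 1, c - r_px : c + r_px + 1][disc] = SLIDE_COLORS["cell"]

    area_um2 = mask_px * spec.pixel_size**2
    area_mm2 = area_um2 / 1e6
    truth = {
        "mask_pixels": mask_px,
        "mask_area_um2": area_um2,
        "mask_area_mm2": area_mm2,
        "red_fraction": counts[0] / mask_px,
        "yellow_fraction": counts[1] / mask_px,
        "green_fraction": counts[2] / mask_px,
        "n_cells": spec.n_cells,
        "cell_radius_px": r_px,
        "cellularity_per_mm2": spec.n_cells / area_mm2,
        "pixel_size_um": spec.pixel_size,
        "seed": spec.seed,
    }
    return SlideResult(image=img, mask=mask, truth=truth)
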
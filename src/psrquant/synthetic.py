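"""Synthetic picrosirius-red (PSR) liver slides and cohorts with exact ground truth.

Every generated slide consists of a white "glass" background, one large
smoothed-polygon tissue silhouette (optionally pierced by vessel-like lumina),
and red collagen drawn either as septal bands (random-walk strokes connecting
scattered vein seeds, emulating bridging fibrosis of the CCl4 model) or as a
perisinusoidal "chicken-wire" lattice of thin strands (emulating early
steatohepatitis fibrosis).  Strokes are added until the ground-truth collagen /
tissue pixel ratio reaches the requested CPA target.

Color model
-----------
Colors are synthesized in optical-density (OD) space so that the downstream
stain-separation step is exercised meaningfully.  The tissue OD cloud has three
populations:

* parenchyma: mean OD vector ``m`` (a grey-tan counterstain, rendered somewhat
  darker than typical PSR counterstains so this axis firmly dominates the OD
  cloud) modulated along an in-plane *tone axis* ``d`` (orthogonal to ``m``)
  by a smooth random field, emulating zonal staining heterogeneity at the
  ~100 µm scale;
* collagen: an OD vector composed of a component along ``m`` plus a sizeable
  component along the *normal* of the parenchyma plane (``n = m x d``);
* glass: OD ~ 0 plus sensor noise.

By construction the parenchyma cloud spans the two highest-variance OD axes
and collagen carries the only consistent signal along the third
(least-variance) axis, which is exactly the geometry the OD/SVD/third-vector
segmenter exploits on real PSR slides.  The default collagen RGB is chosen so
its OD has a *zero* component along the tone axis (no crosstalk between the
second and third singular vectors) — a deep pink-red consistent with Sirius
red F3B under brightfield.

Rendering is internally supersampled 2x and downscaled by area averaging
(majority vote for masks), cheaply emulating scanner optics: fiber edges are
partial-volume mixed rather than razor sharp.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk

from .slide_io import WholeSlideImage, write_slide, write_mask
from .scoring import SYSTEM_NAMES

# Reference pixel size used to express fiber geometry (the emulated scanner's
# 20X pixel pitch); stroke widths below are given in pixels at this scale.
REFERENCE_UM_PER_PIXEL = 0.452

# Internal supersampling factor for rendering.
SUPERSAMPLE = 2

# Tone axis seed direction in OD space (orthogonalized against the parenchyma
# mean OD at runtime): a red<->blue hue modulation of the counterstain.
_TONE_SEED = np.array([0.6, 0.1, -0.6])
TONE_AMPLITUDE = 0.26       # OD units, full scale of the zonal tone field
TONE_FIELD_SD = 0.5         # std of the tone field before clipping to [-1, 1]
TONE_LENGTH_UM = 100.0      # correlation length of the tone field


class UnreachableTargetError(ValueError):
    """Requested CPA target cannot be reached for the given pattern/geometry."""


@dataclass(frozen=True)
class SlideGenParams:
    """Generation parameters of one synthetic PSR slide.

    ``target_cpa`` is the requested collagen proportionate area in percent;
    the generator adds fibers until the ground-truth pixel ratio lands within
    1.5 percentage points of it.  ``seed`` fully determines the output.
    """

    width_px: int = 1024
    height_px: int = 1024
    um_per_pixel: float = 0.452
    pattern: str = "septal"          # septal | perisinusoidal | none
    target_cpa: float = 10.0
    glass_level: Tuple[int, int, int] = (245, 245, 245)
    collagen_color: Tuple[int, int, int] = (210, 131, 170)
    parenchyma_color: Tuple[int, int, int] = (166, 142, 132)
    color_jitter_sd: float = 1.2
    noise_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("slide dimensions must be positive")
        if not (self.um_per_pixel > 0):
            raise ValueError("um_per_pixel must be positive")
        if self.pattern not in ("septal", "perisinusoidal", "none"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if not (0.0 <= self.target_cpa <= 100.0):
            raise ValueError("target_cpa must lie in [0, 100]")
        for tpl in (self.glass_level, self.collagen_color, self.parenchyma_color):
            if len(tpl) != 3 or any(not (0 <= v <= 255) for v in tpl):
                raise ValueError(f"color triplet out of range: {tpl}")
        if self.color_jitter_sd < 0 or self.noise_sd < 0:
            raise ValueError("noise parameters must be nonnegative")


@dataclass
class SyntheticSlide:
    """A generated slide plus its exact ground truth."""

    image: np.ndarray            # (H, W, 3) uint8
    tissue_truth: np.ndarray     # (H, W) bool
    collagen_truth: np.ndarray   # (H, W) bool
    params: SlideGenParams

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.tissue_truth.shape or self.image.shape[:2] != self.collagen_truth.shape:
            raise ValueError("image and ground-truth rasters must share dimensions")
        if np.any(self.collagen_truth & ~self.tissue_truth):
            raise ValueError("collagen ground truth must be nested in tissue")

    @property
    def true_cpa(self) -> float:
        """Ground-truth CPA in percent, exactly the mask pixel-count ratio."""
        tissue = int(np.count_nonzero(self.tissue_truth))
        if tissue == 0:
            return 0.0
        return 100.0 * int(np.count_nonzero(self.collagen_truth)) / tissue

    def as_wsi(self, source_path: str = "") -> WholeSlideImage:
        return WholeSlideImage(self.image, self.params.um_per_pixel, source_path)


# ---------------------------------------------------------------------------
# OD color geometry


def _od(rgb: Sequence[float], glass: Sequence[float]) -> np.ndarray:
    return np.log10(np.asarray(glass, float) / np.maximum(np.asarray(rgb, float), 0.5))


def _tone_axis(parenchyma_od: np.ndarray) -> np.ndarray:
    """Unit tone direction orthogonal to the parenchyma mean OD."""
    m_hat = parenchyma_od / np.linalg.norm(parenchyma_od)
    d = _TONE_SEED - (_TONE_SEED @ m_hat) * m_hat
    return d / np.linalg.norm(d)


def _smooth_field(rng: np.random.Generator, shape: Tuple[int, int], length_px: float) -> np.ndarray:
    """Zero-mean smooth Gaussian field, unit variance, via coarse-grid upsampling."""
    step = max(2.0, length_px / 2.0)
    ch = int(np.ceil(shape[0] / step)) + 2
    cw = int(np.ceil(shape[1] / step)) + 2
    coarse = ndi.gaussian_filter(rng.standard_normal((ch, cw)), sigma=1.0)
    zoom = (shape[0] / (ch - 2), shape[1] / (cw - 2))
    fine = ndi.zoom(coarse, zoom, order=1, grid_mode=True, mode="nearest")
    fine = fine[: shape[0], : shape[1]]
    fine -= fine.mean()
    sd = fine.std()
    if sd > 0:
        fine /= sd
    return fine


# ---------------------------------------------------------------------------
# Geometry: tissue silhouette and collagen patterns


def _tissue_silhouette(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """One large star-convex smoothed blob with 1-2 internal lumina removed.

    The boundary is a low-order random Fourier series in polar coordinates
    around the slide center, filled by a vectorized radius comparison.
    """
    harmonics = [(k, rng.normal(0.0, 1.0 / k), rng.uniform(0, 2 * np.pi)) for k in range(2, 9)]
    cy = h / 2 + rng.uniform(-0.02, 0.02) * h
    cx = w / 2 + rng.uniform(-0.02, 0.02) * w
    r0 = 0.40 * min(h, w)

    yy = np.arange(h, dtype=np.float32)[:, None] - np.float32(cy)
    xx = np.arange(w, dtype=np.float32)[None, :] - np.float32(cx)
    theta = np.arctan2(yy, xx)
    radial = np.zeros((h, w), np.float32)
    peak = 0.0
    for k, amp, phase in harmonics:
        radial += np.float32(amp) * np.cos(k * theta + np.float32(phase))
        peak += abs(amp)
    radial /= max(1e-9, peak)
    boundary = r0 * (1.0 + 0.22 * radial)
    mask = yy * yy + xx * xx <= boundary * boundary

    # vessel-like lumina, large enough that hole filling must not close them
    for _ in range(int(rng.integers(1, 3))):
        lr = rng.uniform(0.02, 0.035) * min(h, w)
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.0, 0.5) * r0
        ly, lx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
        rr, cc = draw_disk((ly, lx), lr, shape=(h, w))
        mask[rr, cc] = False
    return mask


def _stamp_disks(mask: np.ndarray, ys: np.ndarray, xs: np.ndarray, radius: float) -> None:
    """Stamp filled disks of one radius at each (y, x) into ``mask``.

    Vectorized: one disk-offset template indexed at every center.
    """
    h, w = mask.shape
    yc = np.rint(ys).astype(np.int64)
    xc = np.rint(xs).astype(np.int64)
    if radius <= 0.6:
        dy = np.zeros(1, np.int64)
        dx = np.zeros(1, np.int64)
    else:
        r = int(np.ceil(radius))
        oy, ox = np.mgrid[-r:r + 1, -r:r + 1]
        keep = oy * oy + ox * ox <= radius * radius
        dy, dx = oy[keep], ox[keep]
    Y = (yc[:, None] + dy[None, :]).ravel()
    X = (xc[:, None] + dx[None, :]).ravel()
    ok = (Y >= 0) & (Y < h) & (X >= 0) & (X < w)
    mask[Y[ok], X[ok]] = True


def _septal_stroke(rng: np.random.Generator, mask: np.ndarray, seeds: np.ndarray,
                   px_scale: float, max_px: float = np.inf) -> None:
    """One random-walk band from a random vein seed.

    ``px_scale`` converts reference-scale pixels (0.452 µm/px) to the working
    grid; band widths 3-10 px and lengths 150-500 µm at reference scale.
    ``max_px`` caps the approximate painted area so the last strokes near a
    CPA target stay small.
    """
    h, w = mask.shape
    start = seeds[rng.integers(len(seeds))]
    width = rng.uniform(3.0, 10.0) * px_scale
    length_px = rng.uniform(150.0, 500.0) / REFERENCE_UM_PER_PIXEL * px_scale
    if np.isfinite(max_px):
        length_px = min(length_px, max(3.0 * width, max_px / width))
    step = max(1.0, width * 0.5)
    n_steps = max(2, int(length_px / step))
    ang = rng.uniform(0, 2 * np.pi)
    ys = np.empty(n_steps)
    xs = np.empty(n_steps)
    y, x = float(start[0]), float(start[1])
    for i in range(n_steps):
        ys[i], xs[i] = y, x
        ang += rng.normal(0.0, 0.15)
        y += step * np.sin(ang)
        x += step * np.cos(ang)
        if not (0 <= y < h and 0 <= x < w):
            ys, xs = ys[: i + 1], xs[: i + 1]
            break
    _stamp_disks(mask, ys, xs, width / 2.0)


def _lattice_edges(rng: np.random.Generator, h: int, w: int, spacing: float) -> np.ndarray:
    """Jittered-lattice edge endpoints, shuffled: (n, 4) array of y0,x0,y1,x1."""
    ny = max(2, int(h / spacing) + 1)
    nx = max(2, int(w / spacing) + 1)
    gy, gx = np.meshgrid(np.arange(ny) * spacing, np.arange(nx) * spacing, indexing="ij")
    jitter = 0.25 * spacing
    py = gy + rng.normal(0, jitter, gy.shape)
    px = gx + rng.normal(0, jitter, gx.shape)
    edges = []
    for dy, dx in ((0, 1), (1, 0)):
        y0, x0 = py[: ny - dy, : nx - dx], px[: ny - dy, : nx - dx]
        y1, x1 = py[dy:, dx:], px[dy:, dx:]
        edges.append(np.stack([y0.ravel(), x0.ravel(), y1.ravel(), x1.ravel()], axis=1))
    allE = np.concatenate(edges, axis=0)
    return allE[rng.permutation(len(allE))]


def _perisinusoidal_edge(rng: np.random.Generator, mask: np.ndarray, edge: np.ndarray,
                         px_scale: float) -> None:
    """One thin curvilinear strand along a jittered lattice edge (1-2 px wide)."""
    y0, x0, y1, x1 = edge
    width = rng.uniform(1.0, 2.0) * px_scale
    n = max(3, int(np.hypot(y1 - y0, x1 - x0)))
    t = np.linspace(0.0, 1.0, n)
    # quadratic bow for curvature
    bow = rng.normal(0.0, 0.15) * np.hypot(y1 - y0, x1 - x0)
    nyv, nxv = (x1 - x0), -(y1 - y0)
    norm = max(1e-9, np.hypot(nyv, nxv))
    ys = y0 + t * (y1 - y0) + bow * t * (1 - t) * nyv / norm
    xs = x0 + t * (x1 - x0) + bow * t * (1 - t) * nxv / norm
    _stamp_disks(mask, ys, xs, width / 2.0)


def _grow_collagen(rng: np.random.Generator, tissue: np.ndarray, pattern: str,
                   target_cpa: float, px_scale: float, ss: int) -> np.ndarray:
    """Add strokes until the *native-grid* collagen/tissue ratio reaches the target.

    Drawing happens on the supersampled grid, but the stopping criterion is
    evaluated on majority-vote-downsampled masks — the ground truth the slide
    will actually carry — because thin strands change apparent area under
    block resampling.
    """
    h, w = tissue.shape
    collagen = np.zeros_like(tissue)
    if target_cpa <= 0:
        return collagen
    if pattern == "none":
        raise UnreachableTargetError(
            "pattern='none' draws no fibers; achievable target_cpa is exactly 0"
        )
    tissue_native = _downsample_mask(tissue, ss)
    tissue_native_n = int(np.count_nonzero(tissue_native))
    tissue_idx = np.flatnonzero(tissue)
    if tissue_native_n == 0 or len(tissue_idx) == 0:
        raise UnreachableTargetError("tissue silhouette is empty; no CPA > 0 achievable")
    target_n = target_cpa / 100.0 * tissue_native_n  # native pixels

    if pattern == "septal":
        n_seeds = max(4, int(tissue.size / 300_000))
        picks = rng.choice(tissue_idx, size=n_seeds, replace=True)
        seeds = np.stack(np.unravel_index(picks, tissue.shape), axis=1).astype(float)
    else:
        spacing = 25.0 / REFERENCE_UM_PER_PIXEL * px_scale
        edge_queue: List[np.ndarray] = list(_lattice_edges(rng, h, w, spacing))
        edge_native_px = spacing * 1.5 * px_scale / (ss * ss)  # rough area/edge

    def native_count() -> int:
        return int(np.count_nonzero(_downsample_mask(collagen & tissue, ss) & tissue_native))

    max_batches = 20_000
    batch = 0
    count = 0
    while count < target_n:
        batch += 1
        if batch > max_batches:
            achieved = 100.0 * count / tissue_native_n
            raise UnreachableTargetError(
                f"target_cpa={target_cpa} not reached after {max_batches} batches; "
                f"achievable range for this geometry is [0, ~{achieved:.1f}]%"
            )
        remaining = target_n - count
        if pattern == "septal":
            # budget in supersampled pixels, kept under the remaining deficit
            _septal_stroke(rng, collagen, seeds, px_scale,
                           max_px=0.7 * remaining * ss * ss)
        else:
            n_edges = int(np.clip(0.7 * remaining / max(edge_native_px, 1.0), 1, 25))
            for _ in range(n_edges):
                if not edge_queue:
                    edge_queue = list(_lattice_edges(rng, h, w, spacing))
                _perisinusoidal_edge(rng, collagen, edge_queue.pop(), px_scale)
        count = native_count()
    return collagen & tissue


# ---------------------------------------------------------------------------
# Rendering


def _render(rng: np.random.Generator, params: SlideGenParams, tissue: np.ndarray,
            collagen: np.ndarray, um_pp_grid: float) -> np.ndarray:
    """Render float RGB from masks on the (supersampled) working grid."""
    h, w = tissue.shape
    glass = np.asarray(params.glass_level, float)
    m = _od(params.parenchyma_color, glass)
    c = _od(params.collagen_color, glass)
    d_hat = _tone_axis(m)

    tone = _smooth_field(rng, (h, w), TONE_LENGTH_UM / um_pp_grid)
    tone = np.clip(tone * TONE_FIELD_SD, -1.0, 1.0)

    od = np.zeros((h, w, 3), np.float32)
    parench = tissue & ~collagen
    od[parench] = m.astype(np.float32)
    od[parench] += (tone[parench, None] * (TONE_AMPLITUDE * d_hat)).astype(np.float32)
    od[collagen] = c.astype(np.float32)
    np.clip(od, 0.0, None, out=od)

    img = glass.astype(np.float32) * np.power(10.0, -od, dtype=np.float32)
    if params.color_jitter_sd > 0:
        jit = rng.standard_normal(img.shape, dtype=np.float32)
        jit *= np.float32(params.color_jitter_sd)
        img += jit * tissue[:, :, None]
    if params.noise_sd > 0:
        noise = rng.standard_normal(img.shape, dtype=np.float32)
        noise *= np.float32(params.noise_sd)
        img += noise
    return img


def _downsample_image(img: np.ndarray, f: int) -> np.ndarray:
    """Area-average an (H, W, 3) float image by an integer factor, to uint8."""
    h, w = img.shape[:2]
    hh, ww = (h // f) * f, (w // f) * f
    img = img[:hh, :ww]
    blocks = img.reshape(hh // f, f, ww // f, f, 3).mean(axis=(1, 3))
    return np.clip(np.rint(blocks), 0, 255).astype(np.uint8)


def _downsample_mask(mask: np.ndarray, f: int) -> np.ndarray:
    """Majority-vote block resampling of a boolean mask.

    Blocks at exactly half coverage count as True: a half-covered pixel reads
    as stained in the area-averaged image as well, and breaking ties any other
    way fragments strands that are thinner than the output pixel pitch.
    """
    h, w = mask.shape
    hh, ww = (h // f) * f, (w // f) * f
    sums = mask[:hh, :ww].reshape(hh // f, f, ww // f, f).sum(axis=(1, 3))
    return sums * 2 >= f * f


# ---------------------------------------------------------------------------
# Public operations


def make_slide(params: SlideGenParams) -> SyntheticSlide:
    """Generate one synthetic PSR slide; seed-deterministic, CPA within 1.5 pp.

    Raises :class:`UnreachableTargetError` when the target CPA cannot be
    reached for the requested pattern (e.g. any positive target with
    ``pattern='none'``).
    """
    rng = np.random.default_rng(params.seed)
    ss = SUPERSAMPLE
    h2, w2 = params.height_px * ss, params.width_px * ss
    um_pp_grid = params.um_per_pixel / ss
    px_scale = REFERENCE_UM_PER_PIXEL / um_pp_grid  # reference px -> grid px

    tissue2 = _tissue_silhouette(rng, h2, w2)
    collagen2 = _grow_collagen(rng, tissue2, params.pattern, params.target_cpa,
                               px_scale, ss)
    img2 = _render(rng, params, tissue2, collagen2, um_pp_grid)

    image = _downsample_image(img2, ss)
    tissue = _downsample_mask(tissue2, ss)
    collagen = _downsample_mask(collagen2, ss) & tissue
    slide = SyntheticSlide(image=image, tissue_truth=tissue, collagen_truth=collagen,
                           params=params)
    if params.target_cpa > 0 and abs(slide.true_cpa - params.target_cpa) > 1.5:
        raise UnreachableTargetError(
            f"achieved CPA {slide.true_cpa:.2f}% is more than 1.5 pp from the "
            f"target {params.target_cpa}%, geometry too coarse for this slide size"
        )
    return slide


def render_at_resolution(slide: SyntheticSlide, um_per_pixel: float) -> SyntheticSlide:
    """Resample a slide to a coarser pixel pitch (integer factor).

    The image is area-averaged, ground-truth masks are majority-voted, and the
    true CPA is recomputed from the resampled masks.  Upsampling requests and
    non-integer factors raise ``ValueError``.
    """
    native = slide.params.um_per_pixel
    factor = um_per_pixel / native
    if factor < 1.0 - 1e-9:
        raise ValueError(
            f"cannot upsample: requested {um_per_pixel} µm/px is finer than the "
            f"native {native} µm/px"
        )
    f = int(round(factor))
    if abs(factor - f) > 1e-6:
        raise ValueError(f"resampling factor {factor:.4f} is not an integer")
    if f == 1:
        return slide
    image = _downsample_image(slide.image.astype(np.float32), f)
    tissue = _downsample_mask(slide.tissue_truth, f)
    collagen = _downsample_mask(slide.collagen_truth, f) & tissue
    new_params = replace(slide.params, um_per_pixel=um_per_pixel,
                         width_px=image.shape[1], height_px=image.shape[0])
    return SyntheticSlide(image=image, tissue_truth=tissue, collagen_truth=collagen,
                          params=new_params)


def calibration_slides(seed: int = 2026, size_px: int = 768):
    """The standard calibration set for the global collagen threshold.

    Twelve slides spanning CPA 1-25% in the septal pattern and 1-12% in the
    perisinusoidal pattern, at 20X (0.452 µm/px) and including two 40X
    renders.  ``psrquant.segmentation.calibrate_threshold`` run on this set
    (default seed) is how the config default was frozen; yields slides lazily.
    """
    rng = np.random.default_rng(seed)
    plan = [("septal", t) for t in (1, 3, 5, 10, 15, 20, 25)]
    plan += [("perisinusoidal", t) for t in (1, 3, 5, 8, 12)]
    for pattern, target in plan:
        yield make_slide(SlideGenParams(width_px=size_px, height_px=size_px,
                                        pattern=pattern, target_cpa=float(target),
                                        seed=int(rng.integers(2**31))))
    for target in (5, 15):
        fine = make_slide(SlideGenParams(width_px=size_px, height_px=size_px,
                                         um_per_pixel=0.226, target_cpa=float(target),
                                         seed=int(rng.integers(2**31))))
        yield fine


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class CohortDesign:
    """Design of a synthetic cohort: groups, CPA trajectory, HYP linkage, staging.

    ``hyp_*`` parameters define HYP = slope * meanCPA + intercept + N(0, noise)
    in µg/g liver; ``stage_thresholds`` maps each scoring system to ordered CPA
    cutpoints that assign stage labels from the animal's mean true CPA.

    Default groups and trajectory emulate a CCl4 time course: a control group
    of 4 and 6 mice per treated group, 3 sections per animal, CPA rising from
    a 0.8% baseline with fold-changes of roughly 1x (week 1), 2.7x (week 3),
    4x (week 6), 5.7x (week 12) and 8.3x (week 18).
    """

    groups: Tuple[Tuple[str, int, int], ...] = (
        ("control", 0, 4), ("week1", 1, 6), ("week3", 3, 6),
        ("week6", 6, 6), ("week12", 12, 6), ("week18", 18, 6),
    )
    sections_per_animal: int = 3
    cpa_trajectory: Tuple[Tuple[int, float], ...] = (
        (0, 0.8), (1, 0.85), (3, 2.2), (6, 3.2), (12, 4.6), (18, 6.7),
    )
    cpa_between_animal_sd: float = 0.5
    hyp_slope: float = 25.0
    hyp_intercept: float = 150.0
    hyp_noise_sd: float = 30.0
    stage_thresholds: Tuple[Tuple[str, Tuple[float, ...]], ...] = (
        ("ishak", (1.0, 2.0, 4.0, 8.0, 14.0, 22.0)),
        ("ishak_modified", (1.0, 2.0, 4.0, 8.0, 14.0, 22.0)),
        ("nash_crn", (0.8, 1.5, 2.5, 4.0, 8.0, 16.0)),
    )
    slide_width_px: int = 768
    slide_height_px: int = 768
    um_per_pixel: float = 0.452
    pattern: str = "septal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sections_per_animal < 1:
            raise ValueError("sections_per_animal must be >= 1")
        for _, _, n in self.groups:
            if n < 1:
                raise ValueError("every group needs n_animals >= 1")
        for system, cuts in self.stage_thresholds:
            if list(cuts) != sorted(cuts) or len(set(cuts)) != len(cuts):
                raise ValueError(f"stage thresholds for {system} must be strictly increasing")


_STAGE_LABELS: Dict[str, List[str]] = {
    "ishak": ["0", "1", "2", "3", "4", "5", "6"],
    "ishak_modified": ["0", "1", "2", "3", "4", "5", "6"],
    "nash_crn": ["0", "1A", "1B", "1C", "2", "3", "4"],
}


def _stage_label(system: str, cuts: Sequence[float], cpa: float) -> str:
    idx = int(np.searchsorted(np.asarray(cuts), cpa, side="right"))
    return _STAGE_LABELS[system][idx]


def make_cohort(design: CohortDesign, out_dir: str) -> Dict[str, object]:
    """Generate slides and metadata for a whole cohort; fully seed-deterministic.

    Writes one PNG per section plus ground-truth masks, a per-section
    ``sections.csv``, a per-animal ``animals.csv``, and a JSON sidecar with the
    design.  Stage labels are obtained by thresholding each animal's mean true
    CPA at ``design.stage_thresholds``.  Returns the two tables and slide paths.
    """
    os.makedirs(out_dir, exist_ok=True)
    slide_dir = os.path.join(out_dir, "slides")
    os.makedirs(slide_dir, exist_ok=True)
    rng = np.random.default_rng(design.seed)
    trajectory = dict(design.cpa_trajectory)

    section_rows = []
    animal_rows = []
    animal_no = 0
    for label, week, n_animals in design.groups:
        if week not in trajectory:
            raise ValueError(f"no CPA trajectory value for week {week}")
        for _ in range(n_animals):
            animal_no += 1
            animal_id = f"m{animal_no:03d}"
            animal_cpa = float(np.clip(
                trajectory[week] + rng.normal(0.0, design.cpa_between_animal_sd),
                0.2, 60.0,
            ))
            section_cpas = []
            paths = []
            for sec in range(design.sections_per_animal):
                sparams = SlideGenParams(
                    width_px=design.slide_width_px,
                    height_px=design.slide_height_px,
                    um_per_pixel=design.um_per_pixel,
                    pattern=design.pattern,
                    target_cpa=animal_cpa,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                slide = make_slide(sparams)
                rel = os.path.join("slides", f"{animal_id}_s{sec}.png")
                path = os.path.join(out_dir, rel)
                write_slide(slide.as_wsi(), path)
                write_mask(slide.tissue_truth, os.path.join(slide_dir, f"{animal_id}_s{sec}_tissue.png"))
                write_mask(slide.collagen_truth, os.path.join(slide_dir, f"{animal_id}_s{sec}_collagen.png"))
                section_cpas.append(slide.true_cpa)
                paths.append(rel)

            mean_cpa = float(np.mean(section_cpas))
            hyp = design.hyp_slope * mean_cpa + design.hyp_intercept
            hyp += rng.normal(0.0, design.hyp_noise_sd)
            hyp = float(max(0.0, hyp))
            stages = {
                system: _stage_label(system, cuts, mean_cpa)
                for system, cuts in design.stage_thresholds
            }
            for sec, (rel, scpa) in enumerate(zip(paths, section_cpas)):
                section_rows.append({
                    "animal_id": animal_id, "group": label, "week": week,
                    "section_index": sec, "slide_path": rel,
                    "true_cpa": scpa, "hyp_ug_per_g": hyp,
                    **{s: stages.get(s, "") for s in SYSTEM_NAMES},
                })
            animal_rows.append({
                "animal_id": animal_id, "group": label, "week": week,
                "slide_paths": ";".join(paths),
                "mean_true_cpa": mean_cpa, "hyp_ug_per_g": hyp,
                **{s: stages.get(s, "") for s in SYSTEM_NAMES},
            })

    sections = pd.DataFrame(section_rows)
    animals = pd.DataFrame(animal_rows)
    sections.to_csv(os.path.join(out_dir, "sections.csv"), index=False)
    animals.to_csv(os.path.join(out_dir, "animals.csv"), index=False)
    with open(os.path.join(out_dir, "design.json"), "w") as fh:
        json.dump(asdict(design), fh, indent=2, default=list)
    return {"sections": sections, "animals": animals, "out_dir": out_dir}
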
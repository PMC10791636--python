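"""Placenta calcification morphometry from stained slide images.

The recipe: convert to 8-bit grayscale, take the tissue mask with Huang's
fuzzy-entropy auto-threshold, the calcified mask with Yen's
maximum-correlation auto-threshold applied within the tissue, drop
particles smaller than 0.0003 mm^2 (strictly smaller), then pool areas over
all slides of one placenta:

* CCI  = (total calcified area / total tissue area) * 100  [percent]
* CCN  = (number of calcified dots / total tissue area) * 100
  (the printed formula; dots per mm^2 is also reported)
* thickness = mean over slides of the tissue-mask minor-axis extent

Both thresholding criteria are implemented from their original definitions
and are checked against exhaustive 256-level searches in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

DEGENERATE = -1  # sentinel threshold for histograms without two populations


@dataclass
class MorphometryParams:
    pixel_size_mm: float  # mm per pixel side
    min_particle_area_mm2: float = 0.0003
    connectivity: int = 2  # 8-connectivity, the common particle-analysis default
    ccn_times_100: bool = True  # printed formula multiplies by 100

    def __post_init__(self) -> None:
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")
        if self.min_particle_area_mm2 < 0:
            raise ValueError("min_particle_area_mm2 must be >= 0")


@dataclass
class CalcificationMetrics:
    total_area_mm2: float
    calcified_area_mm2: float
    n_dots: int
    cci_pct: float
    ccn: float  # per printed formula (x100) unless ccn_times_100=False
    ccn_per_mm2: float
    thickness_mm: float  # mean over slides
    slide_thickness_mm: list[float]


def _histogram(image: np.ndarray) -> np.ndarray:
    if image.dtype != np.uint8:
        raise ValueError("expected an 8-bit grayscale image")
    return np.bincount(image.ravel(), minlength=256).astype(np.float64)


def huang_threshold(hist: np.ndarray) -> int:
    """Huang's fuzzy thresholding: minimize Shannon entropy of membership.

    For candidate threshold t, pixels <= t belong to the background with
    membership 1/(1 + |g - mu0|/C) and pixels > t to the foreground with
    membership 1/(1 + |g - mu1|/C), where mu0/mu1 are the class means and C
    is the gray-level range of the occupied histogram support.  The returned
    level is the t minimizing total fuzziness; ties break to the lowest
    level.  A histogram with a single occupied level is degenerate and
    returns the ``DEGENERATE`` sentinel.
    """
    hist = np.asarray(hist, dtype=np.float64)
    if hist.size != 256:
        raise ValueError("need a 256-bin histogram")
    occupied = np.flatnonzero(hist)
    if occupied.size == 0:
        raise ValueError("empty histogram")
    if occupied.size == 1:
        return DEGENERATE
    g = np.arange(256, dtype=np.float64)
    c_range = float(occupied[-1] - occupied[0])
    w = hist.cumsum()
    wg = (hist * g).cumsum()
    total_w, total_wg = w[-1], wg[-1]
    best_t, best_s = DEGENERATE, np.inf
    for t in range(occupied[0], occupied[-1]):
        w0 = w[t]
        w1 = total_w - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = wg[t] / w0
        mu1 = (total_wg - wg[t]) / w1
        u = np.empty(256)
        u[: t + 1] = 1.0 / (1.0 + np.abs(g[: t + 1] - mu0) / c_range)
        u[t + 1 :] = 1.0 / (1.0 + np.abs(g[t + 1 :] - mu1) / c_range)
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -(u * np.log(u) + (1 - u) * np.log(1 - u))
        h[~np.isfinite(h)] = 0.0  # u == 1 contributes zero fuzziness
        s = float((hist * h).sum() / total_w)
        if s < best_s - 1e-15:
            best_s, best_t = s, t
    return best_t


def yen_threshold(hist: np.ndarray) -> int:
    """Yen's maximum-correlation thresholding.

    Maximizes TC(t) = -ln(G0(t) * G1(t)) + 2 ln(P0(t) * P1(t)) where P0/P1
    are the class probabilities and G0/G1 the sums of squared normalized
    frequencies below/above t.  Ties break to the lowest level; a
    single-level histogram returns the ``DEGENERATE`` sentinel.
    """
    hist = np.asarray(hist, dtype=np.float64)
    if hist.size != 256:
        raise ValueError("need a 256-bin histogram")
    occupied = np.flatnonzero(hist)
    if occupied.size == 0:
        raise ValueError("empty histogram")
    if occupied.size == 1:
        return DEGENERATE
    p = hist / hist.sum()
    p1 = p.cumsum()
    p2 = (p**2).cumsum()
    total_p2 = p2[-1]
    best_t, best_tc = DEGENERATE, -np.inf
    for t in range(occupied[0], occupied[-1]):
        p0_, p1_ = p1[t], 1.0 - p1[t]
        g0, g1 = p2[t], total_p2 - p2[t]
        if p0_ <= 0 or p1_ <= 0 or g0 <= 0 or g1 <= 0:
            continue
        tc = -np.log(g0 * g1) + 2 * np.log(p0_ * p1_)
        if tc > best_tc + 1e-15:
            best_tc, best_t = tc, t
    return best_t


def threshold_mask(image: np.ndarray, threshold: int) -> np.ndarray:
    """Foreground mask: pixels strictly above the threshold level."""
    return image > threshold


@dataclass
class Particle:
    label: int
    area_mm2: float
    centroid: tuple[float, float]


def particle_analysis(mask: np.ndarray, params: MorphometryParams) -> list[Particle]:
    """Connected-component particles with areas; sub-minimum particles dropped.

    A particle of exactly the minimum area is retained (only strictly
    smaller ones are filtered out).
    """
    if mask.dtype != bool:
        raise ValueError("particle_analysis expects a boolean mask")
    labels = measure.label(mask, connectivity=params.connectivity)
    px_area = params.pixel_size_mm**2
    out = []
    for region in measure.regionprops(labels):
        area = region.area * px_area
        if area < params.min_particle_area_mm2:
            continue
        out.append(Particle(region.label, float(area), tuple(region.centroid)))
    return out


def segment_slide(image: np.ndarray, params: MorphometryParams):
    """Tissue and calcified masks of one slide.

    Tissue: Huang threshold on the full histogram (tissue bright on dark
    background), holes filled so dark pockets inside tissue still count as
    tissue.  Calcified: Yen threshold on the histogram of tissue pixels; if
    the "calcified" class would swallow more than a quarter of the tissue
    the slide is treated as having no distinct calcified population.
    """
    t_tissue = huang_threshold(_histogram(image))
    if t_tissue == DEGENERATE:
        raise ValueError("degenerate slide: single gray level")
    tissue = ndimage.binary_fill_holes(threshold_mask(image, t_tissue))
    tissue_pixels = image[tissue]
    if tissue_pixels.size == 0:
        raise ValueError("empty tissue mask")
    hist_tissue = np.bincount(tissue_pixels.ravel(), minlength=256).astype(np.float64)
    t_cal = yen_threshold(hist_tissue)
    if t_cal == DEGENERATE:
        return tissue, np.zeros_like(tissue)
    calcified = tissue & threshold_mask(image, t_cal)
    # bimodality guard: an auto-threshold always returns *some* split, even
    # on a unimodal (uncalcified) histogram.  Demand that the bright class
    # is genuinely separated from the tissue class relative to the tissue
    # noise, and that it is a minority of the tissue.
    lo = tissue_pixels[tissue_pixels <= t_cal]
    hi = tissue_pixels[tissue_pixels > t_cal]
    if hi.size == 0 or lo.size == 0:
        return tissue, np.zeros_like(tissue)
    sep = float(hi.mean()) - float(lo.mean())
    if sep < 4.0 * max(float(lo.std()), 1.0) or hi.size > 0.25 * tissue_pixels.size:
        calcified = np.zeros_like(tissue)
    return tissue, calcified


def slide_thickness_mm(tissue_mask: np.ndarray, pixel_size_mm: float) -> float:
    """Tissue extent along the minor axis of the tissue bounding box."""
    rows = np.flatnonzero(tissue_mask.any(axis=1))
    cols = np.flatnonzero(tissue_mask.any(axis=0))
    if rows.size == 0:
        return 0.0
    extent_r = rows[-1] - rows[0] + 1
    extent_c = cols[-1] - cols[0] + 1
    return float(min(extent_r, extent_c) * pixel_size_mm)


def compute_metrics(slides: list[np.ndarray], params: MorphometryParams) -> CalcificationMetrics:
    """Pool slide segmentations of one placenta into its metrics.

    Areas are pooled across slides before division, so per-slide variation
    in section size is weighted naturally.
    """
    if not slides:
        raise ValueError("need at least one slide")
    px_area = params.pixel_size_mm**2
    total_px = 0
    cal_area = 0.0
    n_dots = 0
    thicknesses = []
    for img in slides:
        tissue, calcified = segment_slide(img, params)
        total_px += int(tissue.sum())
        particles = particle_analysis(calcified, params)
        cal_area += sum(p.area_mm2 for p in particles)
        n_dots += len(particles)
        thicknesses.append(slide_thickness_mm(tissue, params.pixel_size_mm))
    total_area = total_px * px_area
    if total_area <= 0:
        raise ValueError("total tissue area is zero")
    cci = 100.0 * cal_area / total_area
    ccn_per_mm2 = n_dots / total_area
    ccn = 100.0 * ccn_per_mm2 if params.ccn_times_100 else ccn_per_mm2
    return CalcificationMetrics(
        total_area_mm2=float(total_area),
        calcified_area_mm2=float(cal_area),
        n_dots=n_dots,
        cci_pct=float(cci),
        ccn=float(ccn),
        ccn_per_mm2=float(ccn_per_mm2),
        thickness_mm=float(np.mean(thicknesses)),
        slide_thickness_mm=thicknesses,
    )


def to_grayscale_8bit(image: np.ndarray) -> np.ndarray:
    """Plain-luminance conversion of an RGB(A) image to 8-bit grayscale."""
    if image.ndim == 2:
        return image.astype(np.uint8)
    rgb = image[..., :3].astype(np.float64)
    lum = 0.2126 * rgb[..., 0] + 0.7152 * rgb[..., 1] + 0.0722 * rgb[..., 2]
    return np.clip(np.round(lum), 0, 255).astype(np.uint8)
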
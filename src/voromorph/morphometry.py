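"""Micrograph-style image measurement: segmentation, area fractions, and
nanoscale morphometry of capsule pores, layers, and cells.

The segmentation chain mirrors common electron-micrograph practice: optional
edge emphasis (3x3 gradient magnitude) to sharpen boundaries, Gaussian
smoothing to suppress shot noise, then global thresholding to a binary mask
from which area fractions and distances are measured.  All distances are
reported in nm (or um for whole cells) via the nm-per-pixel calibration.

Operational definitions for quantities the micrographs only show visually:

* pore diameter — maximal inscribed-circle diameter of each pore component
  (distance-transform maximum x 2); equals the wall-to-wall chord on circular
  pores and is robust on polygonal ones;
* pore depth — vertical extent of each wall spine above the dense capsule
  layer in a vertical-section profile;
* layer thickness — foreground run length along radial rays cast from the
  centre of an annular layer mask;
* cell major axis — the longer of the axis-aligned bounding-box height and
  width of each connected component (clusters are measured as units; no
  watershed splitting).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import ndimage as ndi
from skimage import measure as skmeasure
from skimage.filters import threshold_otsu
from skimage.segmentation import clear_border

from .geometry import SeedSet
from .stats import SummaryStat, summarize

__all__ = [
    "GrayImage",
    "BinaryMask",
    "Measurement",
    "MorphometryReport",
    "preprocess",
    "binarize",
    "area_fraction",
    "infer_pore_sites",
    "measure_pore_geometry",
    "measure_layer_thickness",
    "cell_major_axis",
]

logger = logging.getLogger(__name__)

#: measurement kinds and their reporting unit
KIND_UNITS = {
    "pore_diameter": "nm",
    "pore_depth": "nm",
    "capsule_thickness": "nm",
    "cell_wall_thickness": "nm",
    "cell_major_axis": "um",
}


class ImageError(ValueError):
    """Invalid image input or degenerate measurement request."""


@dataclass
class GrayImage:
    """2-D intensity grid in [0, 1] with an nm-per-pixel calibration."""

    pixels: np.ndarray
    nm_per_px: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ImageError("image must be 2-D and at least 2x2")
        if not np.all(np.isfinite(px)):
            raise ImageError("intensities must be finite")
        if px.min() < -1e-9 or px.max() > 1 + 1e-9:
            raise ImageError("intensities must lie in [0, 1]")
        if not self.nm_per_px > 0:
            raise ImageError("nm_per_px must be positive")
        self.pixels = np.clip(px, 0.0, 1.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @classmethod
    def load(cls, path, nm_per_px: float) -> "GrayImage":
        """Read an 8/16-bit grayscale PNG or TIFF and normalise to [0, 1]."""
        arr = np.asarray(Image.open(path).convert("I;16" if str(path).lower().endswith((".tif", ".tiff")) else "L"))
        arr = arr.astype(float)
        denom = 65535.0 if arr.max() > 255 else 255.0
        return cls(arr / denom, nm_per_px)

    def save(self, path) -> None:
        Image.fromarray((self.pixels * 255).round().astype(np.uint8)).save(path)


@dataclass
class BinaryMask:
    """2-D boolean grid (True = foreground: cells or walls) with calibration."""

    pixels: np.ndarray
    nm_per_px: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.dtype != bool:
            px = px.astype(bool)
        if px.ndim != 2:
            raise ImageError("mask must be 2-D")
        if not self.nm_per_px > 0:
            raise ImageError("nm_per_px must be positive")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def complement(self) -> "BinaryMask":
        return BinaryMask(~self.pixels, self.nm_per_px)

    @classmethod
    def load(cls, path, nm_per_px: float) -> "BinaryMask":
        arr = np.asarray(Image.open(path).convert("L"))
        return cls(arr > 127, nm_per_px)

    def save(self, path) -> None:
        Image.fromarray(np.where(self.pixels, 255, 0).astype(np.uint8)).save(path)


@dataclass(frozen=True)
class Measurement:
    kind: str
    value: float  # nm, or um for cell_major_axis
    location: tuple[float, float]  # (row, col) of the measured structure


@dataclass
class MorphometryReport:
    """Per-structure distance measurements with per-kind summaries."""

    measurements: list[Measurement] = field(default_factory=list)

    def values(self, kind: str) -> np.ndarray:
        return np.array([m.value for m in self.measurements if m.kind == kind])

    def kinds(self) -> list[str]:
        seen: list[str] = []
        for m in self.measurements:
            if m.kind not in seen:
                seen.append(m.kind)
        return seen

    def summary(self, kind: str) -> SummaryStat:
        v = self.values(kind)
        if v.size == 0:
            raise ImageError(f"no measurements of kind {kind!r}")
        return summarize(v)

    def extend(self, other: "MorphometryReport") -> "MorphometryReport":
        self.measurements.extend(other.measurements)
        return self

    def to_dict(self) -> dict:
        return {
            kind: {**self.summary(kind).to_dict(), "unit": KIND_UNITS.get(kind, "nm")}
            for kind in self.kinds()
        }


# ---------------------------------------------------------------------------
# segmentation chain

def preprocess(
    img: GrayImage, edge_emphasis: bool = True, smoothing_scale: float = 1.5
) -> GrayImage:
    """Edge emphasis (3x3 gradient magnitude, rescaled to [0, 1]) followed by
    Gaussian smoothing — in that order, edges first."""
    if smoothing_scale < 0:
        raise ImageError("smoothing_scale must be >= 0")
    out = img.pixels
    if edge_emphasis:
        gx = ndi.sobel(out, axis=1)
        gy = ndi.sobel(out, axis=0)
        g = np.hypot(gx, gy)
        mx = g.max()
        out = g / mx if mx > 0 else np.zeros_like(g)
    if smoothing_scale > 0:
        out = ndi.gaussian_filter(out, smoothing_scale)
    return GrayImage(np.clip(out, 0.0, 1.0), img.nm_per_px)


def binarize(
    img: GrayImage,
    method: str = "otsu",
    level: float | None = None,
    foreground: str = "bright",
) -> BinaryMask:
    """Global threshold to a binary mask.

    ``method='otsu'`` maximises between-class variance over a 256-bin
    histogram; ``method='fixed'`` uses the given ``level``.  ``foreground``
    selects polarity: ``'bright'`` keeps pixels above the threshold,
    ``'dark'`` below (micrographs are printed with cells dark on white; the
    internal convention is foreground = cells/walls).
    """
    px = img.pixels
    if method == "otsu":
        if float(px.max() - px.min()) == 0.0:
            raise ImageError("constant image: Otsu threshold undefined")
        thr = float(threshold_otsu(px, nbins=256))
    elif method == "fixed":
        if level is None:
            raise ImageError("fixed method requires a level")
        thr = float(level)
    else:
        raise ImageError(f"unknown binarization method {method!r}")
    if foreground == "bright":
        mask = px > thr
    elif foreground == "dark":
        mask = px < thr
    else:
        raise ImageError(f"unknown polarity {foreground!r}")
    return BinaryMask(mask, img.nm_per_px)


def area_fraction(mask: BinaryMask) -> tuple[float, float]:
    """(foreground %, background %) by pixel count; the pair sums to exactly
    100."""
    total = mask.pixels.size
    fg = float(np.count_nonzero(mask.pixels)) * 100.0 / total
    return fg, 100.0 - fg


# ---------------------------------------------------------------------------
# geometry bridge

def infer_pore_sites(mask: BinaryMask, min_area_px: int = 9) -> SeedSet:
    """One seed per pore (background connected component) at its centroid.

    Coordinates follow the geometry convention x = column, y = -row; the bbox
    is the image extent.  Components smaller than ``min_area_px`` are treated
    as noise and ignored.
    """
    pores = ~mask.pixels
    labels = skmeasure.label(pores, connectivity=1)
    pts = []
    for rp in skmeasure.regionprops(labels):
        if rp.area < min_area_px:
            continue
        r, c = rp.centroid
        pts.append((c, -r))
    if len(pts) < 3:
        raise ImageError(
            f"need >= 3 pore components, found {len(pts)} (min_area_px={min_area_px})"
        )
    h, w = mask.shape
    return SeedSet(np.array(pts), bbox=(0.0, -(h - 1.0), w - 1.0, 0.0))


# ---------------------------------------------------------------------------
# nanoscale morphometry

def measure_pore_geometry(
    mask: BinaryMask,
    mode: str = "horizontal",
    min_area_px: int = 16,
) -> MorphometryReport:
    """Pore diameters (horizontal sections) or pore depths (vertical sections).

    ``mode='horizontal'``: the mask foreground is the wall network; each pore
    is a background component and its diameter is twice the maximum of the
    Euclidean distance transform inside the component (maximal inscribed
    circle).  Components clipped by the image border are excluded — their
    inscribed circle is truncated.

    ``mode='vertical'``: the mask is a section profile with a dense basal
    layer and wall spines rising from it; the cavity depth equals the spine
    length, the vertical extent of each foreground component above the layer
    top (the first row, scanning down, whose foreground fraction exceeds 0.5).
    """
    if mode == "horizontal":
        pores = ~mask.pixels
        labels = clear_border(skmeasure.label(pores, connectivity=1))
        if labels.max() == 0:
            raise ImageError("no interior pore components found")
        edt = ndi.distance_transform_edt(pores)
        report = MorphometryReport()
        for rp in skmeasure.regionprops(labels):
            if rp.area < min_area_px:
                continue
            rr, cc = rp.coords[:, 0], rp.coords[:, 1]
            local = edt[rr, cc]
            k = int(np.argmax(local))
            # EDT is centre-to-centre; the wall boundary lies half a pixel
            # inward of the first wall-pixel centre
            diam_nm = (2.0 * float(local[k]) - 1.0) * mask.nm_per_px
            report.measurements.append(
                Measurement("pore_diameter", diam_nm, (float(rr[k]), float(cc[k])))
            )
        if not report.measurements:
            raise ImageError("no pore component above the minimum area")
        return report

    if mode == "vertical":
        fg = mask.pixels
        row_fraction = fg.mean(axis=1)
        dense_rows = np.flatnonzero(row_fraction > 0.5)
        if dense_rows.size == 0:
            raise ImageError("vertical profile has no dense layer (no row > 50% foreground)")
        layer_top = int(dense_rows.min())
        if layer_top == 0:
            raise ImageError("dense layer reaches the image top: no spines to measure")
        above = fg[:layer_top, :]
        labels = skmeasure.label(above, connectivity=1)
        report = MorphometryReport()
        for rp in skmeasure.regionprops(labels):
            rmin, cmin, rmax, cmax = rp.bbox
            if rmax != layer_top:  # not attached to the dense layer
                continue
            depth_nm = (rmax - rmin) * mask.nm_per_px
            report.measurements.append(
                Measurement("pore_depth", depth_nm, (float(rmin), float((cmin + cmax) / 2)))
            )
        if not report.measurements:
            raise ImageError("no wall spines attached to the dense layer")
        return report

    raise ImageError(f"unknown mode {mode!r}")


def _interior_hole(mask_px: np.ndarray) -> np.ndarray | None:
    """Largest background component not touching the border, or None."""
    bg_labels = clear_border(skmeasure.label(~mask_px, connectivity=1))
    if bg_labels.max() == 0:
        return None
    props = skmeasure.regionprops(bg_labels)
    return max(props, key=lambda rp: rp.area)


def measure_layer_thickness(
    mask: BinaryMask,
    kind: str = "capsule_thickness",
    n_rays: int = 36,
    ray_step_px: float = 0.25,
    center: tuple[float, float] | None = None,
) -> MorphometryReport:
    """Thickness of an annular layer sampled along radial rays.

    The mask must be annular around the centre: a background cell body
    surrounded by the foreground layer.  Rays are cast from the interior-hole
    centroid (or, for a broken annulus whose gap connects the hole to the
    outside, from the foreground centroid); each ray's thickness is the
    length of its first contiguous foreground run.  Rays that cross a gap are
    skipped with a logged warning, reducing n.
    """
    if kind not in ("capsule_thickness", "cell_wall_thickness"):
        raise ImageError(f"unknown layer kind {kind!r}")
    if n_rays < 1:
        raise ImageError("n_rays must be >= 1")
    px = mask.pixels
    if center is None:
        hole = _interior_hole(px)
        if hole is not None:
            center = hole.centroid
        else:
            rr_fg, cc_fg = np.nonzero(px)
            if rr_fg.size == 0:
                raise ImageError("mask is empty")
            center = (float(rr_fg.mean()), float(cc_fg.mean()))
    r0, c0 = center
    ri, ci = int(round(r0)), int(round(c0))
    if 0 <= ri < px.shape[0] and 0 <= ci < px.shape[1] and px[ri, ci]:
        raise ImageError(
            "mask is not annular: the centre lies inside the foreground"
        )
    h, w = px.shape
    max_radius = math.hypot(h, w)
    report = MorphometryReport()
    skipped = 0
    for k in range(n_rays):
        theta = 2.0 * math.pi * k / n_rays
        dr, dc = math.sin(theta), math.cos(theta)
        steps = np.arange(0.0, max_radius, ray_step_px)
        rr = np.round(r0 + steps * dr).astype(int)
        cc = np.round(c0 + steps * dc).astype(int)
        inside = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        vals = np.zeros(len(steps), dtype=bool)
        vals[inside] = px[rr[inside], cc[inside]]
        hits = np.flatnonzero(vals)
        if hits.size == 0:
            skipped += 1
            continue
        entry = hits[0]
        run_end = entry
        while run_end + 1 < len(vals) and vals[run_end + 1]:
            run_end += 1
        thickness_nm = (steps[run_end] - steps[entry] + ray_step_px) * mask.nm_per_px
        loc = (float(r0 + steps[entry] * dr), float(c0 + steps[entry] * dc))
        report.measurements.append(Measurement(kind, thickness_nm, loc))
    if skipped:
        logger.warning(
            "%d of %d radial rays crossed a gap in the layer and were skipped",
            skipped, n_rays,
        )
    if not report.measurements:
        raise ImageError("no ray crossed the layer: mask not annular around the centre")
    return report


def cell_major_axis(mask: BinaryMask, min_area_px: int = 4) -> MorphometryReport:
    """Major axis (longer of bounding-box height and width) per connected
    component, in um.  Touching cells merge into one component and are
    measured as a single cluster (no splitting)."""
    labels = skmeasure.label(mask.pixels, connectivity=1)
    if labels.max() == 0:
        raise ImageError("empty mask: no cell components")
    report = MorphometryReport()
    for rp in skmeasure.regionprops(labels):
        if rp.area < min_area_px:
            continue
        rmin, cmin, rmax, cmax = rp.bbox
        major_px = max(rmax - rmin, cmax - cmin)
        report.measurements.append(
            Measurement(
                "cell_major_axis",
                major_px * mask.nm_per_px / 1000.0,
                tuple(float(v) for v in rp.centroid),
            )
        )
    if not report.measurements:
        raise ImageError("no cell component above the minimum area")
    return report
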
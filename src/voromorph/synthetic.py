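"""Ground-truth-annotated synthetic micrograph generation.

Every downstream stage (segmentation, pore morphometry, Voronoi verification,
band-ratio statistics) is exercised on samples produced here, each carrying
the ground truth needed to score the estimate: the true seed points, the
noise-free mask, and the realized per-structure parameter values.

The capsule-surface model is a perturbed hexagonal point process: pore
centres sit on a triangular lattice whose constant is the nominal pore
diameter plus wall thickness, each node jittered isotropically.  Because the
nearest-neighbour spacing of a jittered lattice is the minimum over ~6
neighbours, jitter systematically shrinks realized spacings below the lattice
constant (an extreme-value effect); the generator therefore rescales the
pattern about its centroid so the realized mean nearest-neighbour spacing
equals the nominal spacing exactly.  Walls are the Voronoi edges of the
rescaled sites, dilated to the nominal wall thickness, so horizontal renders
are exact Voronoi tessellations of their true sites by construction.

Defaults reproduce the reported study conditions: pore diameter 95.0 nm
(per-pore SD 22.05 nm, the printed SE x sqrt(n)), pore depth 166.3 nm
(SD 29.55 nm), dense capsule layer 48.2 nm, cell wall 27.9 nm, cell diameter
1.26 +/- 0.236 um, biofilm cell:cavity area ratio 45.3:54.7, and a 2.0 nm/px
calibration so a 95 nm pore spans ~48 px.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk, line as draw_line

from .geometry import Point2D, SeedSet, Segment2D, Tessellation, build_voronoi
from .morphometry import BinaryMask, GrayImage
from .stats import Spectrum

__all__ = [
    "CapsuleParams",
    "RenderParams",
    "SyntheticSample",
    "sample_pore_centers",
    "render_capsule_cross_section",
    "render_biofilm_section",
    "render_cell_surface",
    "perturb_walls",
    "synth_spectrum",
]


class SynthesisError(ValueError):
    """Unsatisfiable generation request."""


@dataclass(frozen=True)
class CapsuleParams:
    """Nominal structural parameters (nm unless noted).

    Per-pore spreads default to printed-SE x sqrt(n): the SE describes the
    mean of n = 25 measurements, the generator needs per-object spread.
    """

    pore_diameter_mean: float = 95.0
    pore_diameter_sd: float = 4.41 * math.sqrt(25)  # 22.05
    pore_depth_mean: float = 166.3
    pore_depth_sd: float = 5.91 * math.sqrt(25)  # 29.55
    wall_thickness: float = 20.0
    capsule_layer_thickness: float = 48.2
    cell_wall_thickness: float = 27.9
    cell_diameter_mean: float = 1.26  # um
    cell_diameter_sd: float = 0.236  # um

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not value > 0:
                raise SynthesisError(f"{name} must be positive, got {value}")
        if self.pore_diameter_sd >= self.pore_diameter_mean:
            raise SynthesisError("pore_diameter_sd must be below the mean")
        if self.pore_depth_sd >= self.pore_depth_mean:
            raise SynthesisError("pore_depth_sd must be below the mean")
        if self.cell_diameter_sd >= self.cell_diameter_mean:
            raise SynthesisError("cell_diameter_sd must be below the mean")

    @property
    def lattice_constant(self) -> float:
        """Nominal centre-to-centre pore spacing (nm)."""
        return self.pore_diameter_mean + self.wall_thickness


@dataclass(frozen=True)
class RenderParams:
    nm_per_px: float = 2.0
    noise_sd: float = 0.05
    blur_sigma: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.nm_per_px > 0:
            raise SynthesisError("nm_per_px must be positive")
        if self.noise_sd < 0 or self.blur_sigma < 0:
            raise SynthesisError("noise_sd and blur_sigma must be >= 0")


@dataclass
class SyntheticSample:
    """Rendered image plus everything needed to score downstream estimates."""

    image: GrayImage
    truth_mask: BinaryMask
    true_sites: SeedSet | None
    params: dict
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.image.shape != self.truth_mask.shape:
            raise SynthesisError("image and truth mask shapes differ")


def _finish_image(
    clean: np.ndarray, render: RenderParams, rng: np.random.Generator
) -> np.ndarray:
    """Blur + additive Gaussian noise + clip to [0, 1]."""
    out = clean
    if render.blur_sigma > 0:
        out = ndi.gaussian_filter(out, render.blur_sigma)
    if render.noise_sd > 0:
        out = out + rng.normal(0.0, render.noise_sd, size=out.shape)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# point process

def sample_pore_centers(
    params: CapsuleParams,
    extent: tuple[float, float],
    rng_seed: int = 0,
    jitter_sd: float | None = None,
    process: str = "hex",
) -> SeedSet:
    """Near-regular pore centres over ``extent = (width_nm, height_nm)``.

    ``process='hex'`` (default): triangular lattice with constant
    ``pore_diameter_mean + wall_thickness``, each node jittered by an
    isotropic Gaussian, then rescaled about the centroid so the realized mean
    nearest-neighbour spacing over the interior equals the nominal lattice
    constant.  The default jitter sd is ``pore_diameter_sd / sqrt(n=25)`` —
    the printed standard error of the gap measurements: the pores are
    described as equally spaced, so positional disorder at the
    measurement-uncertainty scale (not the full per-object spread, which also
    contains measurement error) is the appropriate prior; larger jitter also
    inflates Voronoi-cell inscribed diameters well above the
    spacing-minus-wall value, destroying the nominal pore size.
    ``process='hardcore'``: uniform points with a minimum-separation
    constraint, as an irregular alternative for robustness checks.

    Coordinates are in nm, image convention x right / y = -depth, with bbox
    ``(0, -height, width, 0)``.
    """
    width, height = float(extent[0]), float(extent[1])
    a = params.lattice_constant
    if width < 2 * a or height < 2 * a:
        raise SynthesisError(
            f"extent {extent} too small for >= 3 sites at spacing {a:.1f} nm"
        )
    rng = np.random.default_rng(rng_seed)
    if jitter_sd is None:
        jitter_sd = params.pore_diameter_sd / 5.0  # = printed SE for n = 25

    if process == "hex":
        dy = a * math.sqrt(3) / 2
        rows = int(math.floor(height / dy)) + 2
        cols = int(math.floor(width / a)) + 2
        pts = []
        for r in range(rows):
            x0 = (a / 2) if (r % 2) else 0.0
            for c in range(cols):
                pts.append((x0 + c * a, r * dy))
        pts = np.array(pts, dtype=float)
        if jitter_sd > 0:
            pts += rng.normal(0.0, jitter_sd, size=pts.shape)
            # undo the extreme-value shrinkage of min-over-neighbours spacing;
            # calibrate on interior sites (the outermost ring has fewer
            # neighbours and artificially long spacings)
            d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
            np.fill_diagonal(d2, np.inf)
            nn = np.sqrt(np.min(d2, axis=1))
            interior = (
                (pts[:, 0] >= a) & (pts[:, 0] <= width - a)
                & (pts[:, 1] >= a) & (pts[:, 1] <= height - a)
            )
            mean_nn = float(np.mean(nn[interior])) if interior.any() else float(np.mean(nn))
            centroid = pts.mean(axis=0)
            pts = centroid + (pts - centroid) * (a / mean_nn)
    elif process == "hardcore":
        n_target = max(3, int(round((width / a) * (height / (a * math.sqrt(3) / 2)))))
        min_sep = 0.7 * a
        accepted: list[np.ndarray] = []
        for _ in range(200 * n_target):
            cand = rng.uniform((0, 0), (width, height))
            if all(np.hypot(*(cand - p)) >= min_sep for p in accepted):
                accepted.append(cand)
                if len(accepted) >= n_target:
                    break
        pts = np.array(accepted)
    else:
        raise SynthesisError(f"unknown point process {process!r}")

    keep = (
        (pts[:, 0] >= 0) & (pts[:, 0] <= width)
        & (pts[:, 1] >= 0) & (pts[:, 1] <= height)
    )
    pts = pts[keep]
    if len(pts) < 3:
        raise SynthesisError("fewer than 3 sites fall inside the extent")
    # image convention: downward depth becomes negative Cartesian y
    sites = np.column_stack([pts[:, 0], -pts[:, 1]])
    return SeedSet(sites, bbox=(0.0, -height, width, 0.0))


# ---------------------------------------------------------------------------
# capsule cross-sections

def _rasterize_edges(
    edges: list[Segment2D],
    shape: tuple[int, int],
    nm_per_px: float,
    wall_px: float,
) -> np.ndarray:
    """Draw segments (nm coordinates, y = -row convention) as walls of the
    given pixel thickness.

    Segments are rasterised to a 1-px chain and thickened by thresholding the
    distance transform at half the wall width, which keeps the realized
    thickness within a pixel of nominal (integer-radius dilation would
    truncate it by up to 2 px).
    """
    canvas = np.zeros(shape, dtype=bool)
    h, w = shape
    for seg in edges:
        r0 = int(round(-seg.a.y / nm_per_px))
        c0 = int(round(seg.a.x / nm_per_px))
        r1 = int(round(-seg.b.y / nm_per_px))
        c1 = int(round(seg.b.x / nm_per_px))
        rr, cc = draw_line(r0, c0, r1, c1)
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        canvas[rr[ok], cc[ok]] = True
    dist_to_chain = ndi.distance_transform_edt(~canvas)
    return dist_to_chain <= wall_px / 2.0


def render_capsule_cross_section(
    sites: SeedSet | None,
    params: CapsuleParams,
    render: RenderParams,
    orientation: str = "horizontal",
    extent: tuple[float, float] | None = None,
    n_spines: int = 60,
) -> SyntheticSample:
    """Render a capsule section as a calibrated grayscale image + truth.

    ``orientation='horizontal'`` (plane through the pore layer): walls are the
    Voronoi edges of ``sites`` dilated to ``wall_thickness``; pores are the
    dark cells between them.  The truth record carries per-site
    nearest-neighbour spacings and the implied geometric pore diameters
    (spacing minus wall thickness).

    ``orientation='vertical'`` (section across the layer stack): a periodic
    comb profile — wall spines of Gaussian-drawn depth rising from the dense
    capsule layer, which sits on the cell-wall band.  ``sites`` is unused and
    may be None; the truth record carries the realized (pixel-quantised)
    spine depths in nm.

    Walls/layers are rendered bright on a dark background, then blurred and
    noised per ``render``; ``truth_mask`` is the noise-free wall/layer mask.
    """
    nmpp = render.nm_per_px
    wall_px = params.wall_thickness / nmpp
    if wall_px < 1:
        raise SynthesisError(
            f"wall thickness {params.wall_thickness} nm is below 1 px at "
            f"{nmpp} nm/px; use a finer calibration"
        )
    rng = np.random.default_rng(render.rng_seed)

    if orientation == "horizontal":
        if sites is None:
            raise SynthesisError("horizontal orientation requires seed sites")
        xmin, ymin, xmax, ymax = sites.bbox
        w = int(round((xmax - xmin) / nmpp)) + 1
        h = int(round((ymax - ymin) / nmpp)) + 1
        tess = build_voronoi(sites)
        mask = _rasterize_edges(tess.edge_segments, (h, w), nmpp, wall_px)
        clean = np.where(mask, 0.85, 0.15)
        image = _finish_image(clean, render, rng)
        pts = sites.points
        d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        nn = np.sqrt(np.min(d2, axis=1))
        truth = {
            "nn_spacing_nm": nn.tolist(),
            "geometric_pore_diameters_nm": (nn - params.wall_thickness).tolist(),
        }
        return SyntheticSample(
            image=GrayImage(image, nmpp),
            truth_mask=BinaryMask(mask, nmpp),
            true_sites=sites,
            params={**asdict(params), **asdict(render), "orientation": orientation},
            truth=truth,
        )

    if orientation == "vertical":
        spacing_px = params.lattice_constant / nmpp
        depth_px_nominal = params.pore_depth_mean / nmpp
        cap_px = max(1, int(round(params.capsule_layer_thickness / nmpp)))
        cw_px = max(1, int(round(params.cell_wall_thickness / nmpp)))
        top_margin = int(round(depth_px_nominal)) + 30
        h = top_margin + cap_px + cw_px + 10
        w = int(round(n_spines * spacing_px)) + 1
        mask = np.zeros((h, w), dtype=bool)
        layer_top = top_margin
        mask[layer_top: layer_top + cap_px, :] = True  # dense capsule layer
        mask[layer_top + cap_px: layer_top + cap_px + cw_px, :] = True  # cell wall
        depths = rng.normal(params.pore_depth_mean, params.pore_depth_sd, n_spines)
        depths = np.clip(depths, 10 * nmpp, (top_margin - 2) * nmpp)
        half = max(1, int(round(wall_px / 2)))
        realized = []
        for i in range(n_spines):
            c = int(round((i + 0.5) * spacing_px))
            if c - half < 0 or c + half >= w:
                continue
            d_rows = int(round(depths[i] / nmpp))
            mask[layer_top - d_rows: layer_top, c - half: c + half + 1] = True
            realized.append(d_rows * nmpp)
        clean = np.where(mask, 0.85, 0.15)
        image = _finish_image(clean, render, rng)
        return SyntheticSample(
            image=GrayImage(image, nmpp),
            truth_mask=BinaryMask(mask, nmpp),
            true_sites=None,
            params={**asdict(params), **asdict(render), "orientation": orientation},
            truth={"spine_depths_nm": realized, "layer_top_row": layer_top},
        )

    raise SynthesisError(f"unknown orientation {orientation!r}")


def render_annular_layer(
    params: CapsuleParams,
    render: RenderParams,
    kind: str = "capsule_thickness",
    inner_radius_nm: float | None = None,
    boundary_jitter_px: float = 0.0,
) -> SyntheticSample:
    """Annular layer mask (dense capsule layer or cell wall around a cell).

    The layer is a circular annulus of the nominal thickness; optional
    boundary jitter roughens both rims.  Truth records the nominal thickness.
    """
    nmpp = render.nm_per_px
    thickness = (
        params.capsule_layer_thickness
        if kind == "capsule_thickness"
        else params.cell_wall_thickness
    )
    if inner_radius_nm is None:
        inner_radius_nm = 5.0 * thickness
    r_in = inner_radius_nm / nmpp
    r_out = (inner_radius_nm + thickness) / nmpp
    half = int(math.ceil(r_out)) + 10
    size = 2 * half + 1
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    rr = np.hypot(yy - half, xx - half)
    rng = np.random.default_rng(render.rng_seed)
    if boundary_jitter_px > 0:
        rr = rr + rng.normal(0.0, boundary_jitter_px, size=rr.shape)
    mask = (rr >= r_in) & (rr < r_out)
    clean = np.where(mask, 0.85, 0.15)
    image = _finish_image(clean, render, rng)
    return SyntheticSample(
        image=GrayImage(image, nmpp),
        truth_mask=BinaryMask(mask, nmpp),
        true_sites=None,
        params={**asdict(params), **asdict(render), "kind": kind},
        truth={"thickness_nm": thickness, "center_px": (float(half), float(half))},
    )


# ---------------------------------------------------------------------------
# sponge biofilm sections

def render_biofilm_section(
    target_cell_fraction: float,
    cell_size_px: float,
    extent: tuple[int, int],
    render: RenderParams,
    fraction_tolerance: float = 0.5,
    max_attempts: int = 300_000,
) -> SyntheticSample:
    """Sponge-biofilm section: non-overlapping discs (cells) on a cavity
    background, placed by rejection until the truth foreground fraction is
    within ``fraction_tolerance`` percentage points of the target.

    Candidate centres are drawn from the free region (background pixels whose
    distance to any placed cell exceeds the disc radius plus a 1-px gap), so
    every draw places a cell; radii shrink as free space tightens.  An
    unreachable fraction raises after ``max_attempts`` placements.
    """
    if not 0.0 < target_cell_fraction < 100.0:
        raise SynthesisError("target cell fraction must be in (0, 100)")
    h, w = int(extent[0]), int(extent[1])
    rng = np.random.default_rng(render.rng_seed)
    mask = np.zeros((h, w), dtype=bool)
    total = h * w
    target = target_cell_fraction / 100.0
    tol = fraction_tolerance / 100.0
    radius = cell_size_px / 2.0
    min_radius = 1.5
    attempts = 0
    centers: list[tuple[float, float, float]] = []
    n_fg = 0
    free_dist = np.full((h, w), np.inf)  # distance to nearest cell pixel
    while True:
        if n_fg / total >= target - tol:
            break
        if attempts >= max_attempts:
            raise SynthesisError(
                f"could not reach {target_cell_fraction}% cell area after "
                f"{max_attempts} placements (reached {n_fg / total * 100:.1f}%)"
            )
        attempts += 1
        r = max(min_radius, radius * rng.uniform(0.8, 1.2))
        # never overshoot past the tolerance band
        if (n_fg + math.pi * r * r) / total > target + tol:
            r = max(min_radius, math.sqrt(max(1.0, (target + tol) * total - n_fg) / math.pi) * 0.9)
        allowed_r, allowed_c = np.nonzero(free_dist > r + 1.0)
        margin = (
            (allowed_r >= r) & (allowed_r < h - r)
            & (allowed_c >= r) & (allowed_c < w - r)
        )
        allowed_r, allowed_c = allowed_r[margin], allowed_c[margin]
        if allowed_r.size == 0:
            if radius <= min_radius:
                raise SynthesisError(
                    f"no free space left at {n_fg / total * 100:.1f}% cell "
                    f"area; target {target_cell_fraction}% unreachable with "
                    "non-overlapping cells"
                )
            radius = max(min_radius, radius * 0.8)
            continue
        k = int(rng.integers(allowed_r.size))
        cy, cx = float(allowed_r[k]), float(allowed_c[k])
        rr, cc = draw_disk((cy, cx), r, shape=(h, w))
        n_fg += int(np.count_nonzero(~mask[rr, cc]))
        mask[rr, cc] = True
        centers.append((cy, cx, r))
        free_dist = ndi.distance_transform_edt(~mask)
    clean = np.where(mask, 0.8, 0.2)
    image = _finish_image(clean, render, rng)
    truth_fraction = np.count_nonzero(mask) * 100.0 / total
    return SyntheticSample(
        image=GrayImage(image, render.nm_per_px),
        truth_mask=BinaryMask(mask, render.nm_per_px),
        true_sites=None,
        params={
            **asdict(render),
            "target_cell_fraction": target_cell_fraction,
            "cell_size_px": cell_size_px,
        },
        truth={"cell_fraction_pct": truth_fraction, "n_cells": len(centers)},
    )


# ---------------------------------------------------------------------------
# cell-surface fields

def render_cell_surface(
    params: CapsuleParams,
    n_cells: int,
    extent: tuple[int, int],
    render: RenderParams,
    min_gap_px: float = 4.0,
    max_attempts: int = 20_000,
) -> SyntheticSample:
    """Field of shaded spherical cells with Gaussian-distributed diameters.

    Diameters are drawn from Normal(cell_diameter_mean, cell_diameter_sd) um,
    truncated positive; the full sample of n diameters is drawn up front and
    every drawn cell is then placed (largest first, position rejection only),
    so the realized size distribution is not biased toward small cells by
    packing failures.  The truth record carries the realized diameters in um.
    """
    if n_cells < 1:
        raise SynthesisError("n_cells must be >= 1")
    h, w = int(extent[0]), int(extent[1])
    nmpp = render.nm_per_px
    rng = np.random.default_rng(render.rng_seed)
    diameters: list[float] = []
    while len(diameters) < n_cells:
        d_um = float(rng.normal(params.cell_diameter_mean, params.cell_diameter_sd))
        if d_um > 0.2 * params.cell_diameter_mean:
            diameters.append(d_um)
    diameters_um: list[float] = []
    placed: list[tuple[float, float, float]] = []
    canvas = np.full((h, w), 0.1)
    mask = np.zeros((h, w), dtype=bool)
    attempts = 0
    for d_um in sorted(diameters, reverse=True):
        r_px = d_um * 1000.0 / nmpp / 2.0
        if 2 * r_px + 2 * min_gap_px >= min(h, w):
            raise SynthesisError(
                f"extent {extent} cannot hold a cell of diameter {d_um:.2f} um"
            )
        while True:
            if attempts >= max_attempts:
                raise SynthesisError(
                    f"extent {extent} too crowded for {n_cells} cells "
                    f"(placed {len(placed)})"
                )
            attempts += 1
            cy = rng.uniform(r_px + min_gap_px, h - r_px - min_gap_px)
            cx = rng.uniform(r_px + min_gap_px, w - r_px - min_gap_px)
            if not any(
                np.hypot(cy - y0, cx - x0) < r_px + r0 + min_gap_px
                for y0, x0, r0 in placed
            ):
                break
        yy, xx = np.mgrid[
            max(0, int(cy - r_px) - 1): min(h, int(cy + r_px) + 2),
            max(0, int(cx - r_px) - 1): min(w, int(cx + r_px) + 2),
        ]
        rr = np.hypot(yy - cy, xx - cx)
        inside = rr <= r_px
        # flat-topped spherical shading with a bright limb: secondary-electron
        # images brighten at steep rims (edge effect), which also keeps the
        # thresholded outline at the true boundary
        shade = 0.45 + 0.45 * np.power(
            np.clip(1.0 - (rr / r_px) ** 2, 0.0, 1.0), 0.15
        )
        region = canvas[yy.min(): yy.max() + 1, xx.min(): xx.max() + 1]
        region[inside] = shade[inside]
        mask[yy.min(): yy.max() + 1, xx.min(): xx.max() + 1][inside] = True
        placed.append((cy, cx, r_px))
        diameters_um.append(d_um)
    image = _finish_image(canvas, render, rng)
    return SyntheticSample(
        image=GrayImage(image, nmpp),
        truth_mask=BinaryMask(mask, nmpp),
        true_sites=None,
        params={**asdict(params), **asdict(render), "n_cells": n_cells},
        truth={"cell_diameters_um": diameters_um},
    )


# ---------------------------------------------------------------------------
# traced-wall perturbation

def perturb_walls(
    tess: Tessellation,
    angle_jitter_sd: float = 0.0,
    vertex_jitter_sd: float = 0.0,
    rng_seed: int = 0,
) -> list[Segment2D]:
    """Emulate hand-traced walls: rotate each Voronoi edge about its midpoint
    by Normal(0, angle_jitter_sd) degrees and jitter both endpoints by
    isotropic Gaussian noise of sd ``vertex_jitter_sd`` (coordinate units)."""
    if angle_jitter_sd < 0 or vertex_jitter_sd < 0:
        raise SynthesisError("jitter sds must be >= 0")
    rng = np.random.default_rng(rng_seed)
    out: list[Segment2D] = []
    for seg in tess.edge_segments:
        a = seg.a.as_array()
        b = seg.b.as_array()
        if angle_jitter_sd > 0:
            theta = math.radians(rng.normal(0.0, angle_jitter_sd))
            mid = (a + b) / 2.0
            rot = np.array(
                [[math.cos(theta), -math.sin(theta)],
                 [math.sin(theta), math.cos(theta)]]
            )
            a = mid + rot @ (a - mid)
            b = mid + rot @ (b - mid)
        if vertex_jitter_sd > 0:
            a = a + rng.normal(0.0, vertex_jitter_sd, 2)
            b = b + rng.normal(0.0, vertex_jitter_sd, 2)
        out.append(Segment2D(Point2D(*a), Point2D(*b)))
    return out


# ---------------------------------------------------------------------------
# spectra

def synth_spectrum(
    peaks: list[tuple[float, float, float]],
    wn_range: tuple[float, float] = (400.0, 4000.0),
    step: float = 1.0,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
    kind: str = "absorbance",
) -> Spectrum:
    """Sum of Gaussian peaks ``(center cm^-1, width cm^-1, area)`` on a flat
    baseline, on a descending wavenumber grid (FT-IR convention).

    ``kind='transmittance'`` converts the absorbance-like sum A to T = 10^-A.
    """
    lo, hi = sorted(float(v) for v in wn_range)
    wn = np.arange(hi, lo - step / 2, -step)
    signal = np.zeros_like(wn)
    for center, width, area in peaks:
        if width <= 0:
            raise SynthesisError("peak widths must be positive")
        signal += (
            area / (width * math.sqrt(2 * math.pi))
            * np.exp(-0.5 * ((wn - center) / width) ** 2)
        )
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    if kind == "transmittance":
        values = np.power(10.0, -np.clip(signal, 0.0, None))
    elif kind == "absorbance":
        values = signal
    else:
        raise SynthesisError(f"unknown spectrum kind {kind!r}")
    return Spectrum(wavenumbers=wn, values=values, kind=kind)
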
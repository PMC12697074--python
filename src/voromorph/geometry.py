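"""Planar Voronoi/Delaunay geometry for pore-wall tessellation analysis.

A honeycomb-like capsule surface is modelled as a Voronoi tessellation of
pore-centre seed points: every wall segment separating two pores lies on the
perpendicular bisector of the segment joining their centres, so the wall and
its dual Delaunay edge meet at exactly 90 degrees.  This module builds the
tessellation by per-site half-plane intersection (the defining construction:
cell *i* is the intersection of the half-planes nearer to site *i* than to any
other site), exposes the brute-force nearest-site raster labelling as an
independent oracle, and provides the angle and congruence statistics used to
compare an observed (hand-traced) wall network with the computed ideal.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import MultiLineString, LineString

from .stats import summarize

__all__ = [
    "Point2D",
    "SeedSet",
    "Segment2D",
    "VoronoiCell",
    "Tessellation",
    "AngleReport",
    "CongruenceReport",
    "parse_seed_coordinates",
    "build_voronoi",
    "nearest_site_raster_oracle",
    "duality_angles",
    "wall_vs_delaunay_angles",
    "tessellation_congruence",
]


class GeometryError(ValueError):
    """Invalid geometric input (degenerate, insufficient, or malformed)."""


@dataclass(frozen=True)
class Point2D:
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise GeometryError(f"non-finite coordinate: ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class Segment2D:
    a: Point2D
    b: Point2D

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise GeometryError("degenerate segment: endpoints coincide")

    @property
    def midpoint(self) -> Point2D:
        return Point2D((self.a.x + self.b.x) / 2.0, (self.a.y + self.b.y) / 2.0)

    @property
    def direction(self) -> np.ndarray:
        return np.array([self.b.x - self.a.x, self.b.y - self.a.y], dtype=float)

    @property
    def length(self) -> float:
        return float(np.hypot(self.b.x - self.a.x, self.b.y - self.a.y))


class SeedSet:
    """Ordered set of seed points (pore centres) with labels and bounding box.

    Parameters
    ----------
    points : (n, 2) array-like
        Site coordinates, plain Cartesian (image-derived sources map row r to
        y = -r so both conventions agree).
    labels : sequence of str, optional
        Per-point identifiers, e.g. ``P1``..``P22``.
    bbox : (xmin, ymin, xmax, ymax), optional
        Clip window.  Defaults to the tight box padded by `margin` of each
        span (a degenerate span is padded to a nonzero extent).
    coincident_eps : float, optional
        Minimum allowed pairwise distance; defaults to 1e-9 x bbox diagonal.
    """

    def __init__(
        self,
        points,
        labels: Sequence[str] | None = None,
        bbox: tuple[float, float, float, float] | None = None,
        margin: float = 0.10,
        coincident_eps: float | None = None,
    ) -> None:
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
            raise GeometryError("points must be an (n, 2) array with n >= 1")
        if not np.all(np.isfinite(pts)):
            raise GeometryError("seed coordinates must be finite")
        if labels is not None and len(labels) != len(pts):
            raise GeometryError("labels length must match number of points")
        self.points = pts
        self.labels = list(labels) if labels is not None else None
        if bbox is None:
            xmin, ymin = pts.min(axis=0)
            xmax, ymax = pts.max(axis=0)
            span_x = xmax - xmin
            span_y = ymax - ymin
            # degenerate spans padded to something usable
            pad_x = margin * span_x if span_x > 0 else max(1.0, margin * max(span_y, 1.0))
            pad_y = margin * span_y if span_y > 0 else max(1.0, margin * max(span_x, 1.0))
            bbox = (xmin - pad_x, ymin - pad_y, xmax + pad_x, ymax + pad_y)
        self.bbox = tuple(float(v) for v in bbox)
        if not (self.bbox[0] <= pts[:, 0].min() and pts[:, 0].max() <= self.bbox[2]
                and self.bbox[1] <= pts[:, 1].min() and pts[:, 1].max() <= self.bbox[3]):
            raise GeometryError("all points must lie inside or on the bbox")
        diag = math.hypot(self.bbox[2] - self.bbox[0], self.bbox[3] - self.bbox[1])
        eps = coincident_eps if coincident_eps is not None else 1e-9 * max(diag, 1e-12)
        if len(pts) > 1:
            d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
            np.fill_diagonal(d2, np.inf)
            if np.min(d2) <= eps * eps:
                i, j = np.unravel_index(np.argmin(d2), d2.shape)
                raise GeometryError(f"coincident seed points at indices {i} and {j}")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def bbox_diagonal(self) -> float:
        return math.hypot(self.bbox[2] - self.bbox[0], self.bbox[3] - self.bbox[1])


@dataclass
class VoronoiCell:
    site: Point2D
    polygon: np.ndarray  # (k, 2) CCW vertices, clipped to bbox, not repeated
    area: float


@dataclass
class Tessellation:
    """Voronoi cells plus finite edges, each linked to its dual Delaunay edge.

    ``edges[k]`` is ``(segment, (i, j))``: the wall separating sites i and j;
    ``delaunay_edges[k]`` is the segment joining those two sites.  The lists
    are index-aligned, so edge k is perpendicular to delaunay edge k by
    construction.
    """

    seeds: SeedSet
    cells: list[VoronoiCell]
    edges: list[tuple[Segment2D, tuple[int, int]]]
    delaunay_edges: list[tuple[Segment2D, tuple[int, int]]]

    @property
    def edge_segments(self) -> list[Segment2D]:
        return [seg for seg, _ in self.edges]

    def delaunay_pairs(self) -> set[tuple[int, int]]:
        return {pair for _, pair in self.delaunay_edges}


@dataclass
class AngleReport:
    """Acute intersection angles (degrees, folded into [0, 90]) and summary."""

    angles: np.ndarray
    n_skipped: int = 0
    mean: float = field(init=False)
    sd: float = field(init=False)
    n: int = field(init=False)
    relative_error_vs_90: float = field(init=False)

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.size == 0:
            raise GeometryError("empty angle set")
        if np.any(self.angles < -1e-9) or np.any(self.angles > 90 + 1e-9):
            raise GeometryError("angles must lie in [0, 90] degrees")
        s = summarize(self.angles)
        self.mean = s.mean
        self.sd = s.sd
        self.n = s.n
        self.relative_error_vs_90 = (90.0 - self.mean) / 90.0 * 100.0

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_deg": self.mean,
            "sd_deg": self.sd,
            "relative_error_vs_90_pct": self.relative_error_vs_90,
            "n_skipped": self.n_skipped,
        }


@dataclass
class CongruenceReport:
    mean_symmetric_distance: float
    max_distance: float
    matched_fraction: float

    def to_dict(self) -> dict:
        return {
            "mean_symmetric_distance": self.mean_symmetric_distance,
            "max_distance": self.max_distance,
            "matched_fraction": self.matched_fraction,
        }


# ---------------------------------------------------------------------------
# parsing

_COORD_RE = re.compile(
    r"(?P<label>[A-Za-z]\w*)\s*=\s*\(\s*(?P<x>[-−+]?[\d.eE+−-]+)\s*,\s*(?P<y>[-−+]?[\d.eE+−-]+)\s*\)"
)


def _to_float(token: str, line_no: int) -> float:
    try:
        return float(token.replace("−", "-"))  # Unicode minus
    except ValueError as exc:
        raise GeometryError(f"malformed number {token!r} on line {line_no}") from exc


def parse_seed_coordinates(text: str, margin: float = 0.10) -> SeedSet:
    """Parse a seed listing into a :class:`SeedSet`.

    Two formats are accepted:

    * free text with ``P1 = (209.57, -7.127)``-style entries (any number per
      line; the Unicode minus sign is handled);
    * CSV with header ``label,x,y``.

    Input order is preserved; duplicate labels or coincident points are
    rejected; the bbox is the tight box padded by ``margin`` of each span.
    """
    lines = text.splitlines()
    labels: list[str] = []
    pts: list[tuple[float, float]] = []
    first = next((ln for ln in lines if ln.strip()), "")
    if first.strip().lower().replace(" ", "") == "label,x,y":
        started = False
        for no, ln in enumerate(lines, start=1):
            if not ln.strip():
                continue
            if not started:
                started = True  # header
                continue
            parts = [p.strip() for p in ln.split(",")]
            if len(parts) != 3 or not parts[0]:
                raise GeometryError(f"malformed CSV record on line {no}: {ln!r}")
            labels.append(parts[0])
            pts.append((_to_float(parts[1], no), _to_float(parts[2], no)))
    else:
        for no, ln in enumerate(lines, start=1):
            stripped = ln.strip()
            if not stripped:
                continue
            matches = list(_COORD_RE.finditer(ln))
            if not matches:
                # a line with content but no parseable record is an error
                if re.search(r"[=(]", stripped):
                    raise GeometryError(f"malformed coordinate record on line {no}: {ln!r}")
                continue
            for m in matches:
                labels.append(m.group("label"))
                pts.append((_to_float(m.group("x"), no), _to_float(m.group("y"), no)))
    if not pts:
        raise GeometryError("no coordinate records found")
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise GeometryError(f"duplicate labels: {dupes}")
    return SeedSet(np.array(pts), labels=labels, margin=margin)


# ---------------------------------------------------------------------------
# half-plane Voronoi construction

def _bbox_polygon(bbox: tuple[float, float, float, float]) -> np.ndarray:
    xmin, ymin, xmax, ymax = bbox
    return np.array(
        [[xmin, ymin], [xmax, ymin], [xmax, ymax], [xmin, ymax]], dtype=float
    )


def _clip_halfplane(poly: np.ndarray, a: np.ndarray, b: float) -> np.ndarray:
    """Sutherland-Hodgman clip of convex `poly` against {q : a.q <= b}."""
    if len(poly) == 0:
        return poly
    vals = poly @ a - b
    out: list[np.ndarray] = []
    n = len(poly)
    for i in range(n):
        p, q = poly[i], poly[(i + 1) % n]
        vp, vq = vals[i], vals[(i + 1) % n]
        if vp <= 0:
            out.append(p)
            if vq > 0:  # leaving
                t = vp / (vp - vq)
                out.append(p + t * (q - p))
        elif vq <= 0:  # entering
            t = vp / (vp - vq)
            out.append(p + t * (q - p))
    return np.array(out) if out else np.empty((0, 2))


def _polygon_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _collinear(pts: np.ndarray, tol: float) -> bool:
    c = pts - pts.mean(axis=0)
    # smallest singular value ~ spread off the best-fit line
    s = np.linalg.svd(c, compute_uv=False)
    return s[-1] <= tol * max(s[0], 1e-300)


def build_voronoi(seeds: SeedSet) -> Tessellation:
    """Construct the bbox-clipped Voronoi tessellation by half-plane intersection.

    Each cell is computed as the intersection of the bounding box with all
    half-planes ``{q : |q - p_i| <= |q - p_j|}`` — the literal
    distance-minimisation definition.  Finite Voronoi edges are identified
    from the cell polygons (an edge whose midpoint is equidistant to its two
    nearest sites separates those sites), and each is linked to its dual
    Delaunay edge joining the site pair.

    Two sites are accepted as a documented special case (the single bisector
    edge clipped to the bbox); otherwise at least 3 non-collinear sites are
    required.
    """
    pts = seeds.points
    n = len(pts)
    if n < 2:
        raise GeometryError("Voronoi construction needs at least 2 sites (>= 3 for a triangulation)")
    if n >= 3 and _collinear(pts, 1e-12):
        raise GeometryError("all sites are collinear: degenerate configuration")

    diag = seeds.bbox_diagonal
    zero_len = 1e-9 * diag
    box = _bbox_polygon(seeds.bbox)

    cells: list[VoronoiCell] = []
    for i in range(n):
        poly = box
        pi = pts[i]
        d2 = np.sum((pts - pi) ** 2, axis=1)
        # clip against nearer sites first: shrinks the polygon fastest, and
        # once every vertex is nearer to the site than half the distance to
        # the next candidate, no remaining bisector can cut the cell
        rmax = float(np.max(np.sqrt(np.sum((poly - pi) ** 2, axis=1))))
        for j in np.argsort(d2):
            if j == i or len(poly) == 0:
                continue
            if 0.5 * math.sqrt(d2[j]) >= rmax:
                break
            pj = pts[j]
            a = pj - pi
            b = 0.5 * (pj @ pj - pi @ pi)
            new_poly = _clip_halfplane(poly, a, b)
            if len(new_poly) != len(poly) or not np.array_equal(new_poly, poly):
                poly = new_poly
                if len(poly):
                    rmax = float(np.max(np.sqrt(np.sum((poly - pi) ** 2, axis=1))))
        if len(poly) < 3:
            raise GeometryError(f"cell of site {i} degenerated to zero area")
        area = _polygon_area(poly)
        cells.append(VoronoiCell(Point2D(*pi), poly, area))

    # identify Voronoi edges from cell boundaries: an edge midpoint equidistant
    # (within tolerance) to sites i and j separates those sites
    tol = 1e-6 * diag
    edge_map: dict[tuple[int, int], Segment2D] = {}
    for i, cell in enumerate(cells):
        poly = cell.polygon
        m = len(poly)
        for k in range(m):
            v1, v2 = poly[k], poly[(k + 1) % m]
            if np.hypot(*(v2 - v1)) < zero_len:
                continue
            mid = 0.5 * (v1 + v2)
            d = np.sqrt(np.sum((pts - mid) ** 2, axis=1))
            order = np.argsort(d)
            j = order[0] if order[0] != i else order[1]
            if abs(d[i] - d[j]) > tol:
                continue  # bbox boundary edge
            pair = (min(i, int(j)), max(i, int(j)))
            if pair not in edge_map:
                edge_map[pair] = Segment2D(Point2D(*v1), Point2D(*v2))

    edges = [(seg, pair) for pair, seg in sorted(edge_map.items())]
    delaunay_edges = [
        (Segment2D(Point2D(*pts[i]), Point2D(*pts[j])), (i, j)) for _, (i, j) in edges
    ]
    return Tessellation(seeds=seeds, cells=cells, edges=edges, delaunay_edges=delaunay_edges)


# ---------------------------------------------------------------------------
# raster oracle

def nearest_site_raster_oracle(
    seeds: SeedSet, resolution: float, tie_eps: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Brute-force nearest-site labelling of a regular grid over the bbox.

    Returns ``(xs, ys, labels)`` where ``labels[iy, ix]`` is the argmin-distance
    site index for grid centre ``(xs[ix], ys[iy])``, or -1 where the two nearest
    sites are within ``tie_eps`` of equidistant (boundary cells).

    This is the independent oracle for :func:`build_voronoi`: it evaluates the
    distance-minimisation definition directly, point by point.
    """
    if resolution <= 0:
        raise GeometryError("resolution must be positive")
    xmin, ymin, xmax, ymax = seeds.bbox
    if tie_eps is None:
        tie_eps = 1e-7 * seeds.bbox_diagonal
    xs = np.arange(xmin + resolution / 2, xmax, resolution)
    ys = np.arange(ymin + resolution / 2, ymax, resolution)
    gx, gy = np.meshgrid(xs, ys)
    q = np.stack([gx.ravel(), gy.ravel()], axis=1)
    d = np.sqrt(((q[:, None, :] - seeds.points[None, :, :]) ** 2).sum(axis=-1))
    labels = np.argmin(d, axis=1)
    if len(seeds) > 1:
        part = np.partition(d, 1, axis=1)
        ties = (part[:, 1] - part[:, 0]) <= tie_eps
        labels = np.where(ties, -1, labels)
    return xs, ys, labels.reshape(len(ys), len(xs))


# ---------------------------------------------------------------------------
# angles

def acute_angle_deg(u, v) -> float:
    """Acute angle in [0, 90] degrees between two undirected directions."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.hypot(*u), np.hypot(*v)
    if nu == 0 or nv == 0:
        raise GeometryError("zero-length direction vector")
    c = abs(float(u @ v)) / (nu * nv)
    return math.degrees(math.acos(min(1.0, c)))


def duality_angles(tess: Tessellation) -> AngleReport:
    """Angle between every finite Voronoi edge and its dual Delaunay edge.

    For an exact Voronoi tessellation each wall lies on the perpendicular
    bisector of its dual edge, so every angle is 90 degrees up to floating
    tolerance; this operation verifies that property.
    """
    if not tess.edges:
        raise GeometryError("tessellation has no finite Voronoi edges")
    angles = [
        acute_angle_deg(seg.direction, dual.direction)
        for (seg, _), (dual, _) in zip(tess.edges, tess.delaunay_edges)
    ]
    return AngleReport(np.array(angles))


def wall_vs_delaunay_angles(
    walls: Iterable[Segment2D], seeds: SeedSet
) -> AngleReport:
    """Measure observed wall segments against the Delaunay edges they separate.

    Each wall segment is assigned to the two sites nearest its midpoint (the
    wall separating two pores is tested against the line joining those pores);
    segments whose site pair is not a Delaunay edge are skipped and counted in
    ``n_skipped``.  Angles are folded acute, in [0, 90] degrees.
    """
    walls = list(walls)
    if not walls:
        raise GeometryError("empty wall set")
    tess = build_voronoi(seeds)
    pairs = tess.delaunay_pairs()
    pts = seeds.points
    angles: list[float] = []
    skipped = 0
    for seg in walls:
        mid = seg.midpoint.as_array()
        d2 = np.sum((pts - mid) ** 2, axis=1)
        order = np.argsort(d2)
        i, j = int(order[0]), int(order[1])
        pair = (min(i, j), max(i, j))
        if pair not in pairs:
            skipped += 1
            continue
        angles.append(acute_angle_deg(seg.direction, pts[j] - pts[i]))
    if not angles:
        raise GeometryError("no wall segment could be assigned to a Delaunay edge")
    return AngleReport(np.array(angles), n_skipped=skipped)


# ---------------------------------------------------------------------------
# congruence

def _sample_along(segments: Sequence[Segment2D], step: float) -> np.ndarray:
    pts = []
    for seg in segments:
        k = max(2, int(math.ceil(seg.length / step)) + 1)
        t = np.linspace(0.0, 1.0, k)
        a, b = seg.a.as_array(), seg.b.as_array()
        pts.append(a[None, :] + t[:, None] * (b - a)[None, :])
    return np.concatenate(pts, axis=0)


def _to_multiline(segments: Sequence[Segment2D]) -> MultiLineString:
    return MultiLineString(
        [LineString([(s.a.x, s.a.y), (s.b.x, s.b.y)]) for s in segments]
    )


def tessellation_congruence(
    observed: Sequence[Segment2D],
    computed: Tessellation,
    tolerance: float,
    sampling_step: float | None = None,
) -> CongruenceReport:
    """Score how well an observed wall network overlays the computed diagram.

    Points are sampled densely along both edge sets; the symmetric
    point-to-nearest-edge distance gives the mean and max discrepancy, and
    ``matched_fraction`` is the share of observed edge length lying within
    ``tolerance`` of the computed diagram.  Comparing a diagram against itself
    yields (0, 0, 1.0).
    """
    observed = list(observed)
    comp_edges = computed.edge_segments
    if not observed or not comp_edges:
        raise GeometryError("both edge sets must be nonempty")
    if tolerance <= 0:
        raise GeometryError("tolerance must be positive")
    if sampling_step is None:
        sampling_step = computed.seeds.bbox_diagonal / 500.0

    obs_pts = _sample_along(observed, sampling_step)
    comp_pts = _sample_along(comp_edges, sampling_step)
    obs_ml = _to_multiline(observed)
    comp_ml = _to_multiline(comp_edges)

    d_obs = shapely.distance(shapely.points(obs_pts), comp_ml)
    d_comp = shapely.distance(shapely.points(comp_pts), obs_ml)
    all_d = np.concatenate([d_obs, d_comp])
    matched = float(np.mean(d_obs <= tolerance))
    return CongruenceReport(
        mean_symmetric_distance=float(np.mean(all_d)),
        max_distance=float(np.max(all_d)),
        matched_fraction=matched,
    )
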
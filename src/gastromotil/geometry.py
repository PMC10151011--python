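"""Stomach wall geometry: wall-point resampling and centerline estimation.

The stomach border in a (semi-)coronal slice is described by two open
polylines, the lesser (inner) and greater (outer) curvature.  Each curvature
is resampled to 200 points at equal arc length ("wall-points"), wall-points
with equal index are paired across the two curvatures, and the midpoint of
each pair is a candidate centerline point ("middle-point").  A middle-point
is *valid* when a circle centred on it, with diameter 90% of the pair
distance, fits entirely inside the closed stomach outline — this rejects
midpoints near the sharply curved ends where the naive pairing cuts across
the wall.  Valid middle-points pooled over all frames are summarised by a
single 5th-order polynomial, the time-independent centerline used as the
reference axis for all contraction measurements.

Coordinates are physical millimetres, image convention (x = column,
y = row, origin top-left).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from shapely.geometry import Point, Polygon

__all__ = [
    "Curvature",
    "CurvaturePair",
    "WallPoints",
    "MiddlePointSet",
    "Centerline",
    "resample_curvature",
    "build_outline",
    "validate_middle_point",
    "candidate_middle_points",
    "fit_centerline",
]

N_WALL_POINTS = 200


@dataclass
class Curvature:
    """An ordered open polyline along one stomach curvature.

    Parameters
    ----------
    label : {"lesser", "greater"}
    vertices : (N, 2) array of (x, y) positions in mm.
    distal_end : {"first", "last"}
        Which end of the vertex list is the distal (pyloric) end.  All
        arc-length fractions downstream run distal (s=0) to proximal (s=1).
    """

    label: str
    vertices: np.ndarray
    distal_end: str = "first"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (N, 2) array")
        if self.label not in ("lesser", "greater"):
            raise ValueError(f"unknown curvature label {self.label!r}")
        if self.distal_end not in ("first", "last"):
            raise ValueError("distal_end must be 'first' or 'last'")

    @property
    def oriented_vertices(self) -> np.ndarray:
        """Vertices ordered distal → proximal."""
        if self.distal_end == "last":
            return self.vertices[::-1]
        return self.vertices

    def arc_length(self) -> float:
        seg = np.diff(self.vertices, axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())


@dataclass
class CurvaturePair:
    """Lesser and greater curvature of one frame (or the baseline shape)."""

    lesser: Curvature
    greater: Curvature

    def swapped(self) -> "CurvaturePair":
        les = Curvature("lesser", self.greater.vertices.copy(), self.greater.distal_end)
        grt = Curvature("greater", self.lesser.vertices.copy(), self.lesser.distal_end)
        return CurvaturePair(lesser=les, greater=grt)


@dataclass
class WallPoints:
    """Equal-arc-length sample of one curvature.

    ``points[n]`` sits at arc-length fraction ``fractions[n]`` from the
    distal end; ``fractions`` is always ``linspace(0, 1, n_points)``.
    """

    label: str
    points: np.ndarray          # (n, 2) mm
    fractions: np.ndarray       # (n,)
    length_mm: float

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass
class MiddlePointSet:
    """Candidate middle-points of one frame with inscribed-circle validity."""

    points: np.ndarray          # (n, 2) midpoint of each wall-point pair, mm
    pair_distance: np.ndarray   # (n,) mm
    radius: np.ndarray          # (n,) = 0.45 * pair_distance, mm
    valid: np.ndarray           # (n,) bool

    @property
    def valid_points(self) -> np.ndarray:
        return self.points[self.valid]


@dataclass
class Centerline:
    """Time-pooled polynomial stomach axis.

    The polynomial is fitted in the principal-axis frame of the pooled
    middle-point cloud (minor coordinate as a 5th-order polynomial of the
    major coordinate) and then discretised to ``n`` points at equal arc
    length, ordered distal → proximal like the wall-points.
    """

    points: np.ndarray              # (n, 2) mm, equal arc-length spacing
    fractions: np.ndarray           # (n,)
    length_mm: float
    coefficients: np.ndarray        # polynomial coefs (ascending) in PCA frame
    rotation: np.ndarray            # (2, 2): PCA frame -> world
    origin: np.ndarray              # (2,) mm, cloud centroid
    domain: tuple = field(default=(0.0, 1.0))  # major-coordinate fit window


def _dedupe(vertices: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Collapse consecutive duplicate vertices."""
    keep = np.ones(len(vertices), dtype=bool)
    d = np.hypot(*(np.diff(vertices, axis=0).T))
    keep[1:] = d > tol
    return vertices[keep]


def resample_curvature(curvature: Curvature, n_points: int = N_WALL_POINTS,
                       dense: int = 20000) -> WallPoints:
    """Resample a curvature to ``n_points`` wall-points at equal arc length.

    A natural cubic spline parameterised by cumulative chord length is fitted
    through the vertices; arc length is integrated on a dense sample of the
    spline and inverted so the returned points are equally spaced along the
    curve, running distal (fraction 0) to proximal (fraction 1).
    """
    verts = _dedupe(curvature.oriented_vertices)
    if len(verts) < 4:
        raise ValueError(
            f"curvature {curvature.label!r} has fewer than 4 distinct vertices")
    chord = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(verts, axis=0).T))])
    spline = CubicSpline(chord, verts, axis=0, bc_type="natural")
    u = np.linspace(0.0, chord[-1], dense)
    xy = spline(u)
    seg = np.hypot(*np.diff(xy, axis=0).T)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    if total <= 0:
        raise ValueError("curvature has zero arc length")
    targets = np.linspace(0.0, total, n_points)
    u_at = np.interp(targets, arclen, u)
    points = spline(u_at)
    return WallPoints(label=curvature.label, points=points,
                      fractions=np.linspace(0.0, 1.0, n_points),
                      length_mm=total)


def build_outline(lesser: WallPoints, greater: WallPoints) -> Polygon:
    """Closed stomach outline: greater wall joined to the reversed lesser wall."""
    ring = np.vstack([greater.points, lesser.points[::-1]])
    poly = Polygon(ring)
    if not poly.is_valid:
        raise ValueError("stomach outline polygon is not simple (self-intersects)")
    return poly


def validate_middle_point(center, radius: float, outline: Polygon) -> bool:
    """True iff the full circle of ``radius`` about ``center`` lies inside ``outline``.

    Equivalent to: the centre is interior and its distance to the outline
    boundary is at least the radius.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    p = Point(float(center[0]), float(center[1]))
    return bool(outline.contains(p) and outline.boundary.distance(p) >= radius)


def candidate_middle_points(lesser: WallPoints, greater: WallPoints,
                            outline: Polygon | None = None) -> MiddlePointSet:
    """Pair wall-points by index and test each midpoint's inscribed circle.

    The circle diameter is 90% of the pair distance (radius ``0.45 * d``).
    The terminal midpoints (most distal and most proximal pair) are always
    kept valid so the fitted axis spans the whole organ.
    """
    if lesser.n_points != greater.n_points:
        raise ValueError("lesser and greater wall-point counts differ")
    if outline is None:
        outline = build_outline(lesser, greater)
    elif not outline.is_valid:
        raise ValueError("stomach outline polygon is not simple (self-intersects)")
    mids = 0.5 * (lesser.points + greater.points)
    dist = np.hypot(*(greater.points - lesser.points).T)
    radius = 0.45 * dist
    valid = np.zeros(len(mids), dtype=bool)
    for i in range(len(mids)):
        valid[i] = validate_middle_point(mids[i], radius[i], outline) if radius[i] > 0 else False
    valid[0] = True
    valid[-1] = True
    return MiddlePointSet(points=mids, pair_distance=dist, radius=radius, valid=valid)


def fit_centerline(middle_point_sets, n_points: int = N_WALL_POINTS,
                   degree: int = 5, dense: int = 200000) -> Centerline:
    """Fit the pooled 5th-order polynomial centerline.

    Parameters
    ----------
    middle_point_sets : MiddlePointSet or sequence of MiddlePointSet
        Per-frame candidates; valid points of every frame enter the fit with
        equal weight, yielding a single time-independent axis.
    n_points : number of equally spaced points to discretise the axis to.
    degree : polynomial order (5 by default).

    Notes
    -----
    The fit is performed in the principal-axis frame of the pooled cloud
    (PCA), regressing the minor coordinate on the major one, so vertically
    oriented organs are handled identically to horizontal ones.  The
    returned points are evaluated exactly on the fitted polynomial at
    parameters chosen by dense arc-length inversion.
    """
    if isinstance(middle_point_sets, MiddlePointSet):
        middle_point_sets = [middle_point_sets]
    clouds = [mps.valid_points for mps in middle_point_sets]
    pts = np.vstack([c for c in clouds if len(c)]) if clouds else np.empty((0, 2))
    if len(pts) < degree + 1 or len(pts) < 6:
        raise ValueError("not enough valid middle-points to fit a centerline")
    origin = pts.mean(axis=0)
    centered = pts - origin
    # principal axes of the cloud
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    pca = vt.T  # columns: major, minor direction (world <- frame is rot @ [a, b])
    # regression frame: the PCA frame is the robust default, but when the
    # cloud is exactly polynomial in an image axis the axis-aligned frame
    # reproduces it to machine precision while the rotated quintic cannot;
    # pick the frame with the smallest fit residual (ties favour PCA).
    candidates = [np.array([[1.0, 0.0], [0.0, 1.0]]),
                  np.array([[0.0, 1.0], [1.0, 0.0]]),
                  pca]
    best = None
    for rot in candidates:
        ab = centered @ rot
        a, b = ab[:, 0], ab[:, 1]
        span = a.max() - a.min()
        if span <= 1e-6 or len(np.unique(np.round(a, 9))) <= degree:
            continue
        cf = np.polynomial.polynomial.polyfit(a, b, deg=degree)
        resid = np.abs(b - np.polynomial.polynomial.polyval(a, cf)).max()
        if best is None or resid < best[0] * (1.0 - 1e-12):
            best = (resid, rot, a, b, cf)
    if best is None:
        raise ValueError("middle-point cloud has degenerate span along its major axis")
    _, rot, a, b, coeffs = best
    a_dense = np.linspace(a.min(), a.max(), dense)
    b_dense = np.polynomial.polynomial.polyval(a_dense, coeffs)
    xy_dense = np.column_stack([a_dense, b_dense])
    seg = np.hypot(*np.diff(xy_dense, axis=0).T)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = float(arclen[-1])
    targets = np.linspace(0.0, total, n_points)
    a_at = np.interp(targets, arclen, a_dense)
    b_at = np.polynomial.polynomial.polyval(a_at, coeffs)
    pca_pts = np.column_stack([a_at, b_at])
    world = pca_pts @ rot.T + origin
    # orientation: keep distal -> proximal order consistent with the wall-point
    # convention; callers that know the organ orientation may flip via
    # ``oriented_like``.
    return Centerline(points=world, fractions=np.linspace(0.0, 1.0, n_points),
                      length_mm=total, coefficients=coeffs, rotation=rot,
                      origin=origin, domain=(float(a.min()), float(a.max())))


def orient_centerline(centerline: Centerline, reference_point) -> Centerline:
    """Flip the centerline in place-order so it starts nearest ``reference_point``.

    Wall-points run distal → proximal; the polynomial fit has no intrinsic
    direction, so the caller supplies a point near the distal end (e.g. the
    first wall-point of either curvature).
    """
    ref = np.asarray(reference_point, dtype=float)
    d_first = np.hypot(*(centerline.points[0] - ref))
    d_last = np.hypot(*(centerline.points[-1] - ref))
    if d_last < d_first:
        centerline = Centerline(
            points=centerline.points[::-1].copy(),
            fractions=centerline.fractions.copy(),
            length_mm=centerline.length_mm,
            coefficients=centerline.coefficients,
            rotation=centerline.rotation,
            origin=centerline.origin,
            domain=centerline.domain,
        )
    return centerline
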
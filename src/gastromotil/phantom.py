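"""Synthetic gastric-motility phantom.

Generates dynamic 2-D image series with analytic ground truth, emulating the
features of free-breathing gastric MRI that the pipeline measures:

* a curved tubular "stomach" (circular-arc or straight medial axis, constant
  or tapered lumen radius) whose two banks play the lesser (inner) and
  greater (outer) curvature;
* a train of circumferential peristaltic indentations — Gaussian bumps in
  wall arc length — travelling toward the distal (pyloric) end at a fixed
  speed and spawn frequency;
* cyclic planar rigid "breathing" motion (sinusoidal translation and
  rotation about the image centre) applied identically to the lumen and to
  four off-lumen landmarks, with every transform recorded as ground truth;
* anti-aliased rasterisation (area sampling via supersampling) so sub-pixel
  wall motion is visible in the intensities, plus seeded Gaussian noise.

The default configuration matches the study conditions the pipeline was
built for: 100 frames at 0.65 s, 1 mm pixels, wall arc lengths of 200 mm
(lesser) and 286 mm (greater), ~3 cycles/min waves travelling at 3 mm/s with
5 mm indentation depth.  Everything is a pure function of the configuration,
including its seed.

Peristaltic crests are parameterised by each wall's own arc length measured
from the distal end and travel at ``wave_speed_mm_s`` in that arc length, so
the configured speed is exactly the quantity the per-curvature speed metric
estimates.  Intensity contrast is synthetic; no MR signal physics and no
through-plane motion are modelled.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
from PIL import Image, ImageDraw

from .geometry import Curvature, CurvaturePair
from .registration import LandmarkSet, RigidTransform
from .series import ImageSeries

__all__ = ["PhantomConfig", "PhantomOutput", "generate_baseline_shape",
           "apply_peristalsis", "apply_breathing", "render_series",
           "crest_positions"]


@dataclass
class PhantomConfig:
    """All parameters of the synthetic phantom.

    Attributes
    ----------
    frames, frame_interval_s : temporal sampling; the series must span at
        least two wave periods (2 * 60 / wave_frequency_cpm).
    pixel_size_mm, image_shape : spatial sampling; image_shape is (rows, cols).
    tube_length_mm : arc length of the medial axis.
    tube_radius_mm : lumen radius; a scalar, a (distal, proximal) pair for a
        linear taper, or a callable of axial arc length (mm).
    centerline_kind : "arc" (circular arc of radius ``arc_radius_mm``) or
        "line" (straight axis).
    wave_frequency_cpm : crest spawn rate in cycles per minute.
    wave_speed_mm_s : crest speed along each wall's arc length.
    wave_amplitude_mm : maximum inward indentation; must stay below the
        minimum lumen radius so the lumen never self-intersects.
    wave_width_mm : Gaussian sigma of the indentation along the wall.
    breathing_amplitude : (dx_mm, dy_mm, degrees) sinusoidal rigid motion.
    breathing_period_s : breathing cycle length.
    noise_sigma : additive Gaussian intensity noise per pixel.
    lumen_intensity, background_intensity : synthetic contrast levels
        (bright lumen mimics the juice-filled stomach).
    seed : RNG seed; a fixed seed yields bit-identical output.
    """

    frames: int = 100
    frame_interval_s: float = 0.65
    pixel_size_mm: float = 1.0
    image_shape: tuple = (272, 144)
    tube_length_mm: float = 243.0
    tube_radius_mm: object = 20.0
    centerline_kind: str = "arc"
    arc_radius_mm: float = 113.0
    wave_frequency_cpm: float = 3.0
    wave_speed_mm_s: float = 3.0
    wave_amplitude_mm: float = 5.0
    wave_width_mm: float = 6.0
    breathing_amplitude: tuple = (2.0, 10.0, 2.0)
    breathing_period_s: float = 4.0
    noise_sigma: float = 2.0
    lumen_intensity: float = 100.0
    background_intensity: float = 20.0
    landmark_intensity: float = 80.0
    seed: int = 0
    n_contour_vertices: int = 400
    supersample: int = 8
    landmark_fractions: tuple = ((0.08, 0.12), (0.92, 0.10),
                                 (0.06, 0.88), (0.90, 0.85))

    def radius_at(self, u) -> np.ndarray:
        """Lumen radius (mm) at axial arc length ``u`` (mm from distal end)."""
        u = np.asarray(u, dtype=float)
        r = self.tube_radius_mm
        if callable(r):
            return np.asarray(r(u), dtype=float)
        if np.isscalar(r):
            return np.full_like(u, float(r))
        r0, r1 = r
        return r0 + (r1 - r0) * u / self.tube_length_mm

    def min_radius(self) -> float:
        u = np.linspace(0.0, self.tube_length_mm, 512)
        return float(self.radius_at(u).min())

    @property
    def duration_s(self) -> float:
        return self.frames * self.frame_interval_s

    @property
    def wave_period_s(self) -> float:
        return 60.0 / self.wave_frequency_cpm

    def validate(self) -> None:
        if self.frames < 1 or self.frame_interval_s <= 0 or self.pixel_size_mm <= 0:
            raise ValueError("frames, frame_interval_s, pixel_size_mm must be positive")
        if self.tube_length_mm <= 0:
            raise ValueError("tube_length_mm must be positive")
        if self.min_radius() <= 0:
            raise ValueError("degenerate geometry: tube radius must be positive everywhere")
        if self.wave_amplitude_mm < 0 or self.wave_width_mm <= 0:
            raise ValueError("wave amplitude must be >= 0 and width > 0")
        if self.wave_amplitude_mm >= self.min_radius():
            raise ValueError("wave_amplitude_mm must be smaller than the minimum "
                             "tube radius (lumen would self-intersect)")
        if self.wave_frequency_cpm <= 0 or self.wave_speed_mm_s <= 0:
            raise ValueError("wave frequency and speed must be positive")
        if self.wave_amplitude_mm > 0 and self.duration_s < 2.0 * self.wave_period_s:
            raise ValueError(
                f"series duration {self.duration_s:.1f}s must cover at least two "
                f"wave periods (2 x {self.wave_period_s:.1f}s)")
        if self.centerline_kind not in ("arc", "line"):
            raise ValueError("centerline_kind must be 'arc' or 'line'")
        if self.centerline_kind == "arc" and self.arc_radius_mm <= self.min_radius():
            raise ValueError("arc radius must exceed the tube radius")
        if self.breathing_period_s <= 0:
            raise ValueError("breathing_period_s must be positive")

    @classmethod
    def test_scale(cls, **overrides) -> "PhantomConfig":
        """A reduced phantom (shorter tube, fewer frames) for fast runs."""
        base = dict(frames=50, image_shape=(152, 80), tube_length_mm=120.0,
                    tube_radius_mm=12.0, arc_radius_mm=60.0,
                    wave_frequency_cpm=4.0, wave_amplitude_mm=4.0,
                    breathing_amplitude=(1.0, 4.0, 1.0))
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        d = asdict(self)
        if callable(d["tube_radius_mm"]):
            d["tube_radius_mm"] = "<callable>"
        return d


@dataclass
class PhantomOutput:
    """Everything the phantom knows about itself.

    ``contours_still`` are the per-frame lumen contours before breathing
    (peristalsis only); ``contours`` are after breathing and correspond to
    the rendered images.  ``transforms`` map frame-1 geometry to frame t, so
    their inverses are what a perfect motion correction should recover.
    """

    images: ImageSeries
    contours_still: list
    contours: list
    transforms: list
    landmarks: LandmarkSet
    config: PhantomConfig


def _image_center_px(config: PhantomConfig) -> np.ndarray:
    h, w = config.image_shape
    return np.array([(w - 1) / 2.0, (h - 1) / 2.0])


def generate_baseline_shape(config: PhantomConfig) -> CurvaturePair:
    """Resting lumen geometry: both walls as offset curves of the medial axis.

    Walls are sampled on a shared axial grid (``n_contour_vertices`` points,
    distal end first) and translated so the shape is centred in the image.
    For an arc axis the greater curvature is the outer bank and is strictly
    longer than the lesser; for a straight axis the walls are parallel.
    """
    config.validate()
    n = config.n_contour_vertices
    u = np.linspace(0.0, config.tube_length_mm, n)
    r = config.radius_at(u)
    if config.centerline_kind == "arc":
        big_r = config.arc_radius_mm
        phi = config.tube_length_mm / big_r
        alpha = -phi / 2.0 + u / big_r
        radial = np.column_stack([np.cos(alpha), np.sin(alpha)])
        axis = big_r * radial
        outward = radial                       # away from the arc centre
    else:
        axis = np.column_stack([u, np.zeros_like(u)])
        outward = np.tile([0.0, 1.0], (n, 1))
    greater = axis + r[:, None] * outward
    lesser = axis - r[:, None] * outward
    # centre the shape on the image
    allpts = np.vstack([greater, lesser])
    bbox_center = 0.5 * (allpts.min(axis=0) + allpts.max(axis=0))
    shift = _image_center_px(config) * config.pixel_size_mm - bbox_center
    return CurvaturePair(
        lesser=Curvature("lesser", lesser + shift, distal_end="first"),
        greater=Curvature("greater", greater + shift, distal_end="first"),
    )


def crest_positions(config: PhantomConfig, t: float, wall_length: float) -> np.ndarray:
    """Arc-length positions (mm from the distal end) of all crests near a wall.

    Crest k sits at ``u_k(t) = k * wavelength - wave_speed * t`` with
    wavelength = speed * period; positions decrease with time (waves travel
    toward the pylorus at s = 0).  Crests within 4 sigma of the wall are
    returned.
    """
    lam = config.wave_speed_mm_s * config.wave_period_s
    pad = 4.0 * config.wave_width_mm
    lo = (-pad + config.wave_speed_mm_s * t) / lam
    hi = (wall_length + pad + config.wave_speed_mm_s * t) / lam
    ks = np.arange(math.floor(lo), math.ceil(hi) + 1)
    pos = ks * lam - config.wave_speed_mm_s * t
    return pos[(pos >= -pad) & (pos <= wall_length + pad)]


def _arc_positions(vertices: np.ndarray) -> np.ndarray:
    seg = np.hypot(*np.diff(vertices, axis=0).T)
    return np.concatenate([[0.0], np.cumsum(seg)])


def apply_peristalsis(shape: CurvaturePair, config: PhantomConfig, t: float) -> CurvaturePair:
    """Indent both walls with the travelling Gaussian wave train at time ``t``.

    Each wall vertex is displaced toward the local axis (the midpoint of the
    paired vertices of the resting shape) by
    ``amplitude * sum_k exp(-(u - u_k(t))^2 / (2 sigma^2))`` where ``u`` is
    the vertex's arc length from the distal end of its own wall.  The summed
    bump field is clipped at 1 so the displacement never exceeds the
    amplitude.
    """
    if t < -1e-12 or t > config.duration_s + 1e-12:
        raise ValueError("t outside the series duration")
    if config.wave_amplitude_mm == 0.0:
        return CurvaturePair(
            lesser=Curvature("lesser", shape.lesser.vertices.copy(),
                             shape.lesser.distal_end),
            greater=Curvature("greater", shape.greater.vertices.copy(),
                              shape.greater.distal_end),
        )
    les = shape.lesser.oriented_vertices
    grt = shape.greater.oriented_vertices
    if len(les) != len(grt):
        raise ValueError("walls must share the vertex grid for peristalsis")
    mid = 0.5 * (les + grt)
    out = []
    for wall in (les, grt):
        u = _arc_positions(wall)
        bump = np.zeros(len(wall))
        for uk in crest_positions(config, t, u[-1]):
            bump += np.exp(-((u - uk) ** 2) / (2.0 * config.wave_width_mm ** 2))
        np.clip(bump, 0.0, 1.0, out=bump)
        inward = mid - wall
        norm = np.hypot(*inward.T)
        inward = inward / norm[:, None]
        out.append(wall + config.wave_amplitude_mm * bump[:, None] * inward)
    return CurvaturePair(
        lesser=Curvature("lesser", out[0], distal_end="first"),
        greater=Curvature("greater", out[1], distal_end="first"),
    )


def breathing_transform(config: PhantomConfig, t: float) -> RigidTransform:
    """Rigid breathing motion at time ``t``: amplitude * sin(2 pi t / period).

    The sine phase convention means t = 0 (and every half period) is the
    rest position, and the positive crest occurs at a quarter period.
    Rotation is about the image centre; dx/dy are returned in pixels.
    """
    ax_mm, ay_mm, adeg = config.breathing_amplitude
    phase = math.sin(2.0 * math.pi * t / config.breathing_period_s)
    cx, cy = _image_center_px(config)
    return RigidTransform(
        dx=ax_mm * phase / config.pixel_size_mm,
        dy=ay_mm * phase / config.pixel_size_mm,
        theta=math.radians(adeg) * phase,
        center=(float(cx), float(cy)),
    )


def apply_breathing(shape: CurvaturePair, config: PhantomConfig, t: float):
    """Apply the breathing transform to a contour pair; returns (moved, transform).

    The same transform moves landmarks (rigid co-motion); contour coordinates
    are mapped analytically — pixels are only resampled when rendering.
    """
    if t < -1e-12 or t > config.duration_s + 1e-12:
        raise ValueError("t outside the series duration")
    tr = breathing_transform(config, t)
    ps = config.pixel_size_mm

    def move(curv: Curvature) -> Curvature:
        moved_px = tr.apply_points(curv.vertices / ps)
        return Curvature(curv.label, moved_px * ps, curv.distal_end)

    return CurvaturePair(lesser=move(shape.lesser), greater=move(shape.greater)), tr


def _lumen_polygon_px(pair: CurvaturePair, pixel_size: float) -> np.ndarray:
    grt = pair.greater.oriented_vertices / pixel_size
    les = pair.lesser.oriented_vertices / pixel_size
    return np.vstack([grt, les[::-1]])


def _rasterize_lumen(poly_px: np.ndarray, config: PhantomConfig) -> np.ndarray:
    """Area-sampled polygon fill: supersampled scanline fill, block-averaged."""
    h, w = config.image_shape
    ss = config.supersample
    fine = (poly_px + 0.5) * ss - 0.5
    img = Image.new("L", (w * ss, h * ss), 0)
    ImageDraw.Draw(img).polygon([(float(x), float(y)) for x, y in fine], fill=1)
    mask = np.asarray(img, dtype=np.float64)
    frac = mask.reshape(h, ss, w, ss).mean(axis=(1, 3))
    return config.background_intensity + frac * (
        config.lumen_intensity - config.background_intensity)


def _add_landmark_blobs(image: np.ndarray, landmarks_px: np.ndarray,
                        amplitude: float, sigma_px: float = 1.5) -> None:
    h, w = image.shape
    half = int(math.ceil(4 * sigma_px))
    for x, y in landmarks_px:
        c0, c1 = max(0, int(x) - half), min(w, int(x) + half + 1)
        r0, r1 = max(0, int(y) - half), min(h, int(y) + half + 1)
        if c0 >= c1 or r0 >= r1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        image[r0:r1, c0:c1] += amplitude * np.exp(
            -((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * sigma_px ** 2))


def _base_landmarks_px(config: PhantomConfig, baseline: CurvaturePair) -> np.ndarray:
    h, w = config.image_shape
    pts = np.array([(fx * (w - 1), fy * (h - 1))
                    for fx, fy in config.landmark_fractions])
    from shapely.geometry import Point, Polygon
    lumen = Polygon(_lumen_polygon_px(baseline, config.pixel_size_mm))
    for x, y in pts:
        if lumen.distance(Point(x, y)) < 5.0:
            raise ValueError(
                "landmark position falls on or too close to the lumen; adjust "
                "landmark_fractions or the image shape")
    return pts


def contour_series(config: PhantomConfig) -> list:
    """Per-frame ground-truth contours without rasterisation or breathing.

    The contours-only path of the phantom: peristalsis applied to the
    resting shape at every frame time.  This is the input the geometry /
    contraction / metrics stages consume after a perfect motion correction,
    and is much cheaper than rendering images.
    """
    config.validate()
    baseline = generate_baseline_shape(config)
    return [apply_peristalsis(baseline, config, i * config.frame_interval_s)
            for i in range(config.frames)]


def render_series(config: PhantomConfig) -> PhantomOutput:
    """Rasterise the full dynamic series with ground truth.

    Frame t (0-based) is rendered at time t * frame_interval_s: peristalsis
    deforms the resting shape, breathing moves the deformed shape and the
    landmarks rigidly, the lumen polygon is area-sampled onto the pixel
    grid, landmark blobs are stamped on the background, and seeded Gaussian
    noise is added.  Raises if the breathing excursion pushes the lumen
    outside the image.
    """
    config.validate()
    baseline = generate_baseline_shape(config)
    lm_base = _base_landmarks_px(config, baseline)
    h, w = config.image_shape
    rng = np.random.default_rng(config.seed)
    frames = np.empty((config.frames, h, w), dtype=np.float64)
    contours_still, contours, transforms, lms = [], [], [], []
    for i in range(config.frames):
        t = i * config.frame_interval_s
        wavy = apply_peristalsis(baseline, config, t)
        moved, tr = apply_breathing(wavy, config, t)
        poly_px = _lumen_polygon_px(moved, config.pixel_size_mm)
        if (poly_px[:, 0].min() < 1 or poly_px[:, 0].max() > w - 2
                or poly_px[:, 1].min() < 1 or poly_px[:, 1].max() > h - 2):
            raise ValueError(
                f"frame {i}: lumen geometry exceeds the image bounds "
                f"(x {poly_px[:, 0].min():.1f}..{poly_px[:, 0].max():.1f}, "
                f"y {poly_px[:, 1].min():.1f}..{poly_px[:, 1].max():.1f} px in "
                f"a {w}x{h} image); enlarge image_shape or reduce motion")
        img = _rasterize_lumen(poly_px, config)
        lm_t = tr.apply_points(lm_base)
        _add_landmark_blobs(img, lm_t, config.landmark_intensity)
        if config.noise_sigma > 0:
            img = img + rng.normal(0.0, config.noise_sigma, size=img.shape)
        frames[i] = img
        contours_still.append(wavy)
        contours.append(moved)
        transforms.append(tr)
        lms.append(lm_t)
    images = ImageSeries(frames, config.pixel_size_mm, config.frame_interval_s)
    return PhantomOutput(images=images, contours_still=contours_still,
                         contours=contours, transforms=transforms,
                         landmarks=LandmarkSet(np.array(lms)), config=config)
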
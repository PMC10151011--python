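"""Contraction quantification: radial distances, contraction maps.

For each curvature, the distance from wall-point n at frame t to centerline
point n is Dc(n, t).  The reference radius is the unconditional time mean

    reference(n) = (1/T) * sum_t Dc(n, t)

and the contraction size and percentage occlusion follow as

    size(n, t)      = reference(n) - Dc(n, t)        (positive = inward)
    occlusion(n, t) = 100 * size(n, t) / reference(n)

Because the reference includes contracted frames, size slightly
under-states the true indentation depth (by the amplitude times the
fraction of time a wave occupies the site); this is a property of the
definition, not corrected here.  The per-point time mean of size is exactly
zero — the module's strongest self-check.

Maps are arranged time (rows) by normalized curvature length (columns) and
rendered as greyscale rasters, darker = stronger contraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .geometry import Centerline, WallPoints

__all__ = ["RadialDistanceField", "ContractionMap", "radial_distances",
           "reference_radius", "contraction_size", "occlusion",
           "compute_contraction_map", "render_map", "render_map_figure"]


@dataclass
class RadialDistanceField:
    """Dc(n, t) as a (T, n) array for one curvature (mm)."""

    label: str
    values: np.ndarray       # (T, n)
    times: np.ndarray        # (T,) s
    fractions: np.ndarray    # (n,)


@dataclass
class ContractionMap:
    """Reference radius, contraction size and occlusion for one curvature."""

    label: str
    reference: np.ndarray    # (n,) mm
    size: np.ndarray         # (T, n) mm
    occlusion: np.ndarray    # (T, n) percent
    times: np.ndarray        # (T,) s
    fractions: np.ndarray    # (n,)

    @property
    def frame_interval_s(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 1.0


def radial_distances(walls, centerline: Centerline,
                     times=None) -> RadialDistanceField:
    """Distances from per-frame wall-points to the index-paired centerline point.

    ``walls`` is a sequence of :class:`WallPoints` (one per frame, same
    curvature); the centerline is the fixed time-pooled axis.  Wall-point n
    corresponds to centerline point n — both sets are equal-arc-length
    samples of the same organ, so index pairing is the stated structure.
    """
    walls = list(walls)
    if not walls:
        raise ValueError("no frames supplied")
    n = walls[0].n_points
    if len(centerline.points) != n:
        raise ValueError("wall-point count must equal centerline point count")
    vals = np.empty((len(walls), n))
    for t, wp in enumerate(walls):
        if wp.n_points != n:
            raise ValueError(f"frame {t}: wall-point count mismatch")
        vals[t] = np.hypot(*(wp.points - centerline.points).T)
    if (vals <= 1e-9).any():
        raise ValueError("zero wall-to-centerline distance: segmentation "
                         "crosses the reference axis")
    if times is None:
        times = np.arange(len(walls), dtype=float)
    return RadialDistanceField(label=walls[0].label, values=vals,
                               times=np.asarray(times, dtype=float),
                               fractions=walls[0].fractions)


def reference_radius(field: RadialDistanceField) -> np.ndarray:
    """Per-point time-mean radius: reference(n) = mean_t Dc(n, t)."""
    return field.values.mean(axis=0)


def contraction_size(field: RadialDistanceField, reference: np.ndarray) -> np.ndarray:
    """size(n, t) = reference(n) - Dc(n, t); positive = inward contraction."""
    return reference[None, :] - field.values


def occlusion(size: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """occlusion(n, t) = 100 * size(n, t) / reference(n)."""
    if (np.asarray(reference) <= 0).any():
        raise ValueError("reference radius must be positive")
    return 100.0 * size / np.asarray(reference)[None, :]


def compute_contraction_map(field: RadialDistanceField) -> ContractionMap:
    """Assemble reference, size and occlusion into one map object."""
    ref = reference_radius(field)
    size = contraction_size(field, ref)
    occ = occlusion(size, ref)
    return ContractionMap(label=field.label, reference=ref, size=size,
                          occlusion=occ, times=field.times,
                          fractions=field.fractions)


def render_map(cmap: ContractionMap, path, component: str = "size",
               percentile: float = 99.0, scale: int = 3) -> np.ndarray:
    """Write the map as a deterministic greyscale PNG; returns the uint8 raster.

    Grey levels are symmetric about zero at the given percentile of
    |values| (so maps are comparable across subjects): 0 maps to mid-grey,
    strong contraction to black, strong distension to white.  Rows are time
    (downward), columns normalized curvature length; each cell is drawn as a
    ``scale`` x ``scale`` block.
    """
    vals = cmap.size if component == "size" else cmap.occlusion
    vmax = np.percentile(np.abs(vals), percentile)
    if vmax == 0:
        vmax = 1.0
    norm = np.clip(vals / vmax, -1.0, 1.0)
    grey = np.round(127.5 * (1.0 - norm)).astype(np.uint8)
    grey = np.kron(grey, np.ones((scale, scale), dtype=np.uint8))
    if path is not None:
        Image.fromarray(grey, mode="L").save(path, format="PNG")
    return grey


def render_map_figure(cmap: ContractionMap, path, component: str = "size",
                      grid=None, tracks=None, percentile: float = 99.0) -> None:
    """Annotated matplotlib rendering with optional region grid and wave tracks.

    ``grid`` draws the 20 region boundaries and shades the excluded end
    regions; ``tracks`` overlays marked-and-interpolated wave trajectories.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = cmap.size if component == "size" else cmap.occlusion
    vmax = np.percentile(np.abs(vals), percentile) or 1.0
    fig, ax = plt.subplots(figsize=(6, 5))
    extent = [0.0, 1.0, cmap.times[-1], cmap.times[0]]
    ax.imshow(vals, cmap="gray_r", vmin=-vmax, vmax=vmax, aspect="auto",
              extent=extent, interpolation="nearest")
    if grid is not None:
        for e in grid.edges[1:-1]:
            ax.axvline(e, color="tab:blue", lw=0.6)
        w = grid.edges[1] - grid.edges[0]
        ax.axvspan(0.0, w, color="red", alpha=0.15, lw=0)
        ax.axvspan(1.0 - w, 1.0, color="red", alpha=0.15, lw=0)
    if tracks is not None:
        for tr in tracks:
            s = np.linspace(tr.s.min(), tr.s.max(), 100)
            ax.plot(s, tr.time_at(s), color="red", lw=1.0)
            ax.plot(tr.s, tr.t, "r.", ms=3)
    ax.set_xlabel("normalized curvature length (distal → proximal)")
    ax.set_ylabel("time (s)")
    unit = "mm" if component == "size" else "%"
    ax.set_title(f"{cmap.label} curvature contraction {component} ({unit})")
    fig.tight_layout()
    fig.savefig(path, dpi=120, metadata={"Software": "gastromotil"})
    plt.close(fig)
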
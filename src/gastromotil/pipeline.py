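"""High-level pipeline: contour stacks in, regional motility metrics out.

Glues the geometry, contraction and metrics modules together the way the
CLI (and the acceptance runs) use them:

    contour pairs per frame
      -> wall-point resampling (200 per curvature per frame)
      -> pooled inscribed-circle middle-points -> 5th-order centerline
      -> per-curvature contraction maps
      -> wave tracks (manual CSV or automatic ridge marker)
      -> per-region speed / frequency / size / occlusion and GMI
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geometry, metrics
from .contraction import ContractionMap, compute_contraction_map, radial_distances
from .geometry import Centerline


@dataclass
class MapResult:
    """Output of :func:`extract_maps`."""

    centerline: Centerline
    maps: dict                 # label -> ContractionMap
    wall_lengths: dict         # label -> mean curvature length (mm)
    middle_points: list        # per-frame MiddlePointSet


def extract_maps(pairs, frame_interval_s: float,
                 n_points: int = geometry.N_WALL_POINTS) -> MapResult:
    """Resample contours, fit the pooled centerline, build contraction maps.

    ``pairs`` is a sequence of per-frame :class:`CurvaturePair` (already
    motion-corrected).  Frames whose segmentation fails the geometric
    invariants are dropped from the pooled centerline fit with a warning
    rather than aborting the run.
    """
    import warnings

    walls = {"lesser": [], "greater": []}
    mid_sets = []
    for t, pair in enumerate(pairs):
        les = geometry.resample_curvature(pair.lesser, n_points)
        grt = geometry.resample_curvature(pair.greater, n_points)
        walls["lesser"].append(les)
        walls["greater"].append(grt)
        try:
            mid_sets.append(geometry.candidate_middle_points(les, grt))
        except ValueError as exc:
            warnings.warn(f"frame {t} excluded from centerline fit: {exc}",
                          stacklevel=2)
    centerline = geometry.fit_centerline(mid_sets, n_points=n_points)
    centerline = geometry.orient_centerline(
        centerline, walls["lesser"][0].points[0])
    times = np.arange(len(pairs)) * frame_interval_s
    maps = {}
    lengths = {}
    for label, stack in walls.items():
        field = radial_distances(stack, centerline, times=times)
        maps[label] = compute_contraction_map(field)
        lengths[label] = float(np.mean([w.length_mm for w in stack]))
    return MapResult(centerline=centerline, maps=maps, wall_lengths=lengths,
                     middle_points=mid_sets)


def analyze_maps(result: MapResult, tracks: dict | None = None,
                 reduction: str = "peak") -> tuple:
    """Regional metric table and GMI summary for both curvatures.

    ``tracks`` maps curvature label to a list of :class:`WaveTrack`; when
    omitted, the automatic ridge marker is run on each map.
    Returns ``(region_metrics, gmi_table, tracks)``.
    """
    used = {}
    frames = []
    for label, cmap in sorted(result.maps.items()):
        trs = tracks.get(label) if tracks else None
        if trs is None:
            trs = metrics.auto_mark_waves(cmap)
        used[label] = trs
        grid = metrics.RegionGrid(result.wall_lengths[label])
        frames.append(metrics.compute_region_metrics(cmap, trs, grid,
                                                     reduction=reduction))
    region_df = pd.concat(frames, ignore_index=True)
    gmi_df = metrics.gmi(region_df)
    return region_df, gmi_df, used
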
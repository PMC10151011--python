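"""Regional motility metrics from contraction maps and wave tracks.

A contraction wave appears on the map as a dark band; it is tracked by
marking points (s, t) along it — normalized curvature position and time —
and interpolating them into a crossing-time function t(s).  The map is
divided into 20 contiguous regions along s; the first and last are excluded
from analysis (boundary effects at the sharply curved organ ends), leaving
18 analyzed regions.

Per region the pipeline reports:

* speed = region_width / (t2 - t1), where region_width is the mean
  curvature length divided by 20 and t1, t2 are the track's times at the
  region boundaries (only for regions fully traversed by the track);
* frequency = 60 / mean time gap between consecutive waves crossing the
  region centre (cycles/min; needs >= 2 waves);
* contraction size and occlusion: per wave, the peak value attained along
  its track within the region, averaged over waves;
* GMI = (mean region speed) x (mean region size), in mm^2/s, for
  proximal/distal halves of each curvature and overall.

Marks normally come from a human reading of the map (CSV input); an
automatic ridge-following marker is provided so phantoms can be scored
without one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator, interp1d
from scipy.signal import find_peaks

from .contraction import ContractionMap

__all__ = ["WaveTrack", "RegionGrid", "interpolate_track", "region_speed",
           "region_frequency", "region_contraction_stats",
           "compute_region_metrics", "gmi", "auto_mark_waves",
           "peak_contraction_size"]

N_REGIONS = 20


@dataclass
class WaveTrack:
    """One marked contraction wave: crossing time as a function of position."""

    wave_id: int
    s: np.ndarray            # mark positions, normalized [0, 1], strictly increasing
    t: np.ndarray            # mark times, s
    label: str = ""
    _interp: object = field(default=None, repr=False)

    @property
    def span(self) -> tuple:
        return float(self.s[0]), float(self.s[-1])

    @property
    def direction(self) -> int:
        """+1 if time increases with s (proximal-ward), -1 if distal-ward."""
        return 1 if self.t[-1] >= self.t[0] else -1

    def time_at(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        lo, hi = self.span
        if (s < lo - 1e-9).any() or (s > hi + 1e-9).any():
            raise ValueError("position outside the track's marked span "
                             "(no extrapolation beyond marks)")
        return self._interp(np.clip(s, lo, hi))


def interpolate_track(marks_s, marks_t, wave_id: int = 0,
                      label: str = "") -> WaveTrack:
    """Build a wave track from marks by monotone piecewise-cubic interpolation.

    Marks must be strictly monotone in s.  The interpolant (PCHIP) passes
    through every mark exactly and is monotone between marks.  If the mark
    times are not monotone along the propagation direction, a warning is
    issued and a piecewise-linear interpolant is used instead.
    """
    s = np.asarray(marks_s, dtype=float)
    t = np.asarray(marks_t, dtype=float)
    if s.ndim != 1 or s.shape != t.shape or len(s) < 2:
        raise ValueError("need >= 2 (s, t) marks")
    order = np.argsort(s)
    s, t = s[order], t[order]
    if (np.diff(s) <= 0).any():
        raise ValueError("mark positions must be strictly monotone in s")
    dt = np.diff(t)
    monotone = (dt >= 0).all() or (dt <= 0).all()
    if monotone:
        interp = PchipInterpolator(s, t)
    else:
        warnings.warn("mark times not monotone along the wave; falling back "
                      "to piecewise-linear interpolation", stacklevel=2)
        interp = interp1d(s, t, kind="linear")
    return WaveTrack(wave_id=wave_id, s=s, t=t, label=label, _interp=interp)


@dataclass
class RegionGrid:
    """20 contiguous regions over s in [0, 1]; regions 2..19 are analyzed.

    Region numbering is 1-based from the distal end (s = 0).
    ``region_width_mm`` is the mean curvature length divided by the region
    count — the distance Eq-6 assigns to one region crossing.
    """

    curvature_length_mm: float
    n_regions: int = N_REGIONS

    def __post_init__(self):
        if self.curvature_length_mm <= 0 or self.n_regions < 3:
            raise ValueError("invalid region grid")

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_regions + 1)

    @property
    def region_width_mm(self) -> float:
        return self.curvature_length_mm / self.n_regions

    @property
    def analyzed(self) -> list:
        return list(range(2, self.n_regions))

    def bounds(self, region: int) -> tuple:
        e = self.edges
        return float(e[region - 1]), float(e[region])

    def center(self, region: int) -> float:
        lo, hi = self.bounds(region)
        return 0.5 * (lo + hi)


def region_speed(track: WaveTrack, grid: RegionGrid) -> dict:
    """Wave speed (mm/s) per analyzed region fully traversed by the track.

    speed = region_width / |t2 - t1| with t1, t2 the interpolated crossing
    times of the two region boundaries.  Regions only partially covered by
    the marked span give no estimate; coincident boundary times are an
    error (degenerate marks imply infinite speed).
    """
    lo, hi = track.span
    out = {}
    for region in grid.analyzed:
        a, b = grid.bounds(region)
        if a < lo - 1e-12 or b > hi + 1e-12:
            continue
        t1, t2 = float(track.time_at(a)), float(track.time_at(b))
        if t1 == t2:
            raise ValueError(f"region {region}: identical boundary crossing "
                             "times (degenerate marks)")
        out[region] = grid.region_width_mm / abs(t2 - t1)
    return out


def region_frequency(tracks, grid: RegionGrid) -> dict:
    """Contraction frequency (cycles/min) per analyzed region.

    At each region centre, the crossing times of all tracks covering that
    position are collected; frequency = 60 / mean gap between consecutive
    crossings.  Regions crossed by fewer than two waves report NaN
    (missing), never zero.
    """
    out = {}
    for region in grid.analyzed:
        sc = grid.center(region)
        times = []
        for tr in tracks:
            lo, hi = tr.span
            if lo - 1e-12 <= sc <= hi + 1e-12:
                times.append(float(tr.time_at(sc)))
        if len(times) < 2:
            out[region] = float("nan")
            continue
        gaps = np.diff(np.sort(times))
        out[region] = 60.0 / gaps.mean()
    return out


def region_contraction_stats(cmap: ContractionMap, tracks, grid: RegionGrid,
                             reduction: str = "peak") -> dict:
    """Per-region contraction size (mm) and occlusion (%) along the tracks.

    reduction="peak" (default): for each wave, the peak value the map
    attains along the track inside the region, averaged over waves.
    reduction="mean_positive": time-mean of positive map values over the
    region, ignoring tracks.
    """
    out = {}
    for region in grid.analyzed:
        a, b = grid.bounds(region)
        if reduction == "mean_positive":
            cols = (cmap.fractions >= a) & (cmap.fractions <= b)
            sz = cmap.size[:, cols]
            oc = cmap.occlusion[:, cols]
            pos = sz > 0
            out[region] = (float(sz[pos].mean()) if pos.any() else 0.0,
                           float(oc[pos].mean()) if pos.any() else 0.0)
            continue
        peaks_sz, peaks_oc = [], []
        for tr in tracks:
            lo, hi = tr.span
            s0, s1 = max(a, lo), min(b, hi)
            cols = np.nonzero((cmap.fractions >= s0) & (cmap.fractions <= s1))[0]
            if len(cols) == 0:
                continue
            tt = np.clip(tr.time_at(cmap.fractions[cols]),
                         cmap.times[0], cmap.times[-1])
            sz = [np.interp(tt[i], cmap.times, cmap.size[:, c])
                  for i, c in enumerate(cols)]
            oc = [np.interp(tt[i], cmap.times, cmap.occlusion[:, c])
                  for i, c in enumerate(cols)]
            peaks_sz.append(max(sz))
            peaks_oc.append(max(oc))
        if peaks_sz:
            out[region] = (float(np.mean(peaks_sz)), float(np.mean(peaks_oc)))
        else:
            out[region] = (float("nan"), float("nan"))
    return out


def compute_region_metrics(cmap: ContractionMap, tracks, grid: RegionGrid,
                           reduction: str = "peak") -> pd.DataFrame:
    """Full per-region metric table for one curvature.

    Columns: curvature, region, speed (mm/s, mean over waves crossing the
    region), size (mm), occlusion (%), frequency (cycles/min), n_waves.
    """
    speed_lists: dict = {r: [] for r in grid.analyzed}
    for tr in tracks:
        for region, v in region_speed(tr, grid).items():
            speed_lists[region].append(v)
    freq = region_frequency(tracks, grid)
    stats = region_contraction_stats(cmap, tracks, grid, reduction=reduction)
    rows = []
    for region in grid.analyzed:
        sv = speed_lists[region]
        rows.append({
            "curvature": cmap.label,
            "region": region,
            "speed_mm_s": float(np.mean(sv)) if sv else float("nan"),
            "size_mm": stats[region][0],
            "occlusion_pct": stats[region][1],
            "frequency_cpm": freq[region],
            "n_waves": len(sv),
        })
    return pd.DataFrame(rows)


def gmi(region_metrics: pd.DataFrame) -> pd.DataFrame:
    """Gastric motility index per region group: mean speed x mean size.

    Groups are the distal (regions 2-10) and proximal (regions 11-19)
    halves of the analyzed regions for each curvature, plus the overall
    pool.  Empty groups yield NaN with a warning.
    """
    df = region_metrics
    half = (df["region"].max() + df["region"].min()) / 2.0
    rows = []

    def summarize(name, sub):
        sp = sub["speed_mm_s"].dropna()
        sz = sub["size_mm"].dropna()
        if len(sp) == 0 or len(sz) == 0:
            warnings.warn(f"GMI group {name!r} has no estimates", stacklevel=2)
            ms = msz = g = float("nan")
        else:
            ms, msz = float(sp.mean()), float(sz.mean())
            g = ms * msz
        rows.append({"group": name, "mean_speed_mm_s": ms,
                     "mean_size_mm": msz, "gmi_mm2_s": g})

    for curv in sorted(df["curvature"].unique()):
        cdf = df[df["curvature"] == curv]
        summarize(f"{curv}_distal", cdf[cdf["region"] <= half])
        summarize(f"{curv}_proximal", cdf[cdf["region"] > half])
    summarize("overall", df)
    return pd.DataFrame(rows)


def peak_contraction_size(cmap: ContractionMap, mode: str = "peak") -> float:
    """Whole-map estimate of the indentation depth (mm).

    mode="peak": maximum contraction size anywhere on the map.  Because the
    time-mean reference radius already includes contracted frames, this
    under-states the true depth by depth x (wave occupancy of the site).
    mode="peak_to_trough": maximum over stations of (max_t - min_t) of the
    size trace; the distension floor at a station equals minus the same
    occupancy bias, so the peak-to-trough amplitude cancels it.
    """
    if mode == "peak":
        return float(cmap.size.max())
    if mode == "peak_to_trough":
        return float((cmap.size.max(axis=0) - cmap.size.min(axis=0)).max())
    raise ValueError(f"unknown mode {mode!r}")


def _refine_peak_time(trace: np.ndarray, idx: int, times: np.ndarray) -> float:
    """Sub-frame peak time via 3-point parabolic interpolation."""
    if idx <= 0 or idx >= len(trace) - 1:
        return float(times[idx])
    y0, y1, y2 = trace[idx - 1], trace[idx], trace[idx + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(times[idx])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    dt = times[1] - times[0]
    return float(times[idx] + delta * dt)


def auto_mark_waves(cmap: ContractionMap, threshold_frac: float = 0.5,
                    n_marks: int = 10, min_span: float = 0.25,
                    min_points: int = 10, max_gap: int = 8) -> list:
    """Automatic ridge-following wave marker for phantom self-tests.

    Per station, contraction-size peaks above ``threshold_frac`` of the map
    maximum are detected (with parabolic sub-frame timing); walking stations
    from the proximal end toward the distal end, each peak either extends
    the nearest active wave (predicted by short linear extrapolation of the
    wave's recent course) or seeds a new one.  Waves spanning at least
    ``min_span`` of the curvature with ``min_points`` stations are
    down-sampled to ``n_marks`` marks and interpolated like manual tracks.
    """
    size = cmap.size
    times = cmap.times
    n_stations = size.shape[1]
    thr = threshold_frac * size.max()
    if thr <= 0:
        return []
    dt = cmap.frame_interval_s
    station_peaks = []
    all_gaps = []
    for n in range(n_stations):
        trace = size[:, n]
        idx, _ = find_peaks(trace, height=thr)
        pk = [_refine_peak_time(trace, i, times) for i in idx]
        station_peaks.append(pk)
        if len(pk) > 1:
            all_gaps.extend(np.diff(pk))
    period_est = float(np.median(all_gaps)) if all_gaps else 4.0 * dt

    active = []   # dicts: points [(station, t)], last_station
    done = []
    for n in range(n_stations - 1, -1, -1):
        peaks = list(station_peaks[n])
        claimed = [False] * len(peaks)
        # candidate matches sorted by time mismatch
        cands = []
        for wi, w in enumerate(active):
            pts = w["points"]
            if len(pts) >= 3:
                sub = pts[-5:]
                ns = np.array([p[0] for p in sub], dtype=float)
                ts = np.array([p[1] for p in sub], dtype=float)
                slope = np.polyfit(ns, ts, 1)[0]
                t_pred = ts[-1] + slope * (n - ns[-1])
                tol = max(3.0 * dt, 0.15 * period_est)
            else:
                t_pred = pts[-1][1]
                tol = 0.35 * period_est
            for pi, pt in enumerate(peaks):
                if abs(pt - t_pred) <= tol:
                    cands.append((abs(pt - t_pred), wi, pi))
        used_w = set()
        for _, wi, pi in sorted(cands):
            if wi in used_w or claimed[pi]:
                continue
            active[wi]["points"].append((n, peaks[pi]))
            active[wi]["last"] = n
            used_w.add(wi)
            claimed[pi] = True
        for pi, pt in enumerate(peaks):
            if not claimed[pi]:
                active.append({"points": [(n, pt)], "last": n})
        still = []
        for w in active:
            if w["last"] - n > max_gap:
                done.append(w)
            else:
                still.append(w)
        active = still
    done.extend(active)

    tracks = []
    wid = 0
    for w in done:
        pts = sorted(w["points"])  # ascending station
        if len(pts) < min_points:
            continue
        s_vals = cmap.fractions[[p[0] for p in pts]]
        if s_vals[-1] - s_vals[0] < min_span:
            continue
        sel = np.unique(np.round(np.linspace(0, len(pts) - 1, n_marks)).astype(int))
        marks_s = s_vals[sel]
        marks_t = np.array([pts[i][1] for i in sel])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tracks.append(interpolate_track(marks_s, marks_t, wave_id=wid,
                                            label=cmap.label))
        wid += 1
    tracks.sort(key=lambda tr: tr.t[0])
    for i, tr in enumerate(tracks):
        tr.wave_id = i
    return tracks
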
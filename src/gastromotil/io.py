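"""Readers and writers for the pipeline's on-disk formats.

Images travel as multi-page TIFF (optionally NIfTI); everything else is
plain CSV/JSON/YAML.  Coordinate convention throughout: image origin
top-left, x = column, y = row, 0-based; physical mm = pixel * pixel_size.
Contour CSVs store vertices ordered distal → proximal.
"""

from __future__ import annotations

import json
import pathlib

import numpy as np
import pandas as pd
import tifffile
import yaml

from .geometry import Centerline, Curvature, CurvaturePair
from .registration import LandmarkSet, RigidTransform
from .series import ImageSeries


# --- images ---------------------------------------------------------------

def write_tiff(series: ImageSeries, path) -> None:
    tifffile.imwrite(str(path), series.data.astype(np.float32),
                     metadata={"pixel_size_mm": series.pixel_size_mm,
                               "frame_interval_s": series.frame_interval_s})


def read_tiff(path, pixel_size_mm: float | None = None,
              frame_interval_s: float | None = None) -> ImageSeries:
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        meta = {}
        if tif.shaped_metadata:
            meta = tif.shaped_metadata[0]
    if data.ndim == 2:
        data = data[None]
    ps = pixel_size_mm if pixel_size_mm is not None else meta.get("pixel_size_mm")
    dt = frame_interval_s if frame_interval_s is not None else meta.get("frame_interval_s")
    if ps is None or dt is None:
        raise ValueError("pixel size and frame interval must be given (not in TIFF metadata)")
    return ImageSeries(np.asarray(data, dtype=float), float(ps), float(dt))


def write_nifti(series: ImageSeries, path) -> None:
    import nibabel as nib
    # (x, y, t) voxel order; in-plane spacing from pixel size, TR from frame interval
    arr = np.transpose(series.data, (2, 1, 0)).astype(np.float32)
    affine = np.diag([series.pixel_size_mm, series.pixel_size_mm, 1.0, 1.0])
    img = nib.Nifti1Image(arr, affine)
    img.header["pixdim"][4] = series.frame_interval_s
    nib.save(img, str(path))


def read_nifti(path, frame_interval_s: float | None = None) -> ImageSeries:
    import nibabel as nib
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=float)
    if arr.ndim != 3:
        raise ValueError("expected a 3-D (x, y, t) NIfTI volume")
    data = np.transpose(arr, (2, 1, 0))
    ps = float(img.header["pixdim"][1])
    dt = frame_interval_s if frame_interval_s is not None else float(img.header["pixdim"][4])
    if dt <= 0:
        raise ValueError("frame interval missing from NIfTI header; pass it explicitly")
    return ImageSeries(data, ps, dt)


# --- contours -------------------------------------------------------------

def write_contours(pairs, path) -> None:
    """CSV columns: frame, curvature, vertex_index, x_mm, y_mm (distal first)."""
    rows = []
    for t, pair in enumerate(pairs):
        for curv in (pair.lesser, pair.greater):
            verts = curv.oriented_vertices
            for i, (x, y) in enumerate(verts):
                rows.append((t, curv.label, i, x, y))
    pd.DataFrame(rows, columns=["frame", "curvature", "vertex_index",
                                "x_mm", "y_mm"]).to_csv(
        path, index=False, float_format="%.9g")


def read_contours(path) -> list:
    df = pd.read_csv(path)
    pairs = []
    for t in sorted(df["frame"].unique()):
        fd = df[df["frame"] == t]
        curvs = {}
        for label in ("lesser", "greater"):
            sub = fd[fd["curvature"] == label].sort_values("vertex_index")
            if len(sub) == 0:
                raise ValueError(f"frame {t}: missing {label} curvature")
            curvs[label] = Curvature(label, sub[["x_mm", "y_mm"]].to_numpy(),
                                     distal_end="first")
        pairs.append(CurvaturePair(lesser=curvs["lesser"], greater=curvs["greater"]))
    return pairs


# --- landmarks / transforms ----------------------------------------------

def write_landmarks(landmarks: LandmarkSet, path) -> None:
    rows = []
    for t in range(landmarks.n_frames):
        for i, (x, y) in enumerate(landmarks.frame(t)):
            rows.append((t, i, x, y))
    pd.DataFrame(rows, columns=["frame", "point_id", "x_px", "y_px"]).to_csv(
        path, index=False, float_format="%.9g")


def read_landmarks(path) -> LandmarkSet:
    df = pd.read_csv(path)
    required = {"frame", "point_id", "x_px", "y_px"}
    if not required.issubset(df.columns):
        raise ValueError(f"landmark CSV must have columns {sorted(required)}")
    frames = sorted(df["frame"].unique())
    pts = sorted(df["point_id"].unique())
    coords = np.empty((len(frames), len(pts), 2))
    for ti, t in enumerate(frames):
        fd = df[df["frame"] == t].set_index("point_id")
        if sorted(fd.index) != pts:
            raise ValueError(f"frame {t}: inconsistent landmark point ids")
        for pi, p in enumerate(pts):
            coords[ti, pi] = (fd.loc[p, "x_px"], fd.loc[p, "y_px"])
    return LandmarkSet(coords)


def write_transforms(transforms, path, residuals: bool = False) -> None:
    rows = []
    for t, tr in enumerate(transforms):
        row = {"frame": t, "dx_px": tr.dx, "dy_px": tr.dy,
               "theta_deg": np.degrees(tr.theta)}
        if residuals:
            row["residual"] = tr.residual
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")


def read_transforms(path, center=(0.0, 0.0)) -> list:
    df = pd.read_csv(path).sort_values("frame")
    return [RigidTransform(dx=r["dx_px"], dy=r["dy_px"],
                           theta=np.radians(r["theta_deg"]), center=center)
            for _, r in df.iterrows()]


# --- centerline / middle points -------------------------------------------

def write_middle_points(sets, path) -> None:
    rows = []
    for t, mps in enumerate(sets):
        for n in range(len(mps.points)):
            rows.append((t, n, mps.points[n, 0], mps.points[n, 1],
                         mps.pair_distance[n], bool(mps.valid[n])))
    pd.DataFrame(rows, columns=["frame", "n", "x_mm", "y_mm",
                                "pair_distance_mm", "valid"]).to_csv(
        path, index=False, float_format="%.9g")


def write_centerline(centerline: Centerline, csv_path, meta_path=None) -> None:
    pd.DataFrame({"n": np.arange(len(centerline.points)),
                  "x_mm": centerline.points[:, 0],
                  "y_mm": centerline.points[:, 1]}).to_csv(
        csv_path, index=False, float_format="%.9g")
    if meta_path is not None:
        meta = {"coefficients": centerline.coefficients.tolist(),
                "rotation": centerline.rotation.tolist(),
                "origin": centerline.origin.tolist(),
                "domain": list(centerline.domain),
                "length_mm": centerline.length_mm}
        pathlib.Path(meta_path).write_text(json.dumps(meta, indent=2))


def read_centerline(csv_path) -> np.ndarray:
    df = pd.read_csv(csv_path).sort_values("n")
    return df[["x_mm", "y_mm"]].to_numpy()


# --- maps / tracks / config ----------------------------------------------

def write_map(values: np.ndarray, times: np.ndarray, path) -> None:
    """Map CSV: one row per frame (time_s first), columns n = 1..N."""
    cols = {f"n{i + 1}": values[:, i] for i in range(values.shape[1])}
    pd.DataFrame({"time_s": times, **cols}).to_csv(
        path, index=False, float_format="%.9g")


def read_map(path):
    df = pd.read_csv(path)
    times = df["time_s"].to_numpy()
    vals = df.drop(columns=["time_s"]).to_numpy()
    return vals, times


def write_tracks(tracks, path) -> None:
    rows = []
    for tr in tracks:
        for s, t in zip(tr.s, tr.t):
            rows.append((tr.wave_id, tr.label, s, t))
    pd.DataFrame(rows, columns=["wave_id", "curvature", "s", "t_s"]).to_csv(
        path, index=False, float_format="%.9g")


def read_tracks(path) -> list:
    from .metrics import interpolate_track
    df = pd.read_csv(path)
    if not {"wave_id", "s", "t_s"}.issubset(df.columns):
        raise ValueError("tracks CSV needs columns wave_id, s, t_s")
    tracks = []
    for wid in sorted(df["wave_id"].unique()):
        sub = df[df["wave_id"] == wid]
        label = str(sub["curvature"].iloc[0]) if "curvature" in sub else ""
        tracks.append(interpolate_track(sub["s"].to_numpy(),
                                        sub["t_s"].to_numpy(),
                                        wave_id=int(wid), label=label))
    return tracks


def write_config(config, path) -> None:
    yaml.safe_dump(config.to_dict(), open(path, "w"), sort_keys=True)


def read_config(path):
    from .phantom import PhantomConfig
    raw = yaml.safe_load(open(path))
    for key in ("image_shape", "breathing_amplitude"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    if "landmark_fractions" in raw:
        raw["landmark_fractions"] = tuple(tuple(p) for p in raw["landmark_fractions"])
    if isinstance(raw.get("tube_radius_mm"), list):
        raw["tube_radius_mm"] = tuple(raw["tube_radius_mm"])
    return PhantomConfig(**raw)
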
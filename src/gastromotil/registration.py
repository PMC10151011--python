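"""Landmark-based rigid motion correction and the DVARS stability metric.

Breathing shifts the stomach within the imaging plane.  Four manually placed
landmarks per frame (in the study: three on the liver, one on the gall
bladder) define a rigid transform per frame; the transform minimising the
sum of squared distances between the frame's landmarks and the frame-1
landmarks is found with a derivative-free simplex search (Nelder–Mead, as in
MATLAB's ``fminsearch``) and applied to the image.  Residual instability is
scored with DVARS: the mean, over successive frame pairs, of the RMS
intensity change along a probe line crossing the stomach.

The transform model is "rotate about the image centre, then translate".
A rotation about the origin plus translation (as the objective is sometimes
written) describes the same family of maps — the two parameterisations
differ only by a reparameterised translation, which the optimiser absorbs —
but rotating about the centre keeps the parameters well-conditioned for
small angles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize

from .series import ImageSeries

__all__ = [
    "RigidTransform",
    "LandmarkSet",
    "DvarsResult",
    "estimate_transform",
    "apply_transform",
    "correct_series",
    "dvars",
    "probe_line",
]


def _rot(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


@dataclass
class RigidTransform:
    """Planar rigid map: rotate by ``theta`` about ``center``, then translate.

    ``dx``/``dy`` are in pixels, ``theta`` in radians (positive = from +x
    toward +y, i.e. clockwise on screen with y pointing down).
    """

    dx: float
    dy: float
    theta: float
    center: tuple = (0.0, 0.0)
    residual: float = float("nan")

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 2) points (x, y) through the transform analytically."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        c = np.asarray(self.center, dtype=float)
        out = (p - c) @ _rot(self.theta).T + c + np.array([self.dx, self.dy])
        return out if np.asarray(points).ndim == 2 else out[0]

    def inverse(self) -> "RigidTransform":
        d = np.array([self.dx, self.dy])
        dinv = -(_rot(-self.theta) @ d)
        return RigidTransform(dx=float(dinv[0]), dy=float(dinv[1]),
                              theta=-self.theta, center=self.center)

    @property
    def is_identity(self) -> bool:
        return self.dx == 0.0 and self.dy == 0.0 and self.theta == 0.0

    def params(self) -> tuple:
        return (self.dx, self.dy, self.theta)


@dataclass
class LandmarkSet:
    """Per-frame landmark coordinates, (T, K, 2) in pixels.

    Point ``i`` must refer to the same anatomical landmark in every frame.
    """

    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValueError("landmark coords must be (T, K, 2)")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_points(self) -> int:
        return self.coords.shape[1]

    def frame(self, t: int) -> np.ndarray:
        return self.coords[t]


@dataclass
class DvarsResult:
    """DVARS value with its probe line and the T-1 per-step RMS terms."""

    value: float
    line: np.ndarray
    steps: np.ndarray = field(default_factory=lambda: np.empty(0))


def _procrustes_params(target: np.ndarray, reference: np.ndarray,
                       center: np.ndarray) -> tuple:
    """Closed-form least-squares rigid fit (Kabsch/SVD), reparameterised to
    the rotate-about-center-then-translate model."""
    tc = target.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (target - tc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, d]) @ u.T
    theta = float(np.arctan2(r[1, 0], r[0, 0]))
    # full map: p' = R (p - tc) + rc  ==  R (p - c) + c + d_eff
    d_eff = rc - center - _rot(theta) @ (tc - center)
    return float(d_eff[0]), float(d_eff[1]), theta


def estimate_transform(target_landmarks: np.ndarray,
                       reference_landmarks: np.ndarray,
                       center=(0.0, 0.0),
                       tol: float = 1e-6,
                       max_iter: int = 4000) -> RigidTransform:
    """Rigid transform mapping target landmarks onto reference landmarks.

    Minimises sum_i |T(P_target,i) - P_ref,i|^2 over (dx, dy, theta) with a
    Nelder–Mead simplex started at (0, 0, 0); if the residual at the simplex
    optimum exceeds ``tol`` the search is restarted once from the closed-form
    Procrustes solution and the better optimum is kept.

    Raises
    ------
    ValueError
        Fewer than 2 non-coincident landmark pairs, or all landmarks
        coincident (rotation indeterminate).
    RuntimeError
        Non-convergence after ``max_iter`` iterations (the message carries
        the best parameters found).
    """
    tgt = np.atleast_2d(np.asarray(target_landmarks, dtype=float))
    ref = np.atleast_2d(np.asarray(reference_landmarks, dtype=float))
    if tgt.shape != ref.shape or tgt.shape[0] < 2:
        raise ValueError("need >= 2 landmark pairs with matching shapes")
    if np.allclose(tgt, tgt[0], atol=1e-12):
        raise ValueError("all landmarks coincident: rotation is indeterminate")
    c = np.asarray(center, dtype=float)

    def objective(params):
        dxy = params[:2]
        th = params[2]
        mapped = (tgt - c) @ _rot(th).T + c + dxy
        return float(((mapped - ref) ** 2).sum())

    opts = dict(xatol=1e-9, fatol=1e-15, maxiter=max_iter)
    res = minimize(objective, x0=np.zeros(3), method="Nelder-Mead", options=opts)
    best = res
    if res.fun > tol:
        x0 = np.array(_procrustes_params(tgt, ref, c))
        res2 = minimize(objective, x0=x0, method="Nelder-Mead", options=opts)
        if res2.fun < best.fun:
            best = res2
    if not best.success and best.nit >= max_iter:
        raise RuntimeError(
            f"rigid fit did not converge after {max_iter} iterations; "
            f"best-so-far (dx, dy, theta) = {tuple(best.x)} with residual {best.fun:.3e}")
    dx, dy, theta = best.x
    return RigidTransform(dx=float(dx), dy=float(dy), theta=float(theta),
                          center=(float(c[0]), float(c[1])), residual=float(best.fun))


def apply_transform(image: np.ndarray, transform: RigidTransform) -> np.ndarray:
    """Resample an image under a rigid transform (bilinear, zero-filled).

    Features move as the transform moves points: the output value at pixel q
    is the input sampled at T^-1(q).  An exact identity returns a copy and
    integer pure translations incur no interpolation blur.
    """
    img = np.asarray(image, dtype=float)
    if transform.is_identity:
        return img.copy()
    inv = transform.inverse()
    # input (row, col) = A @ output (row, col) + offset
    a_xy = _rot(inv.theta)
    c = np.asarray(inv.center, dtype=float)
    b_xy = c + np.array([inv.dx, inv.dy]) - a_xy @ c
    swap = np.array([[0.0, 1.0], [1.0, 0.0]])
    a_rc = swap @ a_xy @ swap
    b_rc = swap @ b_xy
    return ndimage.affine_transform(img, a_rc, offset=b_rc, order=1,
                                    mode="constant", cval=0.0)


def correct_series(series: ImageSeries, landmarks: LandmarkSet):
    """Align every frame to frame 1 via its landmark-derived rigid transform.

    Returns the corrected series and the per-frame transforms (frame 0 gets
    an exact identity).  Contour coordinates can be carried along by
    applying the same transforms with :meth:`RigidTransform.apply_points`.
    """
    if landmarks.n_frames != series.n_frames:
        raise ValueError("landmarks must cover every frame of the series")
    h, w = series.shape
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    ref = landmarks.frame(0)
    out = np.empty_like(series.data, dtype=float)
    out[0] = np.asarray(series.data[0], dtype=float)
    transforms = [RigidTransform(0.0, 0.0, 0.0, center=center, residual=0.0)]
    for t in range(1, series.n_frames):
        try:
            tr = estimate_transform(landmarks.frame(t), ref, center=center)
        except (ValueError, RuntimeError) as exc:
            raise type(exc)(f"frame {t}: {exc}") from exc
        out[t] = apply_transform(series.data[t], tr)
        transforms.append(tr)
    corrected = ImageSeries(out, series.pixel_size_mm, series.frame_interval_s)
    return corrected, transforms


def dvars(series: ImageSeries, line: np.ndarray,
          exclude_zero: bool = False) -> DvarsResult:
    """Temporal derivative of RMS variance over a probe line.

    DVARS = 1/(T-1) * sum_{t=2..T} sqrt( 1/n * sum_p (I_{p,t} - I_{p,t-1})^2 )

    ``line`` is an (n, 2) integer array of (x, y) pixel coordinates; its
    value is invariant to the ordering of the pixels.  With
    ``exclude_zero=True``, pixels that are exactly zero in any frame
    (zero-filled after resampling out of frame) are dropped from the line.
    """
    if series.n_frames < 2:
        raise ValueError("DVARS needs at least 2 frames")
    pts = np.atleast_2d(np.asarray(line))
    if pts.size == 0:
        raise ValueError("probe line is empty")
    x = np.asarray(np.round(pts[:, 0]), dtype=int)
    y = np.asarray(np.round(pts[:, 1]), dtype=int)
    h, w = series.shape
    if (x < 0).any() or (x >= w).any() or (y < 0).any() or (y >= h).any():
        raise ValueError("probe line extends outside the image")
    intens = series.data[:, y, x].astype(float)   # (T, n)
    if exclude_zero:
        keep = (intens != 0).all(axis=0)
        if not keep.any():
            raise ValueError("all probe pixels are zero-filled")
        intens = intens[:, keep]
        pts = pts[keep]
    diffs = np.diff(intens, axis=0)
    steps = np.sqrt((diffs ** 2).mean(axis=1))
    return DvarsResult(value=float(steps.mean()), line=pts, steps=steps)


def probe_line(series: ImageSeries, contour_points_mm: np.ndarray | None = None,
               column: int | None = None) -> np.ndarray:
    """Default DVARS probe: a vertical line crossing the stomach.

    Column defaults to the mean x of the frame-1 contour (or the image
    centre column); rows span the contour's y-range (or the full image).
    """
    h, w = series.shape
    if contour_points_mm is not None:
        px = np.asarray(contour_points_mm, dtype=float) / series.pixel_size_mm
        col = int(round(px[:, 0].mean())) if column is None else int(column)
        r0 = max(0, int(np.floor(px[:, 1].min())))
        r1 = min(h - 1, int(np.ceil(px[:, 1].max())))
    else:
        col = w // 2 if column is None else int(column)
        r0, r1 = 0, h - 1
    rows = np.arange(r0, r1 + 1)
    return np.column_stack([np.full_like(rows, col), rows])
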
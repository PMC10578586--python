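"""Colony-outline measurement from Petri-dish images.

Pipeline: (1) detect the Petri dish by thresholding, morphological closing
and a least-squares circle fit to the largest round component; (2) segment
the colony inside the dish and extract a marching-squares contour,
resampled to equally spaced points; (3) refine each outline point by
sampling pixel intensities along the outward normal, fitting a sigmoid
``I(x) = a + b/(1+exp(-(x-x0)/s))`` and moving the point to the fitted
inflection ``x0``.  The refinement makes the outline robust to shading and
other smooth illumination gradients that bias a plain intensity threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from shapely.geometry import LinearRing
from skimage import filters, measure, morphology

logger = logging.getLogger(__name__)

__all__ = [
    "Circle",
    "Outline",
    "SigmoidFit",
    "detect_dish",
    "segment_colony",
    "fit_sigmoid",
    "refine_outline",
    "outline_radius",
    "process_series",
    "load_image",
]


class DishNotFoundError(RuntimeError):
    pass


class ColonyNotFoundError(RuntimeError):
    pass


@dataclass(frozen=True)
class Circle:
    """Least-squares circle (pixel coordinates, x = column, y = row)."""

    cx: float
    cy: float
    radius: float
    residual: float
    truncated: bool = False


@dataclass
class Outline:
    """Ordered closed polygon of (sub)pixel colony boundary points.

    ``points`` is (n, 2) in (x, y); ``normals`` are outward unit normals;
    ``shifts`` and ``converged`` describe the sigmoid refinement applied to
    each point (0 / False before refinement).
    """

    points: np.ndarray
    normals: np.ndarray
    shifts: np.ndarray
    converged: np.ndarray

    def __post_init__(self) -> None:
        if len(self.points) < 16:
            raise ValueError("outline needs at least 16 points")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def is_simple(self) -> bool:
        return LinearRing(self.points).is_simple

    def copy(self) -> "Outline":
        return Outline(
            self.points.copy(),
            self.normals.copy(),
            self.shifts.copy(),
            self.converged.copy(),
        )


@dataclass(frozen=True)
class SigmoidFit:
    """Parameters of a logistic edge profile fit."""

    a: float
    b: float
    x0: float
    s: float
    converged: bool
    residual: float


def load_image(path) -> np.ndarray:
    """Read an 8/16-bit grayscale PNG or TIFF as a float array."""
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    return img.astype(float)


def _fit_circle(xs: np.ndarray, ys: np.ndarray) -> Tuple[float, float, float, float]:
    """Algebraic (Kasa) least-squares circle through boundary pixels."""
    A = np.column_stack([xs, ys, np.ones_like(xs)])
    b = xs**2 + ys**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = sol[0] / 2, sol[1] / 2
    radius = np.sqrt(max(sol[2] + cx**2 + cy**2, 0.0))
    dist = np.hypot(xs - cx, ys - cy)
    residual = float(np.sqrt(np.mean((dist - radius) ** 2)))
    return float(cx), float(cy), float(radius), residual


def detect_dish(
    image: np.ndarray,
    min_area_frac: float = 0.25,
    min_circularity: float = 0.8,
    closing_radius: int = 3,
) -> Circle:
    """Locate the Petri dish as the largest bright, round component."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 64:
        raise ValueError("image must be 2-D grayscale, at least 64x64")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite intensities")
    if np.ptp(image) == 0:
        raise DishNotFoundError("dish not found: uniform image")
    thresh = filters.threshold_otsu(image)
    binary = morphology.closing(image > thresh, morphology.disk(closing_radius))
    labels = measure.label(binary)
    props = measure.regionprops(labels)
    if not props:
        raise DishNotFoundError("dish not found: no component above threshold")
    frame_area = image.shape[0] * image.shape[1]
    best = max(props, key=lambda p: p.area)
    circularity = 4 * np.pi * best.area / max(best.perimeter, 1e-12) ** 2
    mask = labels == best.label
    touches = (
        mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any()
    )
    # a dish cut by the frame cannot be round; gate on circularity only when
    # the component lies fully inside the frame
    if best.area < min_area_frac * frame_area or (
        not touches and circularity < min_circularity
    ):
        raise DishNotFoundError(
            f"dish not found: best component area {best.area/frame_area:.2f} "
            f"of frame, circularity {circularity:.2f}"
        )
    boundary = mask & ~ndimage.binary_erosion(mask)
    if touches:  # frame-edge pixels are not dish rim; keep them out of the fit
        boundary[0, :] = boundary[-1, :] = False
        boundary[:, 0] = boundary[:, -1] = False
    ys, xs = np.nonzero(boundary)
    cx, cy, radius, residual = _fit_circle(xs.astype(float), ys.astype(float))
    if not (0 <= cx < image.shape[1] and 0 <= cy < image.shape[0]):
        raise DishNotFoundError("dish not found: fitted center outside image")
    return Circle(cx=cx, cy=cy, radius=radius, residual=residual, truncated=touches)


def _resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to n points equally spaced by arc length."""
    closed = np.vstack([points, points[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    targets = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(targets, cum, closed[:, 0])
    y = np.interp(targets, cum, closed[:, 1])
    return np.column_stack([x, y])


def _outward_normals(points: np.ndarray) -> np.ndarray:
    """Unit normals perpendicular to the local tangent, pointing away from
    the polygon centroid."""
    nxt = np.roll(points, -1, axis=0)
    prv = np.roll(points, 1, axis=0)
    tangent = nxt - prv
    normals = np.column_stack([tangent[:, 1], -tangent[:, 0]])
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    normals = normals / norms
    centroid = points.mean(axis=0)
    flip = np.einsum("ij,ij->i", normals, points - centroid) < 0
    normals[flip] *= -1
    return normals


def segment_colony(
    image: np.ndarray,
    dish: Circle,
    margin_frac: float = 0.05,
    n_points: int = 360,
    threshold: Optional[float] = None,
) -> Outline:
    """Threshold-segment the colony inside the dish and extract its contour.

    The analysis is restricted to the dish interior minus a margin; the
    threshold defaults to Otsu's on those pixels.  The largest component is
    kept (additional components are logged) and its marching-squares
    contour is resampled to ``n_points`` equally spaced points.
    """
    image = np.asarray(image, dtype=float)
    yy, xx = np.mgrid[: image.shape[0], : image.shape[1]]
    interior = (
        np.hypot(xx - dish.cx, yy - dish.cy) <= dish.radius * (1 - margin_frac)
    )
    if not interior.any():
        raise ColonyNotFoundError("colony not found: empty dish interior")
    if threshold is None:
        vals = image[interior]
        if np.ptp(vals) == 0:
            raise ColonyNotFoundError("colony not found: uniform dish interior")
        threshold = float(filters.threshold_otsu(vals))
    binary = (image > threshold) & interior
    labels = measure.label(binary)
    props = measure.regionprops(labels)
    if not props:
        raise ColonyNotFoundError("colony not found: nothing above threshold")
    props = sorted(props, key=lambda p: p.area, reverse=True)
    if len(props) > 1:
        logger.info(
            "segment_colony: %d components, keeping the largest (%d px)",
            len(props), props[0].area,
        )
    mask = labels == props[0].label
    # marching squares at the threshold level, outside-interior suppressed
    work = np.where(mask, image, min(threshold - 1.0, image.min() - 1.0))
    contours = measure.find_contours(work, level=threshold)
    if not contours:
        raise ColonyNotFoundError("colony not found: no contour at threshold")
    contour = max(contours, key=len)  # (row, col)
    points = _resample_closed(contour[:, ::-1], n_points)  # -> (x, y)
    n = len(points)
    return Outline(
        points=points,
        normals=_outward_normals(points),
        shifts=np.zeros(n),
        converged=np.zeros(n, dtype=bool),
    )


def _logistic(x: np.ndarray, a: float, b: float, x0: float, s: float) -> np.ndarray:
    u = np.clip(-(x - x0) / s, -500.0, 500.0)
    return a + b / (1.0 + np.exp(u))


def fit_sigmoid(
    profile: np.ndarray, x: Optional[np.ndarray] = None
) -> SigmoidFit:
    """Least-squares logistic fit to an intensity profile.

    Initialization: ``a`` at the profile minimum, ``b`` at its range, ``x0``
    at the steepest finite-difference gradient, ``s`` a quarter of the
    profile length.  Never raises: non-convergence (or an unidentifiable
    flat profile) returns ``converged=False``.  Fits with negative slope
    scale are renormalized to ``s > 0`` via the equivalent ``b -> -b`` form.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size < 7:
        raise ValueError("sigmoid fit needs at least 7 samples")
    if x is None:
        x = np.arange(profile.size, dtype=float)
    else:
        x = np.asarray(x, dtype=float)
    if np.ptp(profile) <= 1e-9 * max(1.0, float(np.abs(profile).max())) or not np.all(
        np.isfinite(profile)
    ):
        return SigmoidFit(
            a=float(profile[0]) if np.isfinite(profile[0]) else np.nan,
            b=0.0, x0=np.nan, s=np.nan, converged=False, residual=np.nan,
        )
    grad = np.abs(np.gradient(profile, x))
    p0 = [
        float(profile.min()),
        float(np.ptp(profile)),
        float(x[int(np.argmax(grad))]),
        float((x[-1] - x[0]) / 4),
    ]
    try:
        with warnings.catch_warnings():
            # only the parameters are used, never the covariance estimate
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                _logistic, x, profile, p0=p0, maxfev=2000
            )
        a, b, x0, s = (float(v) for v in popt)
        if s < 0:  # equivalent parameterization with positive slope scale
            a, b, s = a + b, -b, -s
        resid = float(np.sqrt(np.mean((_logistic(x, a, b, x0, s) - profile) ** 2)))
        ok = np.isfinite([a, b, x0, s]).all() and s > 0
        return SigmoidFit(a=a, b=b, x0=x0, s=s, converged=bool(ok), residual=resid)
    except (RuntimeError, optimize.OptimizeWarning, ValueError):
        return SigmoidFit(
            a=p0[0], b=p0[1], x0=np.nan, s=np.nan, converged=False, residual=np.nan
        )


def _moving_median_closed(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    half = window // 2
    padded = np.concatenate([values[-half:], values, values[:half]])
    out = np.empty_like(values)
    for i in range(len(values)):
        out[i] = np.median(padded[i : i + 2 * half + 1])
    return out


def refine_outline(
    image: np.ndarray,
    outline: Outline,
    L: float = 10.0,
    max_shift: float = 8.0,
    step: float = 0.5,
    smooth_window: int = 5,
) -> Outline:
    """Move each outline point to the sigmoid inflection of its normal profile.

    Intensities are sampled by bilinear interpolation along the outward
    normal over ``[-L, +L]`` pixels; a point moves by the fitted ``x0`` only
    if the fit converged and ``|x0| <= max_shift``, and shifts are smoothed
    by a circular moving median along the contour.  If the shifted polygon
    self-intersects, the largest offending shifts are reverted.
    """
    if L < 3:
        raise ValueError("profile half-length L must be >= 3 px")
    image = np.asarray(image, dtype=float)
    offsets = np.arange(-L, L + step / 2, step)
    pts = outline.points
    nrm = outline.normals
    n = len(pts)
    shifts = np.zeros(n)
    converged = np.zeros(n, dtype=bool)
    for i in range(n):
        sample_xy = pts[i] + offsets[:, None] * nrm[i]
        prof = ndimage.map_coordinates(
            image, [sample_xy[:, 1], sample_xy[:, 0]], order=1, mode="nearest"
        )
        fit = fit_sigmoid(prof, x=offsets)
        if fit.converged and abs(fit.x0) <= max_shift:
            shifts[i] = fit.x0
            converged[i] = True
    shifts = _moving_median_closed(shifts, smooth_window)
    new_pts = pts + shifts[:, None] * nrm
    refined = Outline(
        points=new_pts, normals=nrm.copy(), shifts=shifts, converged=converged
    )
    # revert the largest shifts until the polygon is simple again
    order = np.argsort(-np.abs(shifts))
    j = 0
    while not refined.is_simple() and j < n:
        i = order[j]
        refined.points[i] = pts[i]
        refined.shifts[i] = 0.0
        refined.converged[i] = False
        j += 1
    return refined


def outline_radius(
    outline: Outline, pixel_size_mm: Optional[float] = None
) -> Dict[str, float]:
    """Equivalent-area radius sqrt(area/pi) of the outline polygon.

    Also reports the mean centroid distance; values in mm when
    ``pixel_size_mm`` is given.
    """
    pts = outline.points
    x, y = pts[:, 0], pts[:, 1]
    area = 0.5 * abs(
        float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    )
    if area <= 0:
        raise ValueError("degenerate polygon with zero area")
    radius = float(np.sqrt(area / np.pi))
    centroid = pts.mean(axis=0)
    mean_dist = float(np.hypot(*(pts - centroid).T).mean())
    out = {"radius_px": radius, "centroid_mean_px": mean_dist, "area_px2": area}
    if pixel_size_mm is not None:
        out["radius_mm"] = radius * pixel_size_mm
    return out


def process_series(
    manifest: pd.DataFrame,
    L: float = 10.0,
    max_shift: float = 8.0,
    n_points: int = 360,
    corrections: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Run the full pipeline over an image series.

    ``manifest`` needs columns ``path`` and ``time_h`` (optionally
    ``pixel_size_mm``); per-image failures are flagged in the output and do
    not stop the series.  ``corrections`` (columns ``path``, ``point_index``,
    ``x``, ``y``) overrides individual refined outline points, mirroring a
    manual-adjustment step.
    """
    required = {"path", "time_h"}
    if not required <= set(manifest.columns):
        raise ValueError(f"manifest needs columns {sorted(required)}")
    if "pixel_size_mm" in manifest.columns:
        px = manifest["pixel_size_mm"].dropna().unique()
        if len(px) > 1:
            raise ValueError("pixel size must be consistent across the series")
    rows = []
    for _, rec in manifest.iterrows():
        row = {"path": rec["path"], "time_h": float(rec["time_h"]),
               "radius_px": np.nan, "radius_mm": np.nan, "ok": False, "error": ""}
        try:
            image = load_image(rec["path"])
            dish = detect_dish(image)
            outline = segment_colony(image, dish, n_points=n_points)
            outline = refine_outline(image, outline, L=L, max_shift=max_shift)
            if corrections is not None:
                sel = corrections[corrections["path"] == rec["path"]]
                for _, c in sel.iterrows():
                    outline.points[int(c["point_index"])] = (c["x"], c["y"])
            psz = rec.get("pixel_size_mm", None)
            psz = None if psz is None or pd.isna(psz) else float(psz)
            stats = outline_radius(outline, pixel_size_mm=psz)
            row["radius_px"] = stats["radius_px"]
            row["radius_mm"] = stats.get("radius_mm", np.nan)
            row["ok"] = True
        except Exception as exc:  # noqa: BLE001 - per-image isolation contract
            row["error"] = str(exc)
            logger.warning("image %s failed: %s", rec["path"], exc)
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["path", "time_h", "radius_px", "radius_mm", "ok", "error"]
    )
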
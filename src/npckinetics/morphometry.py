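"""Membrane-profile morphometry of INM evaginations.

Traces are ordered 2-D point sets (nm, tomogram section plane) clicked along
the inner or outer nuclear membrane around one event (assembly intermediate,
mature pore, or ONM/INM fusion).  The pipeline aligns each INM trace so the
flat flanking membrane becomes the x-axis with the evagination pointing +y,
interpolates it with a cubic spline on a 1-nm grid, smooths with a local
second-degree polynomial (Savitzky-Golay) window, and extracts:

* evagination depth: maximum height above the baseline,
* evagination diameter: width between the outermost crossings of a
  near-baseline threshold (a profile-based stand-in for manual top-view
  diameter measurements; manually measured diameters can be supplied via
  tables instead and are never silently mixed with profile-based ones),
* ONM/INM distance: median perpendicular membrane separation at 50 stations
  in a 45-90 nm band away from a mature pore.

Coordinates are assumed pre-scaled and shrinkage-corrected
(:func:`npckinetics.density.apply_shrinkage`); no voxel anisotropy handling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import Akima1DInterpolator
from scipy.signal import savgol_filter

__all__ = [
    "ProfileTrace",
    "ProfileMetrics",
    "RigidTransform",
    "align_profile",
    "smooth_profile",
    "evagination_depth",
    "evagination_diameter",
    "onm_inm_distance",
    "average_profiles",
]

log = logging.getLogger("npckinetics.morphometry")


@dataclass(frozen=True)
class ProfileTrace:
    """Ordered membrane outline of one event in the section plane (nm)."""

    structure: str  # "INM" or "ONM"
    points: np.ndarray  # (n, 2)
    event_id: str = ""
    time_ao: float | None = None
    region: str | None = None
    event_type: str | None = None  # intermediate / mature / fusion

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if self.structure not in ("INM", "ONM"):
            raise ValueError("structure must be 'INM' or 'ONM'")
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
            raise ValueError("need >= 4 finite 2-D points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("coordinates must be finite")


@dataclass(frozen=True)
class ProfileMetrics:
    """Per-event geometry; ``diameter`` may come from manual top views."""

    depth: float  # nm, >= 0
    diameter: float | None = None  # nm
    onm_inm_distance: float | None = None  # nm
    diameter_source: str = "profile"  # "profile" or "manual"

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.diameter is not None and self.diameter <= 0:
            raise ValueError("diameter must be > 0")
        if (
            self.onm_inm_distance is not None
            and self.depth > 2.0 * self.onm_inm_distance
        ):
            warnings.warn(
                "depth exceeds twice the ONM/INM distance - check the trace",
                stacklevel=2,
            )


@dataclass(frozen=True)
class RigidTransform:
    """Rotation by ``angle`` about the origin followed by ``shift``."""

    angle: float
    shift: np.ndarray  # (2,)

    def apply(self, points: np.ndarray) -> np.ndarray:
        c, s = np.cos(self.angle), np.sin(self.angle)
        R = np.array([[c, -s], [s, c]])
        return np.asarray(points, float) @ R.T + self.shift


def _flank_indices(n: int, flank_fraction: float):
    k = max(int(round(n * flank_fraction)), 2)
    return np.r_[0:k, n - k : n]


def align_profile(
    inm: ProfileTrace,
    flank_fraction: float = 0.25,
    baseline_max_rms: float = 5.0,
) -> tuple[ProfileTrace, RigidTransform]:
    """Rigidly align a trace so the flanking baseline is the x-axis.

    The baseline is a least-squares line through the outer ``flank_fraction``
    of points on each flank; the trace is rotated to level it, translated to
    put it at y = 0, and flipped (180-degree rotation) if the evagination
    points -y.  Returns the aligned trace and the transform, for co-aligning
    the event's ONM trace.  Raises if the flanks do not form a line
    (baseline RMS residual above ``baseline_max_rms`` nm).
    """
    pts = inm.points
    idx = _flank_indices(len(pts), flank_fraction)
    fx, fy = pts[idx, 0], pts[idx, 1]
    if np.ptp(fx) < 1e-9:
        raise ValueError("flank points are vertical: no identifiable baseline")
    slope, intercept = np.polyfit(fx, fy, 1)
    angle = -np.arctan(slope)
    tr = RigidTransform(angle, np.zeros(2))
    rot = tr.apply(pts)
    base_y = np.mean(tr.apply(np.c_[fx, fy])[:, 1])
    tr = RigidTransform(angle, np.array([0.0, -base_y]))
    out = tr.apply(pts)
    resid = out[idx, 1]
    rms = float(np.sqrt(np.mean(resid**2)))
    if rms > baseline_max_rms:
        raise ValueError(
            f"no identifiable baseline: flank RMS {rms:.1f} nm exceeds "
            f"{baseline_max_rms} nm"
        )
    interior = out[np.setdiff1d(np.arange(len(pts)), idx), 1]
    if interior.size and np.mean(interior) < 0:
        flip = RigidTransform(np.pi, np.zeros(2))
        out = flip.apply(out)
        tr = RigidTransform(tr.angle + np.pi, flip.apply(tr.shift[None, :])[0])
    return replace(inm, points=out), tr


def smooth_profile(
    trace: ProfileTrace,
    window_nm: float = 15.0,
    grid_nm: float = 1.0,
) -> np.ndarray:
    """Spline-interpolate an aligned trace to a dense grid and smooth it.

    Local spline (Akima) interpolation onto a ``grid_nm`` grid followed by a
    moving local second-degree polynomial (Savitzky-Golay) of width
    ``window_nm``; ``window_nm=0`` skips the polynomial smoothing (useful for
    width measurements, which the moving window would smear outward).  Akima
    rather than a global cubic spline: it does not ring at the sharp
    dome-flank junction and keeps flat flanks exactly flat.  Duplicate x
    positions are averaged with a warning.  Returns an (n, 2) array.
    """
    pts = trace.points[np.argsort(trace.points[:, 0], kind="stable")]
    x, y = pts[:, 0], pts[:, 1]
    ux, inv = np.unique(x, return_inverse=True)
    if ux.size < x.size:
        warnings.warn("duplicate x after alignment: averaging", stacklevel=2)
        y = np.bincount(inv, weights=y) / np.bincount(inv)
        x = ux
    spline = Akima1DInterpolator(x, y)
    n_grid = max(int(round((x[-1] - x[0]) / grid_nm)), 1)
    xg = np.linspace(x[0], x[-1], n_grid + 1)
    yg = spline(xg)
    window = int(round(window_nm / grid_nm))
    window += 1 - window % 2  # odd
    if window >= 5 and xg.size > window:
        yg = savgol_filter(yg, window, polyorder=2)
    return np.c_[xg, yg]


def evagination_depth(profile: np.ndarray) -> float:
    """Maximum height (nm) of a smoothed, aligned profile above its baseline."""
    y = np.asarray(profile)[:, 1]
    top = float(y.max())
    if top <= 0:
        warnings.warn("profile never rises above the baseline", stacklevel=2)
        return 0.0
    return top


def evagination_diameter(
    profile: np.ndarray, baseline_threshold: float = 2.0
) -> float | None:
    """Width (nm) between the outermost crossings of y = threshold.

    Returns ``None`` (missing) when the profile never reaches the threshold.
    """
    p = np.asarray(profile, float)
    x, y = p[:, 0], p[:, 1] - baseline_threshold
    above = y > 0
    if not above.any():
        return None
    first = int(np.argmax(above))
    last = int(len(above) - 1 - np.argmax(above[::-1]))

    def crossing(i0, i1):
        if y[i0] == y[i1]:
            return x[i0]
        return x[i0] + (x[i1] - x[i0]) * (0.0 - y[i0]) / (y[i1] - y[i0])

    x_left = crossing(first - 1, first) if first > 0 else x[0]
    x_right = crossing(last + 1, last) if last < len(x) - 1 else x[-1]
    return float(abs(x_right - x_left))


def onm_inm_distance(
    onm: np.ndarray,
    inm: np.ndarray,
    pore_edge_x: float,
    band: tuple[float, float] = (45.0, 90.0),
    n_stations: int = 50,
) -> float:
    """Median perpendicular INM->ONM membrane separation near a mature pore.

    Stations are placed evenly inside the band ``band[0]``-``band[1]`` nm
    away from ``pore_edge_x`` (both sides when both lie within the traces,
    always ``n_stations`` in total); at each station the foot-of-normal
    distance from the INM to the ONM polyline is taken, and the median over
    stations is returned (robust to local bumps in either membrane).
    """
    onm = np.asarray(onm, float)
    inm = np.asarray(inm, float)
    lo, hi = band
    sides = []
    for sign in (+1, -1):
        a = pore_edge_x + sign * lo
        b = pore_edge_x + sign * hi
        x0, x1 = min(a, b), max(a, b)
        if x0 >= inm[:, 0].min() and x1 <= inm[:, 0].max():
            sides.append((x0, x1))
    if not sides:
        raise ValueError("the 45-90 nm band lies outside the INM trace extent")
    per_side = n_stations // len(sides)
    stations = np.concatenate(
        [np.linspace(x0, x1, per_side + (n_stations - per_side * len(sides) if i == 0 else 0))
         for i, (x0, x1) in enumerate(sides)]
    )
    iy = np.interp(stations, inm[:, 0], inm[:, 1])
    pts = np.c_[stations, iy]
    dists = _point_polyline_distance(pts, onm)
    return float(np.median(dists))


def _point_polyline_distance(points: np.ndarray, line: np.ndarray) -> np.ndarray:
    """Distance from each point to the nearest foot on a polyline."""
    a, b = line[:-1], line[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom[denom == 0] = 1.0
    ap = points[:, None, :] - a[None, :, :]
    t = np.clip(np.einsum("pij,ij->pi", ap, ab) / denom, 0.0, 1.0)
    foot = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    d = np.linalg.norm(points[:, None, :] - foot, axis=2)
    return d.min(axis=1)


def average_profiles(profiles: list[np.ndarray], grid_nm: float = 1.0):
    """Apex-centered pointwise mean and s.d. of aligned, smoothed profiles.

    Each profile is shifted so its apex sits at x = 0; profiles are resampled
    on a common grid restricted to the intersection of their x-ranges (with a
    warning when the restriction is substantial).  Returns an (n, 3) array of
    (x, mean, sd).
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to average")
    centered = []
    for p in profiles:
        p = np.asarray(p, float)
        apex = p[np.argmax(p[:, 1]), 0]
        centered.append(np.c_[p[:, 0] - apex, p[:, 1]])
    lo = max(p[:, 0].min() for p in centered)
    hi = min(p[:, 0].max() for p in centered)
    if hi <= lo:
        raise ValueError("profiles do not overlap after apex centering")
    full = min(p[:, 0].min() for p in centered), max(p[:, 0].max() for p in centered)
    if (hi - lo) < 0.5 * (full[1] - full[0]):
        warnings.warn("profiles overlap on less than half their extent", stacklevel=2)
    xg = np.arange(lo, hi + grid_nm / 2, grid_nm)
    ys = np.stack([np.interp(xg, p[:, 0], p[:, 1]) for p in centered])
    return np.c_[xg, ys.mean(axis=0), ys.std(axis=0, ddof=1)]
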
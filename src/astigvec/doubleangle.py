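"""Double-angle plots: point mapping, centroids, and confidence ellipses.

A cylinder ``M @ alpha`` maps to the double-angle point
``(M cos 2*alpha, M sin 2*alpha)``, the plane where cylinders add linearly
and the 0/180 degree wrap disappears.  Polar values about phi are the same
construction rotated by 2*phi, so a DA result's component pair
(delta KP(phi), delta KP(phi+45)) is already a double-angle point in the
eye's own reference frame.

The ellipse drawn around a centroid is a confidence region for the *mean*
(Hotelling T-squared, F-scaled): its axes shrink like 1/sqrt(n).  A
tolerance ellipse for the data cloud itself (chi-squared scaling, n-stable)
is available behind ``kind="tolerance"``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .core import DAResult, NetAstigmatism

__all__ = [
    "DoubleAnglePoint",
    "ConfidenceEllipse",
    "to_double_angle",
    "mean_confidence_ellipse",
    "ellipse_contains",
    "render_da_plot",
]


@dataclass(frozen=True)
class DoubleAnglePoint:
    """Cartesian double-angle coordinates (D): x = M cos 2a, y = M sin 2a."""

    x: float
    y: float


@dataclass(frozen=True)
class ConfidenceEllipse:
    """An ellipse in double-angle space.

    ``semi_axes`` is (major, minor) with major >= minor; ``orientation`` is
    the major-axis direction in double-angle degrees; ``level`` the
    confidence level.
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    orientation: float
    level: float
    n: int

    @property
    def area(self) -> float:
        return math.pi * self.semi_axes[0] * self.semi_axes[1]


def to_double_angle(net: NetAstigmatism) -> DoubleAnglePoint:
    """Map a net cylinder to its double-angle point (injective on [0, 180))."""
    two_a = math.radians(2.0 * net.meridian)
    return DoubleAnglePoint(net.magnitude * math.cos(two_a), net.magnitude * math.sin(two_a))


def _as_xy(points: Sequence) -> np.ndarray:
    arr = np.array(
        [
            (p.x, p.y)
            if isinstance(p, DoubleAnglePoint)
            else (p.delta_kp_phi, p.delta_kp_phi45)
            if isinstance(p, DAResult)
            else tuple(p)
            for p in points
        ],
        dtype=float,
    )
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be 2-D")
    return arr


def mean_confidence_ellipse(
    points: Sequence, level: float = 0.95, *, kind: str = "mean"
) -> ConfidenceEllipse:
    """Confidence ellipse around the centroid of a 2-D point cloud.

    ``kind="mean"`` (default): Hotelling T-squared region for the true mean,
    scaled by ``2(n-1)/(n-2) * F(2, n-2)`` over n -- this is the ellipse the
    accuracy plots draw around centroids.  ``kind="tolerance"``: chi-squared
    region for the data cloud.  Requires n >= 3 and a non-degenerate sample
    covariance (otherwise raises, suggesting jitter or more data).
    """
    xy = _as_xy(points)
    n = xy.shape[0]
    if n < 3:
        raise ValueError("confidence ellipse needs n >= 3 points")
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    center = xy.mean(axis=0)
    cov = np.cov(xy, rowvar=False, ddof=1)
    if not np.all(np.isfinite(cov)) or np.linalg.det(cov) <= 0.0:
        raise ValueError(
            "degenerate covariance: points are (nearly) collinear or identical; "
            "jitter the data or collect more points"
        )
    if kind == "mean":
        scale = 2.0 * (n - 1) / (n - 2) * stats.f.ppf(level, 2, n - 2) / n
    elif kind == "tolerance":
        scale = stats.chi2.ppf(level, 2)
    else:
        raise ValueError("kind must be 'mean' or 'tolerance'")
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    semi = np.sqrt(eigval * scale)
    orient = math.degrees(math.atan2(eigvec[1, 0], eigvec[0, 0])) % 180.0
    return ConfidenceEllipse(
        center=(float(center[0]), float(center[1])),
        semi_axes=(float(semi[0]), float(semi[1])),
        orientation=orient,
        level=level,
        n=n,
    )


def ellipse_contains(ellipse: ConfidenceEllipse, point: tuple[float, float]) -> bool:
    """Whether ``point`` lies inside (or on) the ellipse."""
    dx = point[0] - ellipse.center[0]
    dy = point[1] - ellipse.center[1]
    t = math.radians(ellipse.orientation)
    u = math.cos(t) * dx + math.sin(t) * dy
    v = -math.sin(t) * dx + math.cos(t) * dy
    a, b = ellipse.semi_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def render_da_plot(
    das: Sequence,
    path: str | Path,
    *,
    title: str = "Difference in astigmatism",
    level: float = 0.95,
    limit: float | None = None,
) -> Path:
    """Double-angle scatter with centroid and mean confidence ellipse.

    Writes SVG or PNG according to the file suffix; the SVG output is
    byte-stable for fixed input (fixed hash salt, no timestamp metadata).
    A cloud too degenerate for an ellipse (e.g. an all-zero DA cohort) is
    drawn without one, with a warning.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse as MplEllipse

    if len(das) == 0:
        raise ValueError("nothing to plot")
    xy = _as_xy(das)
    plt.rcParams["svg.hashsalt"] = "astigvec"
    fig, ax = plt.subplots(figsize=(5.0, 5.0))
    ax.axhline(0.0, color="0.7", lw=0.8, zorder=1)
    ax.axvline(0.0, color="0.7", lw=0.8, zorder=1)
    ax.scatter(xy[:, 0], xy[:, 1], s=14, color="#2060a0", alpha=0.7, zorder=3)
    centroid = xy.mean(axis=0)
    ax.plot(*centroid, marker="D", color="#c03020", ms=7, zorder=4)
    try:
        ell = mean_confidence_ellipse(das, level)
        ax.add_patch(
            MplEllipse(
                ell.center,
                2 * ell.semi_axes[0],
                2 * ell.semi_axes[1],
                angle=ell.orientation,
                fill=False,
                color="#c03020",
                lw=1.4,
                zorder=4,
            )
        )
    except ValueError as exc:
        warnings.warn(f"ellipse omitted: {exc}")
    lim = limit if limit is not None else max(1.0, float(np.abs(xy).max()) * 1.2)
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_aspect("equal")
    ax.set_xlabel(r"$\Delta$KP($\Phi$)  (D)")
    ax.set_ylabel(r"$\Delta$KP($\Phi$+45)  (D)")
    ax.set_title(title)
    # single-angle meridian annotations at the double-angle compass points
    for ang, label in ((0, "0°"), (90, "45°"), (180, "90°"), (270, "135°")):
        r = lim * 0.93
        t = math.radians(ang)
        ax.annotate(
            label,
            (r * math.cos(t), r * math.sin(t)),
            ha="center",
            va="center",
            fontsize=8,
            color="0.4",
        )
    out = Path(path)
    fig.savefig(out, metadata={"Date": None} if out.suffix == ".svg" else None)
    plt.close(fig)
    return out
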
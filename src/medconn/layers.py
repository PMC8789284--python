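"""Depth normalization, layer lookup, kernel-smoothed profiles and the
dorsal-rim ellipse linearization.

Depth is expressed as a signed percentage along the columnar axis: 0 at the
distal neuropil surface, 100 at the proximal surface, negative values distal
to the neuropil (the optic chiasm), values above 100 proximal to it. Layers
are percent-depth bands between published demarcations; membership uses
half-open intervals ``[lower, upper)`` with 100 included in the last layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import integrate, optimize

from .io import NM_PER_UM, Point3

__all__ = [
    "LayerFrame",
    "MEDULLA_FRAME",
    "LOBULA_FRAME",
    "PlanarDepthAxis",
    "depth_fraction",
    "layer_of",
    "ProfileSeries",
    "smoothed_profile",
    "EllipseModel",
    "EllipseFitError",
    "fit_ellipse_lsq",
    "arc_position",
]


@dataclass(frozen=True)
class LayerFrame:
    """Ordered fractional boundaries mapping percent depth to named layers."""

    neuropil: str
    boundaries: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        b = self.boundaries
        if len(b) < 2 or b[0] != 0.0 or b[-1] != 100.0:
            raise ValueError("boundaries must start at 0 and end at 100")
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("boundaries must be strictly increasing")
        if len(self.labels) != len(b) - 1:
            raise ValueError("need exactly one label per band")

    def band(self, label: str) -> tuple[float, float]:
        """The ``[lower, upper)`` percent-depth band of a named layer."""
        i = self.labels.index(label)
        return (self.boundaries[i], self.boundaries[i + 1])


#: Medulla strata M1-M10 as percent-depth demarcations.
MEDULLA_FRAME = LayerFrame(
    neuropil="medulla",
    boundaries=(0.0, 8.2, 26.2, 36.1, 45.9, 54.1, 62.3, 67.2, 76.2, 91.0, 100.0),
    labels=("M1", "M2", "M3", "M4", "M5", "M6", "M7", "M8", "M9", "M10"),
)

#: Lobula strata (Lo5 split into A/B sublayers) as percent-depth demarcations.
LOBULA_FRAME = LayerFrame(
    neuropil="lobula",
    boundaries=(0.0, 4.2, 11.3, 22.4, 37.4, 49.4, 64.7, 100.0),
    labels=("Lo1", "Lo2", "Lo3", "Lo4", "Lo5A", "Lo5B", "Lo6"),
)


def layer_of(fraction: float, frame: LayerFrame) -> str:
    """Layer label for a percent depth, or ``"outside"`` beyond [0, 100].

    Bands are half-open ``[lower, upper)``; a fraction of exactly 100 maps to
    the last (most proximal) layer.
    """
    if fraction < 0.0 or fraction > 100.0:
        return "outside"
    if fraction == 100.0:
        return frame.labels[-1]
    i = int(np.searchsorted(frame.boundaries, fraction, side="right")) - 1
    return frame.labels[i]


# ---------------------------------------------------------------------------
# Depth axis
# ---------------------------------------------------------------------------

@dataclass
class PlanarDepthAxis:
    """Planar-slab realization of the columnar depth axis.

    The neuropil is modelled as a slab bounded by two parallel planes: the
    distal surface through ``origin_nm`` with unit ``normal`` pointing
    proximally, and the proximal surface ``thickness_um`` micrometres deeper.
    Any implementation providing a distal surface, a proximal surface and a
    monotone projection rule satisfies the same contract; the slab is the
    synthetic-data backend.
    """

    origin_nm: np.ndarray
    normal: np.ndarray
    thickness_um: float

    def __post_init__(self) -> None:
        self.origin_nm = np.asarray(self.origin_nm, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("degenerate axis: zero normal")
        if self.thickness_um <= 0:
            raise ValueError("degenerate axis: non-positive thickness")
        self.normal = n / norm
        # Deterministic in-plane basis (u, v) for planar coordinates.
        trial = np.array([1.0, 0.0, 0.0])
        if abs(self.normal @ trial) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        u = trial - (trial @ self.normal) * self.normal
        self._u = u / np.linalg.norm(u)
        self._v = np.cross(self.normal, self._u)

    def depth_fraction(self, points_nm: np.ndarray) -> np.ndarray | float:
        """Signed percent depth of point(s) given in nm; linear along the axis."""
        p = np.asarray(points_nm, dtype=float)
        d = (p - self.origin_nm) @ self.normal
        return d / (self.thickness_um * NM_PER_UM) * 100.0

    def to_plane_um(self, points_nm: np.ndarray) -> np.ndarray:
        """Project point(s) onto the distal plane; 2-D coordinates in um."""
        p = np.atleast_2d(np.asarray(points_nm, dtype=float)) - self.origin_nm
        return np.stack([p @ self._u, p @ self._v], axis=-1) / NM_PER_UM


def depth_fraction(point: Point3 | np.ndarray, axis: PlanarDepthAxis) -> float:
    """Signed percent depth of one point along the columnar axis."""
    if isinstance(point, Point3):
        point = np.array(point.as_tuple())
    return float(axis.depth_fraction(point))


# ---------------------------------------------------------------------------
# Kernel-smoothed profiles
# ---------------------------------------------------------------------------

@dataclass
class ProfileSeries:
    """A kernel density of synapse positions in synapses per micrometre.

    The trapezoidal integral of ``density`` over ``positions`` equals
    ``total_count`` to within 1% (mass conservation of the Gaussian kernel
    on a grid padded four bandwidths beyond the data).
    """

    positions: np.ndarray
    density: np.ndarray
    sigma: float
    total_count: int

    @property
    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.positions))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"position_um": self.positions, "density_per_um": self.density}
        )


def smoothed_profile(
    values: Sequence[float] | np.ndarray,
    sigma: float,
    grid_step: float = 0.05,
) -> ProfileSeries:
    """Zero-phase Gaussian smoothing of point positions into a density.

    Each input position (in um) contributes a unit-mass Gaussian kernel of
    standard deviation ``sigma`` um; the sum is evaluated by direct kernel
    summation on a regular grid padded +/- 4 sigma beyond the data range.
    The kernel is symmetric, so the filter introduces no phase shift. The
    published bandwidths are 0.4 um for depth profiles and 0.6 um for radial
    (home-column) and dorsal-rim arc-length profiles.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        grid = np.array([0.0])
        return ProfileSeries(grid, np.zeros_like(grid), sigma, 0)
    lo = v.min() - 4.0 * sigma
    hi = v.max() + 4.0 * sigma
    n = int(math.ceil((hi - lo) / grid_step)) + 1
    grid = lo + np.arange(n) * grid_step
    # Direct summation, chunked over input points to bound memory.
    density = np.zeros_like(grid)
    norm = 1.0 / (sigma * math.sqrt(2.0 * math.pi))
    for start in range(0, v.size, 2048):
        chunk = v[start : start + 2048]
        z = (grid[None, :] - chunk[:, None]) / sigma
        density += norm * np.exp(-0.5 * z * z).sum(axis=0)
    return ProfileSeries(grid, density, sigma, int(v.size))


# ---------------------------------------------------------------------------
# Ellipse fit and arc-length linearization
# ---------------------------------------------------------------------------

class EllipseFitError(ValueError):
    """Degenerate point configuration (collinear, or best conic not an ellipse)."""


@dataclass(frozen=True)
class EllipseModel:
    """Geometric ellipse: center, semi-axes ``a >= b > 0``, rotation angle.

    ``theta`` is the angle of the major axis against +x, normalized to
    ``[0, pi)``. Units are micrometres throughout.
    """

    center: tuple[float, float]
    a: float
    b: float
    theta: float

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError("require a >= b > 0")

    def point_at(self, t: float | np.ndarray) -> np.ndarray:
        """Point(s) on the ellipse at parametric angle ``t``."""
        ct, st = np.cos(self.theta), np.sin(self.theta)
        x = self.a * np.cos(t)
        y = self.b * np.sin(t)
        return np.stack(
            [self.center[0] + ct * x - st * y, self.center[1] + st * x + ct * y],
            axis=-1,
        )

    def to_local(self, point: np.ndarray) -> np.ndarray:
        """Rotate/translate a point into the axis-aligned ellipse frame."""
        ct, st = math.cos(self.theta), math.sin(self.theta)
        dx = point[0] - self.center[0]
        dy = point[1] - self.center[1]
        return np.array([ct * dx + st * dy, -st * dx + ct * dy])


def fit_ellipse_lsq(points: np.ndarray) -> EllipseModel:
    """Direct algebraic least-squares ellipse fit (ellipse-constrained conic).

    Solves the stable generalized eigenproblem formulation of the direct
    least-squares conic fit with the ellipse constraint ``4AC - B^2 = 1``,
    then converts the conic to geometric center/axes/angle. At least six
    non-collinear points are required. A geometric (orthogonal-distance)
    refinement is intentionally not applied: the algebraic fit is
    deterministic and standard.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if pts.shape[0] < 6:
        raise EllipseFitError("need at least 6 points")
    mean = pts.mean(axis=0)
    x = pts[:, 0] - mean[0]
    y = pts[:, 1] - mean[1]
    # Halir-Flusser partitioned scatter matrices.
    d1 = np.column_stack([x * x, x * y, y * y])
    d2 = np.column_stack([x, y, np.ones_like(x)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError:
        raise EllipseFitError("degenerate configuration (collinear points?)")
    m = s1 + s2 @ t
    c1inv = np.array([[0.0, 0.0, 0.5], [0.0, -1.0, 0.0], [0.5, 0.0, 0.0]])
    m = c1inv @ m
    eigval, eigvec = np.linalg.eig(m)
    # The ellipse solution has 4AC - B^2 > 0.
    cond = 4.0 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    candidates = np.where((cond > 0) & np.isfinite(eigval))[0]
    if candidates.size == 0:
        raise EllipseFitError("best-fit conic is not an ellipse")
    a1 = np.real(eigvec[:, candidates[0]])
    a2 = t @ a1
    A, B, C = a1
    D, E, F = a2
    return _conic_to_ellipse(A, B, C, D, E, F, shift=mean)


def _conic_to_ellipse(
    A: float, B: float, C: float, D: float, E: float, F: float, shift=(0.0, 0.0)
) -> EllipseModel:
    """Convert ``Ax^2 + Bxy + Cy^2 + Dx + Ey + F = 0`` to geometric form."""
    disc = B * B - 4.0 * A * C
    if disc >= 0:
        raise EllipseFitError("conic is not an ellipse")
    x0 = (2.0 * C * D - B * E) / disc
    y0 = (2.0 * A * E - B * D) / disc
    # Conic value at the center; axes from the quadratic-form eigenvalues.
    f0 = A * x0 * x0 + B * x0 * y0 + C * y0 * y0 + D * x0 + E * y0 + F
    q = np.array([[A, B / 2.0], [B / 2.0, C]])
    eigval, eigvec = np.linalg.eigh(q)
    scale = -f0
    if scale == 0 or np.any(eigval * scale <= 0):
        raise EllipseFitError("degenerate conic")
    semi = np.sqrt(scale / eigval)  # semi-axis along each eigenvector
    order = np.argsort(semi)[::-1]  # major first
    a, b = float(semi[order[0]]), float(semi[order[1]])
    major = eigvec[:, order[0]]
    theta = math.atan2(major[1], major[0]) % math.pi
    return EllipseModel(
        center=(float(x0 + shift[0]), float(y0 + shift[1])), a=a, b=b, theta=theta
    )


def _arc_speed(ellipse: EllipseModel):
    a, b = ellipse.a, ellipse.b

    def speed(t: float) -> float:
        return math.hypot(a * math.sin(t), b * math.cos(t))

    return speed


def arc_length(ellipse: EllipseModel, t: float) -> float:
    """Arc length from the positive major-axis vertex (t=0) to angle ``t``.

    Computed by adaptive quadrature of the parametric speed; monotone in
    ``t`` by construction.
    """
    val, _ = integrate.quad(_arc_speed(ellipse), 0.0, t, limit=200)
    return val


def ellipse_perimeter(ellipse: EllipseModel) -> float:
    """Full circumference; the arc-length coordinate is cyclic modulo this."""
    return arc_length(ellipse, 2.0 * math.pi)


def arc_position(
    point: Sequence[float] | np.ndarray, ellipse: EllipseModel
) -> tuple[float, float]:
    """Perpendicular projection of a 2-D point onto the ellipse.

    Returns ``(arc, normal)``: the arc length (um) from the positive
    major-axis vertex to the foot point, increasing with parametric angle,
    and the signed perpendicular distance (positive outside the ellipse,
    negative inside). The foot point is found by bracketed 1-D minimization
    of the squared distance over the parametric angle. A point at the
    ellipse center has no unique projection and raises ``ValueError``.
    """
    p = ellipse.to_local(np.asarray(point, dtype=float))
    r = math.hypot(p[0], p[1])
    if r < 1e-12 * max(ellipse.a, 1.0):
        raise ValueError("point at ellipse center: projection ambiguous")
    a, b = ellipse.a, ellipse.b

    def sqdist(t: float) -> float:
        return (a * math.cos(t) - p[0]) ** 2 + (b * math.sin(t) - p[1]) ** 2

    # Coarse global scan, then local refinement around the best bracket.
    # The bracket may cross t = 0; the angle is reduced modulo 2*pi after.
    ts = np.linspace(0.0, 2.0 * math.pi, 720, endpoint=False)
    step = ts[1] - ts[0]
    d = (a * np.cos(ts) - p[0]) ** 2 + (b * np.sin(ts) - p[1]) ** 2
    i = int(np.argmin(d))
    res = optimize.minimize_scalar(
        sqdist,
        bounds=(ts[i] - step, ts[i] + step),
        method="bounded",
        options={"xatol": 1e-12},
    )
    t_star = float(res.x) % (2.0 * math.pi)
    if 2.0 * math.pi - t_star < 1e-9:
        t_star = 0.0
    foot = np.array([a * math.cos(t_star), b * math.sin(t_star)])
    dist = float(np.hypot(*(p - foot)))
    inside = (p[0] / a) ** 2 + (p[1] / b) ** 2 < 1.0
    return arc_length(ellipse, t_star), (-dist if inside else dist)
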
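"""3D spine geometry and analytic deformity indices.

A spine is an ordered chain of 18 vertebral poses (S1 caudal to T1 cephalad),
each a centroid plus a right-handed orthonormal frame.  Coordinate convention:
+Z cephalad, +X anterior, +Y patient-left (so a right thoracic curve has its
apex at negative Y relative to the CSVL).  All public angles are degrees.

The coronal Cobb angle is measured analytically: a smoothing spline is fitted
through the centroids, side-change points are located as sign changes of the
coronal curvature y''(z), and the angle is taken between the curve tangents at
the two side-change points bracketing the regional apex (which equals the
angle between their perpendiculars).  Where no side-change point exists above
(below) the apex, the T1 (S1) end of the curve bounds the arc instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import BSpline, make_smoothing_spline
from scipy.optimize import brentq

from .levels import CANONICAL_LEVELS, LEVEL_INDEX, LUMBAR_LEVELS, THORACIC_LEVELS

__all__ = [
    "GeometryError",
    "VertebraPose",
    "SpineShape",
    "ClinicalIndices",
    "SpinalCurve",
    "CobbMeasurement",
    "fit_spinal_curve",
    "fit_centroid_curve",
    "measure_cobb",
    "measure_sagittal",
    "measure_axial_rotation",
    "csvl",
    "find_apex",
    "measure_indices",
]

_DEG = 180.0 / np.pi

#: lateral deviations below this (mm) are treated as a straight region
LATERAL_FLOOR_MM = 2.0

#: default residual bound (mm) the smoothing spline must satisfy
MAX_CENTROID_RESIDUAL_MM = 3.0

DEFAULT_KYPHOSIS_LEVELS = ("T1", "T12")
DEFAULT_LORDOSIS_LEVELS = ("L1", "S1")


class GeometryError(ValueError):
    """Invalid or degenerate spinal geometry."""


@dataclass(frozen=True)
class VertebraPose:
    """One vertebra: centroid (mm, global frame) and orthonormal local triad."""

    label: str
    centroid: np.ndarray
    anterior: np.ndarray
    left: np.ndarray
    up: np.ndarray

    def __post_init__(self) -> None:
        if self.label not in LEVEL_INDEX:
            raise GeometryError(f"unknown vertebral label {self.label!r}")
        for name in ("centroid", "anterior", "left", "up"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise GeometryError(f"{name} of {self.label} must be a finite 3-vector")
            object.__setattr__(self, name, v)
        axes = np.stack([self.anterior, self.left, self.up])
        gram = axes @ axes.T
        if not np.allclose(gram, np.eye(3), atol=1e-6):
            raise GeometryError(f"frame of {self.label} is not orthonormal")
        if np.dot(np.cross(self.anterior, self.left), self.up) < 0:
            raise GeometryError(f"frame of {self.label} is left-handed")

    @property
    def frame(self) -> np.ndarray:
        """3x3 matrix with columns (anterior, left, up)."""
        return np.column_stack([self.anterior, self.left, self.up])


def identity_frame() -> dict:
    return dict(
        anterior=np.array([1.0, 0.0, 0.0]),
        left=np.array([0.0, 1.0, 0.0]),
        up=np.array([0.0, 0.0, 1.0]),
    )


@dataclass(frozen=True)
class SpineShape:
    """Ordered vertebral poses S1..T1 for one patient in one posture."""

    patient_id: str
    posture: str
    vertebrae: tuple[VertebraPose, ...]
    body_mass: Optional[float] = None

    def __post_init__(self) -> None:
        labels = tuple(v.label for v in self.vertebrae)
        if labels != CANONICAL_LEVELS:
            raise GeometryError(
                "SpineShape requires exactly the 18 canonical levels S1..T1 in order"
            )
        object.__setattr__(self, "vertebrae", tuple(self.vertebrae))
        z = self.z
        dz = np.diff(z)
        if np.any(dz <= 0):
            raise GeometryError("vertebral cephalad coordinates must strictly increase")
        spacing = np.linalg.norm(np.diff(self.centroids, axis=0), axis=1)
        if np.any(spacing < 10.0) or np.any(spacing > 60.0):
            raise GeometryError(
                f"consecutive centroid spacing outside [10, 60] mm: "
                f"min {spacing.min():.1f}, max {spacing.max():.1f}"
            )

    @property
    def centroids(self) -> np.ndarray:
        return np.stack([v.centroid for v in self.vertebrae])

    @property
    def x(self) -> np.ndarray:
        return self.centroids[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.centroids[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.centroids[:, 2]

    def vertebra(self, label: str) -> VertebraPose:
        return self.vertebrae[LEVEL_INDEX[label]]

    def level_z(self, label: str) -> float:
        return float(self.vertebra(label).centroid[2])

    def with_centroids(
        self, centroids: np.ndarray, posture: Optional[str] = None
    ) -> "SpineShape":
        """Copy with replaced centroids (frames kept)."""
        vs = tuple(
            replace(v, centroid=np.asarray(c, dtype=float))
            for v, c in zip(self.vertebrae, centroids)
        )
        return SpineShape(
            patient_id=self.patient_id,
            posture=posture or self.posture,
            vertebrae=vs,
            body_mass=self.body_mass,
        )


@dataclass
class ClinicalIndices:
    """The scalar deformity indices reported for one posture."""

    cobb_thoracic: float
    cobb_lumbar: float
    kyphosis: float
    lordosis: float
    apical_rotation_thoracic: Optional[float]
    apex_thoracic: Optional[str]
    apex_lumbar: Optional[str]
    side_change_levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("cobb_thoracic", "cobb_lumbar", "kyphosis", "lordosis"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise GeometryError(f"{name} must be finite")
        for name in ("cobb_thoracic", "cobb_lumbar"):
            v = getattr(self, name)
            if not (0.0 <= v < 120.0):
                raise GeometryError(f"{name}={v:.1f} outside [0, 120)")

    def to_dict(self) -> dict:
        return {
            "cobb_thoracic": self.cobb_thoracic,
            "cobb_lumbar": self.cobb_lumbar,
            "kyphosis": self.kyphosis,
            "lordosis": self.lordosis,
            "apical_rotation_thoracic": self.apical_rotation_thoracic,
            "apex_thoracic": self.apex_thoracic,
            "apex_lumbar": self.apex_lumbar,
            "side_change_levels": list(self.side_change_levels),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class SpinalCurve:
    """Smooth twice-differentiable curve through the vertebral centroids.

    ``sy`` and ``sx`` map the cephalad coordinate z to coronal (patient-left)
    and sagittal (anterior) deviation, respectively.  Both are penalized
    natural cubic smoothing splines, which depend continuously on the data
    and the smoothing parameter (no discrete knot selection).
    """

    sy: BSpline
    sx: BSpline
    z_nodes: np.ndarray
    smoothing: float
    level_z: dict = field(default_factory=dict)
    csvl_xy: tuple[float, float] = (0.0, 0.0)

    @property
    def z_min(self) -> float:
        return float(self.z_nodes[0])

    @property
    def z_max(self) -> float:
        return float(self.z_nodes[-1])

    def y(self, z):
        return self.sy(z)

    def x(self, z):
        return self.sx(z)

    def dy(self, z):
        return self.sy.derivative(1)(z)

    def dx(self, z):
        return self.sx.derivative(1)(z)

    def d2y(self, z):
        return self.sy.derivative(2)(z)

    def lateral_deviation(self, z):
        """Coronal deviation from the CSVL (positive = patient-left)."""
        return self.sy(z) - self.csvl_xy[1]

    def max_residual(self, y_nodes: np.ndarray, x_nodes: np.ndarray) -> float:
        ry = np.abs(self.sy(self.z_nodes) - y_nodes)
        rx = np.abs(self.sx(self.z_nodes) - x_nodes)
        return float(max(ry.max(), rx.max()))


@dataclass
class CobbMeasurement:
    angle: float
    apex: Optional[str]
    bounds: Optional[tuple[float, float]]
    flagged: bool = False

    def __iter__(self):
        return iter((self.angle, self.apex, self.bounds))


def csvl(spine: SpineShape) -> tuple[float, float]:
    """Transverse coordinates (x0, y0) of the Central Sacral Vertical Line."""
    c = spine.vertebra("S1").centroid
    return float(c[0]), float(c[1])


DEFAULT_SMOOTHING_LAM = 100.0


def _pad_quadratic(z: np.ndarray, v: np.ndarray, n_ghost: int = 2) -> tuple:
    """Extend the data at both ends with quadratically extrapolated ghost
    points, so the spline's natural boundary condition (zero end curvature)
    acts outside the measured range and does not flatten the end tangents."""
    h0, h1 = z[1] - z[0], z[-1] - z[-2]
    z_lo = z[0] - h0 * np.arange(n_ghost, 0, -1)
    z_hi = z[-1] + h1 * np.arange(1, n_ghost + 1)
    p_lo = np.polynomial.polynomial.polyfit(z[:4], v[:4], 2)
    p_hi = np.polynomial.polynomial.polyfit(z[-4:], v[-4:], 2)
    v_lo = np.polynomial.polynomial.polyval(z_lo, p_lo)
    v_hi = np.polynomial.polynomial.polyval(z_hi, p_hi)
    return np.concatenate([z_lo, z, z_hi]), np.concatenate([v_lo, v, v_hi])


def fit_centroid_curve(
    centroids: np.ndarray, smoothing: Optional[float] = None
) -> SpinalCurve:
    """Fit a SpinalCurve through a bare (18, 3) centroid array.

    Used where a deformed configuration must be re-measured without the
    SpineShape invariants (e.g. linear extrapolation at extreme stiffness
    scales during calibration).
    """
    centroids = np.asarray(centroids, dtype=float)
    z, y, x = centroids[:, 2], centroids[:, 1], centroids[:, 0]
    if np.any(np.diff(z) <= 0):
        raise GeometryError("cephalad coordinate must be strictly increasing")
    auto = smoothing is None
    lam = DEFAULT_SMOOTHING_LAM if auto else float(smoothing)
    if lam < 0:
        raise GeometryError("smoothing must be non-negative")
    x0, y0 = float(x[0]), float(y[0])
    level_z = {lab: float(zi) for lab, zi in zip(CANONICAL_LEVELS, z)}
    z_ext, y_ext = _pad_quadratic(z, y)
    _, x_ext = _pad_quadratic(z, x)
    for _ in range(20):
        curve = SpinalCurve(
            sy=make_smoothing_spline(z_ext, y_ext, lam=lam),
            sx=make_smoothing_spline(z_ext, x_ext, lam=lam),
            z_nodes=z,
            smoothing=lam,
            level_z=level_z,
            csvl_xy=(x0, y0),
        )
        if not auto or curve.max_residual(y, x) <= MAX_CENTROID_RESIDUAL_MM:
            return curve
        lam *= 0.5
        if lam < 1e-9:
            lam = 0.0
    return curve


def fit_spinal_curve(spine: SpineShape, smoothing: Optional[float] = None) -> SpinalCurve:
    """Fit penalized cubic smoothing splines y(z), x(z) through the centroids.

    ``smoothing`` is the curvature-penalty weight (0 interpolates).  When
    omitted, the default is halved until the maximum centroid residual is
    below 3 mm (the default already keeps smooth spines well under 0.1 mm).
    """
    return fit_centroid_curve(spine.centroids, smoothing)


def _region_window(curve: SpinalCurve, region: str) -> tuple[float, float]:
    lz = curve.level_z
    if region == "thoracic":
        return lz["T12"], lz["T1"]
    if region == "lumbar":
        return lz["S1"], lz["T12"]
    raise GeometryError(f"unknown region {region!r}")


def _region_levels(region: str) -> Sequence[str]:
    return THORACIC_LEVELS if region == "thoracic" else LUMBAR_LEVELS


def _sign_change_roots(fun, grid: np.ndarray) -> list[float]:
    vals = fun(grid)
    roots = []
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            roots.append(float(grid[i]))
        elif a * b < 0.0:
            roots.append(float(brentq(fun, grid[i], grid[i + 1])))
    return roots


def _simplified_extrema(curve: SpinalCurve, grid: np.ndarray) -> list[tuple[float, float]]:
    """Extrema of the coronal deviation, with sub-millimetre wiggles merged.

    Adjacent extremum pairs whose deviation swing is below 1 mm are dropped so
    that fit noise cannot split one anatomical arc into several.
    """
    pts = [
        (zr, float(curve.lateral_deviation(zr)))
        for zr in _sign_change_roots(curve.dy, grid)
    ]
    changed = True
    while changed and len(pts) >= 2:
        changed = False
        for i in range(len(pts) - 1):
            if abs(pts[i][1] - pts[i + 1][1]) < 1.0:
                del pts[i : i + 2]
                changed = True
                break
    return pts


def _steepest_tangent(curve: SpinalCurve, z_a: float, z_b: float) -> float:
    """z of maximal |dy/dz| on [z_a, z_b] (a curvature zero when interior)."""
    if z_b - z_a < 1e-9:
        return z_a
    grid = np.linspace(z_a, z_b, max(int((z_b - z_a) / 0.5), 8))
    slopes = np.abs(curve.dy(grid))
    return float(grid[np.argmax(slopes)])


def measure_cobb(
    curve: SpinalCurve, region: str, apex_hint: Optional[float] = None
) -> CobbMeasurement:
    """Cobb angle of the thoracic or lumbar arc, from curve tangents.

    The regional apex is the extremum of |lateral deviation| in the region;
    the arc is delimited against each neighbouring arc at the point of
    minimal |deviation| between the apexes, and each bound is the side-change
    point realized as the tangent extremum within the arc (the curve end
    serves as bound where no neighbouring arc exists).  The angle is the
    unsigned difference of the tangent angles at the two bounds, equal to the
    angle between their perpendiculars.  Regions with lateral deviation below
    2 mm everywhere return angle 0, flagged.

    ``apex_hint`` (a z position) selects the arc nearest the hint instead of
    the largest one — used when re-measuring a deformed posture so the same
    anatomical arc is tracked even if an over-corrected mirror arc appears.
    """
    z_lo, z_hi = _region_window(curve, region)
    grid_full = np.linspace(curve.z_min, curve.z_max, 1501)
    window = np.linspace(z_lo, z_hi, 601)
    dev = curve.lateral_deviation(window)
    if np.max(np.abs(dev)) < LATERAL_FLOOR_MM:
        return CobbMeasurement(angle=0.0, apex=None, bounds=None, flagged=True)

    extrema = _simplified_extrema(curve, grid_full)
    in_window = [p for p in extrema if z_lo - 1e-9 <= p[0] <= z_hi + 1e-9]
    if in_window and apex_hint is not None:
        z_apex = min(in_window, key=lambda p: abs(p[0] - apex_hint))[0]
    elif in_window:
        z_apex = max(in_window, key=lambda p: abs(p[1]))[0]
    else:  # monotone deviation in window: take the grid extremum
        z_apex = float(window[np.argmax(np.abs(dev))])

    below = [p[0] for p in extrema if p[0] < z_apex - 1e-9]
    above = [p[0] for p in extrema if p[0] > z_apex + 1e-9]

    def divider(z_neighbor: float) -> float:
        lo, hi = sorted((z_neighbor, z_apex))
        grid = np.linspace(lo, hi, max(int((hi - lo) / 0.5), 8))
        return float(grid[np.argmin(np.abs(curve.lateral_deviation(grid)))])

    z_div_low = divider(max(below)) if below else curve.z_min
    z_div_up = divider(min(above)) if above else curve.z_max
    z_low = _steepest_tangent(curve, z_div_low, z_apex)
    z_up = _steepest_tangent(curve, z_apex, z_div_up)

    slope_low = float(curve.dy(z_low))
    slope_up = float(curve.dy(z_up))
    angle = abs(np.arctan(slope_up) - np.arctan(slope_low)) * _DEG

    apex_level = _apex_level_in(curve, region, z_div_low, z_div_up)
    return CobbMeasurement(angle=float(angle), apex=apex_level, bounds=(z_low, z_up))


def _apex_level_in(
    curve: SpinalCurve, region: str, z_low: float, z_up: float
) -> Optional[str]:
    best, best_dev = None, -np.inf
    for lab in reversed(_region_levels(region)):  # cephalad first: wins ties
        zl = curve.level_z[lab]
        if not (z_low - 1e-9 <= zl <= z_up + 1e-9):
            continue
        d = abs(float(curve.lateral_deviation(zl)))
        if d > best_dev + 1e-12:
            best, best_dev = lab, d
    if best is None:  # arc bounds exclude all region centroids; use window max
        for lab in reversed(_region_levels(region)):
            d = abs(float(curve.lateral_deviation(curve.level_z[lab])))
            if d > best_dev + 1e-12:
                best, best_dev = lab, d
    return best


def find_apex(curve: SpinalCurve, region: str) -> str:
    """Level with maximal |lateral deviation from CSVL| in the region.

    Ties break toward the more cephalad level.  Raises on regions flagged
    straight (below the 2 mm measurement floor).
    """
    z_lo, z_hi = _region_window(curve, region)
    window = np.linspace(z_lo, z_hi, 601)
    if np.max(np.abs(curve.lateral_deviation(window))) < LATERAL_FLOOR_MM:
        raise GeometryError(f"{region} region is straight; apex undefined")
    best, best_dev = None, -np.inf
    for lab in reversed(_region_levels(region)):
        d = abs(float(curve.lateral_deviation(curve.level_z[lab])))
        if d > best_dev + 1e-12:
            best, best_dev = lab, d
    return best


def measure_sagittal(
    curve: SpinalCurve,
    kyphosis_levels: tuple[str, str] = DEFAULT_KYPHOSIS_LEVELS,
    lordosis_levels: tuple[str, str] = DEFAULT_LORDOSIS_LEVELS,
) -> tuple[float, float]:
    """Kyphosis and lordosis as unsigned sagittal tangent-angle differences."""

    def tangent_angle_diff(levels: tuple[str, str]) -> float:
        a, b = levels
        if a == b:
            raise GeometryError("sagittal measurement levels must differ")
        za, zb = curve.level_z[a], curve.level_z[b]
        return abs(
            np.arctan(float(curve.dx(za))) - np.arctan(float(curve.dx(zb)))
        ) * _DEG

    return tangent_angle_diff(kyphosis_levels), tangent_angle_diff(lordosis_levels)


def measure_axial_rotation(vertebra: VertebraPose) -> float:
    """Signed axial rotation (deg) of the vertebra about the vertical axis.

    The local anterior axis is projected onto the global transverse plane and
    compared with global anterior (+X).  Positive = rotated toward the
    patient's right (-Y); range (-180, 180].
    """
    ax, ay = float(vertebra.anterior[0]), float(vertebra.anterior[1])
    if np.hypot(ax, ay) < 1e-6:
        raise GeometryError(
            f"anterior axis of {vertebra.label} is vertical; rotation undefined"
        )
    ang = np.degrees(np.arctan2(-ay, ax))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def measure_indices(
    spine: SpineShape,
    smoothing: Optional[float] = None,
    kyphosis_levels: tuple[str, str] = DEFAULT_KYPHOSIS_LEVELS,
    lordosis_levels: tuple[str, str] = DEFAULT_LORDOSIS_LEVELS,
    apex_hints: Optional[dict] = None,
) -> ClinicalIndices:
    """Full set of deformity indices for one posture.

    ``apex_hints`` maps region name to a z position and pins each region's
    apex search to the arc nearest that position (see ``measure_cobb``).
    """
    curve = fit_spinal_curve(spine, smoothing)
    hints = apex_hints or {}
    thoracic = measure_cobb(curve, "thoracic", apex_hint=hints.get("thoracic"))
    lumbar = measure_cobb(curve, "lumbar", apex_hint=hints.get("lumbar"))
    kyph, lord = measure_sagittal(curve, kyphosis_levels, lordosis_levels)
    rotation = None
    if thoracic.apex is not None:
        rotation = measure_axial_rotation(spine.vertebra(thoracic.apex))
    side_levels = []
    for meas in (lumbar, thoracic):
        if meas.bounds:
            for zb in meas.bounds:
                lab = min(CANONICAL_LEVELS, key=lambda L: abs(curve.level_z[L] - zb))
                if lab not in side_levels:
                    side_levels.append(lab)
    return ClinicalIndices(
        cobb_thoracic=thoracic.angle,
        cobb_lumbar=lumbar.angle,
        kyphosis=kyph,
        lordosis=lord,
        apical_rotation_thoracic=rotation,
        apex_thoracic=thoracic.apex,
        apex_lumbar=lumbar.apex,
        side_change_levels=tuple(side_levels),
    )
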
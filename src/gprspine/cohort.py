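"""Synthetic scoliotic cohort generator.

Emulates a right-thoracic (or double-major with right thoracic component)
adolescent cohort: thoracic Cobb 33 +/- 9 deg on [11, 45], lumbar Cobb mean
27 deg on [13, 42], kyphosis mean 30 deg on [10, 47], lordosis mean 70 deg on
[57, 85], apical axial rotation 11 +/- 9 deg on [-6, 22].  Parameters are
drawn from hard-truncated normals (sd = range/4 where only mean and range are
known); each drawn spine is built so that re-measuring it with the analytic
pipeline reproduces the drawn indices (Cobb within 1 deg, sagittal within
2 deg).

Geometry template: S1 at the origin, 17 segment lengths linearly decreasing
38 -> 22 mm cephalad, parameterized by arclength so the spacing invariant
holds at any curvature.  The coronal profile is a piecewise-smoothstep
deviation chain realizing a thoracic and a lumbar arc of opposite sign
(right thoracic => apex at negative Y); the sagittal profile integrates a
smoothstep tangent-angle distribution with a balance constant chosen so T1
stands over S1.  Vertebral frames carry pure axial rotations proportional to
the local lateral deviation, peaking at the drawn apical rotation at the
thoracic apex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .geometry import (
    GeometryError,
    SpinalCurve,
    SpineShape,
    VertebraPose,
    csvl,
    find_apex,
    fit_spinal_curve,
    measure_cobb,
    measure_sagittal,
)
from .levels import CANONICAL_LEVELS

__all__ = [
    "ParamSpec",
    "CohortParams",
    "PatientDraw",
    "SelfCorrectionTargets",
    "LevelTarget",
    "draw_patient",
    "generate_spine",
    "generate_cohort",
    "generate_self_correction_targets",
    "template_z",
]

class ConvergenceError(RuntimeError):
    """The generator's scaling loop failed to reach the drawn indices."""


@dataclass(frozen=True)
class ParamSpec:
    """Mean / sd / hard range of one cohort parameter (degrees)."""

    mean: float
    sd: Optional[float]
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (self.lo <= self.mean <= self.hi):
            raise ValueError(f"range [{self.lo}, {self.hi}] must contain mean {self.mean}")
        if self.sd is not None and self.sd <= 0:
            raise ValueError("sd must be positive")

    @property
    def effective_sd(self) -> float:
        # range/4 when the cohort description gives only mean and range
        return self.sd if self.sd is not None else (self.hi - self.lo) / 4.0


@dataclass(frozen=True)
class CohortParams:
    n: int = 16
    thoracic_cobb: ParamSpec = field(default=ParamSpec(33.0, 9.0, 11.0, 45.0))
    lumbar_cobb: ParamSpec = field(default=ParamSpec(27.0, None, 13.0, 42.0))
    kyphosis: ParamSpec = field(default=ParamSpec(30.0, None, 10.0, 47.0))
    lordosis: ParamSpec = field(default=ParamSpec(70.0, None, 57.0, 85.0))
    apical_rotation: ParamSpec = field(default=ParamSpec(11.0, 9.0, -6.0, 22.0))
    thoracic_apex_levels: tuple[str, ...] = ("T7", "T8", "T9")
    lumbar_apex_levels: tuple[str, ...] = ("L1", "L2", "L3")
    body_mass: ParamSpec = field(default=ParamSpec(50.0, 7.0, 35.0, 70.0))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass(frozen=True)
class PatientDraw:
    thoracic_cobb: float
    lumbar_cobb: float
    kyphosis: float
    lordosis: float
    apical_rotation: float
    thoracic_apex: str
    lumbar_apex: str
    body_mass: float = 50.0


@dataclass(frozen=True)
class LevelTarget:
    level: str
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("target coordinates must be finite")


@dataclass(frozen=True)
class SelfCorrectionTargets:
    """Transverse (x, y) target positions for T1 and the two apical vertebrae."""

    t1: LevelTarget
    thoracic_apex: LevelTarget
    lumbar_apex: LevelTarget
    source: str = "synthetic"

    def __post_init__(self) -> None:
        levels = {self.t1.level, self.thoracic_apex.level, self.lumbar_apex.level}
        if len(levels) != 3:
            raise ValueError("target levels must be distinct")

    def as_dict(self) -> dict:
        return {
            t.level: (t.x, t.y)
            for t in (self.t1, self.thoracic_apex, self.lumbar_apex)
        }


def template_z() -> np.ndarray:
    """Cephalad coordinates of S1..T1: segments linearly decreasing 38->22 mm."""
    seg = np.linspace(38.0, 22.0, 17)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _truncnorm_rv(rng: np.random.Generator, spec: ParamSpec) -> float:
    sd = spec.effective_sd
    a, b = (spec.lo - spec.mean) / sd, (spec.hi - spec.mean) / sd
    return float(truncnorm.rvs(a, b, loc=spec.mean, scale=sd, random_state=rng))


def _apex_pair_feasible(
    theta_t: float, theta_l: float, s_al: float, s_at: float, level_s: dict
) -> bool:
    """Whether the drawn Cobb pair is realizable with these apex levels.

    Adjacent arcs share flank tangents, so a large curve next to a small one
    puts a floor on the small curve's measurable angle; and every flank needs
    enough arclength to be resolved at vertebral sampling.
    """
    s_c, s_e = _coronal_geometry(level_s, s_al, s_at, theta_t, theta_l)
    d1, d2 = s_al, s_c - s_al
    d3, d4 = s_at - s_c, s_e - s_at
    if min(d2, d3, d4) < 40.0:
        return False
    if theta_l * d1 / (d1 + d2) > 0.65 * theta_t:
        return False
    return True


def draw_patient(params: CohortParams, rng: np.random.Generator) -> PatientDraw:
    """One patient's parameter draw.

    Apex levels are drawn uniformly among the feasible (thoracic, lumbar)
    pairs for the drawn Cobb angles; when no pair is feasible (strongly
    lumbar-dominant combinations that a right-thoracic-major cohort does not
    contain), the lumbar Cobb is redrawn.
    """
    s = template_z()
    level_s = {lab: float(si) for lab, si in zip(CANONICAL_LEVELS, s)}
    theta_t = _truncnorm_rv(rng, params.thoracic_cobb)
    for _ in range(500):
        theta_l = _truncnorm_rv(rng, params.lumbar_cobb)
        combos = [
            (ta, la)
            for ta in params.thoracic_apex_levels
            for la in params.lumbar_apex_levels
            if _apex_pair_feasible(theta_t, theta_l, level_s[la], level_s[ta], level_s)
        ]
        if combos:
            apex_t, apex_l = combos[int(rng.integers(len(combos)))]
            break
    else:
        raise ConvergenceError(
            f"no feasible apex pair for thoracic Cobb {theta_t:.1f}"
        )
    return PatientDraw(
        thoracic_cobb=theta_t,
        lumbar_cobb=theta_l,
        kyphosis=_truncnorm_rv(rng, params.kyphosis),
        lordosis=_truncnorm_rv(rng, params.lordosis),
        apical_rotation=_truncnorm_rv(rng, params.apical_rotation),
        thoracic_apex=apex_t,
        lumbar_apex=apex_l,
        body_mass=_truncnorm_rv(rng, params.body_mass),
    )


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _coronal_geometry(
    level_s: dict,
    s_apex_l: float,
    s_apex_t: float,
    theta_t_deg: float,
    theta_l_deg: float,
) -> tuple:
    """Breakpoints of the coronal deviation profile.

    The arc crossing sits near the thoracolumbar junction.  The thoracic
    arc's upper end is placed so its lower-flank tangent angle stays below
    ~70% of the lumbar target: the lower-flank tangent is shared with the
    lumbar arc's upper bound, so a large thoracic curve would otherwise put a
    floor on the measurable lumbar Cobb angle.
    """
    s_c = 0.5 * (s_apex_l + s_apex_t)
    s_c = float(np.clip(s_c, s_apex_l + 25.0, level_s["T12"] + 15.0))
    ang_lo = np.radians(min(0.5 * theta_t_deg, 0.7 * theta_l_deg))
    ang_hi = np.radians(theta_t_deg) - ang_lo
    ratio = np.tan(ang_lo) / np.tan(ang_hi)
    s_e = s_apex_t + float(np.clip(ratio, 0.25, 1.3)) * (s_apex_t - s_c)
    s_e = min(s_e, level_s["T1"] - 5.0)
    return s_c, s_e


def _deviation_amplitude(theta_deg: float, gap_lo: float, gap_hi: float) -> float:
    # first-order inverse of theta = atan(1.5 D/gap_lo) + atan(1.5 D/gap_hi)
    return np.tan(np.radians(theta_deg) / 2.0) * (
        2.0 * gap_lo * gap_hi / (1.5 * (gap_lo + gap_hi))
    )


def _coronal_deviation_profile(
    sg: np.ndarray,
    level_s: dict,
    s_apex_t: float,
    s_apex_l: float,
    dev_l: float,
    dev_t: float,
    breaks: tuple[float, float],
) -> np.ndarray:
    """Coronal deviation y(s) of a right-thoracic double curve.

    Four smoothstep pieces: rise to +dev_l at the lumbar apex, fall to zero
    at the arc crossing, dip to -dev_t at the thoracic apex (patient-right),
    return to the CSVL below T1.  Each piece's tangent extremum sits at its
    midpoint, so the side-change points bracketing either apex depend only on
    that arc's own amplitude — the two Cobb angles stay decoupled even for
    very unbalanced curve pairs.
    """
    s_c, s_e = breaks
    y = np.zeros_like(sg)
    pieces = [
        (level_s["S1"], s_apex_l, 0.0, dev_l),
        (s_apex_l, s_c, dev_l, 0.0),
        (s_c, s_apex_t, 0.0, -dev_t),
        (s_apex_t, s_e, -dev_t, 0.0),
    ]
    for s0, s1, y0, y1 in pieces:
        mask = (sg >= s0) & (sg <= s1)
        t = (sg[mask] - s0) / (s1 - s0)
        y[mask] = y0 + (y1 - y0) * _smoothstep(t)
    return y


def _build_centroids(
    s_levels: np.ndarray,
    level_s: dict,
    s_apex_t: float,
    s_apex_l: float,
    dev_l: float,
    dev_t: float,
    breaks: tuple[float, float],
    K_deg: float,
    Lo_deg: float,
) -> np.ndarray:
    """Integrate unit tangents along the arclength template.

    The sagittal tangent angle follows smoothstep transitions over the
    lordotic (S1->L1) and kyphotic (T12->T1) spans, offset by a balance
    constant so T1 stands over S1; the coronal deviation follows the
    piecewise-smoothstep double-curve profile above.  Parameterizing by
    arclength keeps every consecutive centroid spacing at its template value
    regardless of how steep the drawn curvatures are.
    """
    s_total = float(s_levels[-1])
    sg = np.linspace(0.0, s_total, 801)
    # sagittal: steep anterior tilt at the sacrum decaying over the lordotic
    # span, kyphotic rise over the thoracic span
    u_l = 1.0 - _smoothstep((sg - level_s["S1"]) / (level_s["L1"] - level_s["S1"]))
    u_k = _smoothstep((sg - level_s["T12"]) / (level_s["T1"] - level_s["T12"]))
    phi_shape = np.radians(Lo_deg) * u_l + np.radians(K_deg) * u_k
    y_profile = _coronal_deviation_profile(
        sg, level_s, s_apex_t, s_apex_l, dev_l, dev_t, breaks
    )
    m = np.gradient(y_profile, sg)
    c_lo = -1.40
    c_hi = 1.40 - float(np.max(phi_shape))
    if c_hi <= c_lo:
        raise GeometryError("sagittal profile too steep to balance")

    def net_anterior_offset(c: float) -> float:
        tx = np.tan(phi_shape + c)
        norm = np.sqrt(1.0 + tx**2 + m**2)
        return float(np.trapezoid(tx / norm, sg))

    c = brentq(net_anterior_offset, c_lo, c_hi)
    tx = np.tan(phi_shape + c)
    norm = np.sqrt(1.0 + tx**2 + m**2)
    xg = cumulative_trapezoid(tx / norm, sg, initial=0.0)
    yg = cumulative_trapezoid(m / norm, sg, initial=0.0)
    zg = cumulative_trapezoid(1.0 / norm, sg, initial=0.0)
    return np.column_stack(
        [np.interp(s_levels, sg, xg), np.interp(s_levels, sg, yg), np.interp(s_levels, sg, zg)]
    )


def _axial_frames(
    centroids: np.ndarray, rho_deg: float, apex_index: int
) -> list[VertebraPose]:
    y = centroids[:, 1]
    dev = y - y[0]
    apex_dev = dev[apex_index]
    scale = 0.0 if abs(apex_dev) < 1e-9 else 1.0 / apex_dev
    vertebrae = []
    for lab, c, d in zip(CANONICAL_LEVELS, centroids, dev):
        r = np.radians(rho_deg * d * scale)
        # positive rotation = anterior axis toward patient-right (-Y)
        vertebrae.append(
            VertebraPose(
                label=lab,
                centroid=c,
                anterior=np.array([np.cos(r), -np.sin(r), 0.0]),
                left=np.array([np.sin(r), np.cos(r), 0.0]),
                up=np.array([0.0, 0.0, 1.0]),
            )
        )
    return vertebrae


def generate_spine(
    params: CohortParams,
    draw: PatientDraw,
    patient_id: str = "SYN01",
    max_iter: int = 50,
) -> SpineShape:
    """Build one spine whose measured indices match the drawn ones.

    The thoracic/lumbar coronal amplitudes and the sagittal angle scales are
    adjusted multiplicatively until ``measure_cobb`` returns the drawn Cobb
    angles within 1 deg and ``measure_sagittal`` the drawn kyphosis/lordosis
    within 2 deg.
    """
    for name, spec in (
        ("thoracic_cobb", params.thoracic_cobb),
        ("lumbar_cobb", params.lumbar_cobb),
        ("kyphosis", params.kyphosis),
        ("lordosis", params.lordosis),
        ("apical_rotation", params.apical_rotation),
    ):
        v = getattr(draw, name)
        if not (spec.lo - 1e-9 <= v <= spec.hi + 1e-9):
            raise ValueError(
                f"drawn {name}={v:.1f} outside the cohort range [{spec.lo}, {spec.hi}]"
            )

    s = template_z()
    level_s = {lab: float(si) for lab, si in zip(CANONICAL_LEVELS, s)}
    s_at, s_al = level_s[draw.thoracic_apex], level_s[draw.lumbar_apex]
    breaks = _coronal_geometry(
        level_s, s_al, s_at, draw.thoracic_cobb, draw.lumbar_cobb
    )
    s_c, s_e = breaks
    dev_l = _deviation_amplitude(draw.lumbar_cobb, s_al, s_c - s_al)
    dev_t = _deviation_amplitude(draw.thoracic_cobb, s_at - s_c, s_e - s_at)
    k_scale, lo_scale = 1.0, 1.0
    damp = 0.6  # damps the period-2 cycles a full multiplicative step excites
    best_centroids, best_score = None, np.inf

    for _ in range(max_iter):
        centroids = _build_centroids(
            s, level_s, s_at, s_al, dev_l, dev_t, breaks,
            k_scale * draw.kyphosis, lo_scale * draw.lordosis,
        )
        spine = SpineShape(
            patient_id=patient_id,
            posture="reference",
            vertebrae=tuple(
                VertebraPose(label=lab, centroid=c, **_identity_axes())
                for lab, c in zip(CANONICAL_LEVELS, centroids)
            ),
            body_mass=draw.body_mass,
        )
        curve = fit_spinal_curve(spine)
        th = measure_cobb(curve, "thoracic").angle
        lu = measure_cobb(curve, "lumbar").angle
        kyph, lord = measure_sagittal(curve)
        score = max(
            abs(th - draw.thoracic_cobb),
            abs(lu - draw.lumbar_cobb),
            0.5 * abs(kyph - draw.kyphosis),
            0.5 * abs(lord - draw.lordosis),
        )
        if score < best_score:
            best_centroids, best_score = centroids, score
        if (
            abs(th - draw.thoracic_cobb) <= 0.5
            and abs(lu - draw.lumbar_cobb) <= 0.5
            and abs(kyph - draw.kyphosis) <= 1.0
            and abs(lord - draw.lordosis) <= 1.0
        ):
            break
        dev_t *= (draw.thoracic_cobb / max(th, 0.5)) ** damp
        dev_l *= (draw.lumbar_cobb / max(lu, 0.5)) ** damp
        k_scale *= (draw.kyphosis / max(kyph, 0.5)) ** damp
        lo_scale *= (draw.lordosis / max(lord, 0.5)) ** damp
    else:
        # measurement discontinuities can trap the loop in a limit cycle
        # straddling the fixed point; the best iterate is accepted as long as
        # it still meets the 1 deg Cobb / 2 deg sagittal contract
        if best_score > 0.9:
            raise ConvergenceError(
                f"generator did not converge in {max_iter} iterations for "
                f"{patient_id} (best error {best_score:.2f} deg)"
            )
        centroids = best_centroids

    apex_index = CANONICAL_LEVELS.index(draw.thoracic_apex)
    vertebrae = _axial_frames(centroids, draw.apical_rotation, apex_index)
    return SpineShape(
        patient_id=patient_id,
        posture="reference",
        vertebrae=tuple(vertebrae),
        body_mass=draw.body_mass,
    )


def _identity_axes() -> dict:
    return dict(
        anterior=np.array([1.0, 0.0, 0.0]),
        left=np.array([0.0, 1.0, 0.0]),
        up=np.array([0.0, 0.0, 1.0]),
    )


def generate_cohort(params: CohortParams) -> list[SpineShape]:
    """n spines from truncated-normal draws; deterministic under the seed."""
    rng = np.random.default_rng(params.seed)
    spines = []
    for i in range(params.n):
        draw = draw_patient(params, rng)
        spines.append(generate_spine(params, draw, patient_id=f"SYN{i + 1:02d}"))
    return spines


def _target_shape(
    spine: SpineShape,
    curve: SpinalCurve,
    apex_t: str,
    apex_l: str,
    gamma: float,
    t1_pull: float,
) -> SpineShape:
    """Reference shape with the thoracic arc flattened toward the CSVL.

    Every centroid above the arc crossing moves a fraction ``gamma`` of its
    CSVL offset (smoothly blended in from zero at the lumbar apex), plus a
    T1-righting term that brings T1 to a fraction ``t1_pull`` of its own
    offset; gamma = 1 flattens the whole thoracic arc onto the CSVL.
    """
    _, y0 = csvl(spine)
    z = spine.z
    z_al, z_at = curve.level_z[apex_l], curve.level_z[apex_t]
    z_t1 = curve.level_z["T1"]
    grid = np.linspace(z_al, z_at, 200)
    z_x = float(grid[np.argmin(np.abs(curve.lateral_deviation(grid)))])
    w = _smoothstep((z - z_al) / max(z_x - z_al, 1e-6))
    b = _smoothstep((z - z_at) / max(z_t1 - z_at, 1e-6))
    y = spine.centroids[:, 1]
    y_t1 = float(spine.vertebra("T1").centroid[1])
    dy = gamma * (y0 - y) * w + (t1_pull - gamma) * (y0 - y_t1) * b
    centroids = spine.centroids.copy()
    centroids[:, 1] += dy
    return spine.with_centroids(centroids, posture="self_corrected")


def generate_self_correction_targets(
    spine: SpineShape, thoracic_reduction_fraction: float
) -> SelfCorrectionTargets:
    """Target (x, y) positions for T1 and the apical vertebrae emulating a
    self-correction that reduces the thoracic Cobb by the requested fraction.

    T1 is pulled onto the CSVL (proportionally for fractions below the
    cohort-average 0.33); the lumbar apex stays at its reference position; the
    thoracic apex moves toward the CSVL until the interpolated target shape
    re-measures at the requested reduction (within 3 percentage points).
    Sagittal targets reduce kyphosis and lordosis by 6 and 5 deg scaled by
    fraction/0.33.
    """
    f = float(thoracic_reduction_fraction)
    if not (-0.2 <= f <= 0.8):
        raise ValueError("thoracic_reduction_fraction must lie in [-0.2, 0.8]")

    curve = fit_spinal_curve(spine)
    apex_t = find_apex(curve, "thoracic")
    apex_l = find_apex(curve, "lumbar")
    ref = {lab: spine.vertebra(lab).centroid for lab in ("T1", apex_t, apex_l)}

    if f == 0.0:
        return SelfCorrectionTargets(
            t1=LevelTarget("T1", float(ref["T1"][0]), float(ref["T1"][1])),
            thoracic_apex=LevelTarget(apex_t, float(ref[apex_t][0]), float(ref[apex_t][1])),
            lumbar_apex=LevelTarget(apex_l, float(ref[apex_l][0]), float(ref[apex_l][1])),
        )

    theta0 = measure_cobb(curve, "thoracic").angle
    t1_pull = float(np.clip(f / 0.33, 0.0, 1.0))
    target_pct = 100.0 * f

    def reduction_error(gamma: float) -> float:
        shape = _target_shape(spine, curve, apex_t, apex_l, gamma, t1_pull)
        theta = measure_cobb(fit_spinal_curve(shape), "thoracic").angle
        return 100.0 * (theta0 - theta) / theta0 - target_pct

    lo, hi = -0.6, 1.1
    flo, fhi = reduction_error(lo), reduction_error(hi)
    if flo * fhi > 0:
        raise GeometryError("requested reduction unreachable by arc flattening")
    c_star = brentq(reduction_error, lo, hi, xtol=1e-4)
    shape = _target_shape(spine, curve, apex_t, apex_l, c_star, t1_pull)

    # sagittal: subtract smoothstep tangent-angle reductions and re-integrate,
    # anchored so the lumbar apex keeps its reference sagittal position
    scale = f / 0.33
    dK, dLo = 6.0 * scale, 5.0 * scale
    zg = np.linspace(curve.z_min, curve.z_max, 801)
    phi = np.arctan(np.asarray(curve.dx(zg), dtype=float))
    lz = curve.level_z
    sgn_k = np.sign(float(curve.dx(lz["T1"])) - float(curve.dx(lz["T12"]))) or 1.0
    sgn_l = np.sign(float(curve.dx(lz["S1"])) - float(curve.dx(lz["L1"]))) or 1.0
    phi_t = (
        phi
        - sgn_k * np.radians(dK) * _smoothstep((zg - lz["T12"]) / (lz["T1"] - lz["T12"]))
        - sgn_l * np.radians(dLo) * (1.0 - _smoothstep((zg - lz["S1"]) / (lz["L1"] - lz["S1"])))
    )
    phi_t = np.clip(phi_t, -1.45, 1.45)
    x_t = cumulative_trapezoid(np.tan(phi_t), zg, initial=0.0) + float(curve.x(zg[0]))
    x_curve = np.asarray(curve.x(zg), dtype=float)
    dx_g = x_t - x_curve
    z_al = lz[apex_l]
    dx_at_al = float(np.interp(z_al, zg, dx_g))
    dx_g -= dx_at_al  # constant shift: lumbar apex sagittal position unchanged

    def dx_at(label: str) -> float:
        return float(np.interp(lz[label], zg, dx_g))

    _, y0 = csvl(spine)
    y_t1 = float(ref["T1"][1]) + t1_pull * (y0 - float(ref["T1"][1]))
    y_at = float(shape.vertebra(apex_t).centroid[1])
    return SelfCorrectionTargets(
        t1=LevelTarget("T1", float(ref["T1"][0]) + dx_at("T1"), y_t1),
        thoracic_apex=LevelTarget(apex_t, float(ref[apex_t][0]) + dx_at(apex_t), y_at),
        lumbar_apex=LevelTarget(apex_l, float(ref[apex_l][0]), float(ref[apex_l][1])),
    )
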
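"""Simplified linear trunk finite-element model.

Rigid vertebrae are nodes with 6 dof (three translations in mm, three
rotations in rad, global axes); each intervertebral joint is a two-node 3D
Timoshenko beam element whose section properties are the functional-spinal-
unit stiffnesses mapped to an equivalent prismatic beam of the segment length
L: EA = k_ax*L, GAs = k_sh*L, GJ = k_tor*L, EI = k_bend*L.  The rib cage,
sternum and soft tissues are collapsed into a multiplicative stiffening
factor on the thoracic segments; a global scale on all stiffnesses stands in
for the unpersonalized overall trunk rigidity and can be calibrated against a
cohort-level correction target.

The pelvis/S1 node is always fully fixed.  Constraints are handled by dof
elimination (partitioned solve), which yields exact prescribed values and
clean reaction forces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import scipy.linalg
from scipy.spatial.transform import Rotation

from .geometry import SpineShape, VertebraPose
from .levels import CANONICAL_LEVELS, LEVEL_INDEX, is_thoracic

__all__ = [
    "FEMError",
    "MechanismError",
    "SegmentProperties",
    "TrunkFEModel",
    "SolveResult",
    "beam_element_stiffness",
    "assemble_chain",
    "solve_system",
    "build_fem",
    "solve",
    "apply_gravity",
    "calibrate_global_scale",
    "DEFAULT_MASS_FRACTIONS",
]

GRAVITY_M_PER_S2 = 9.81

# Trunk mass above the pelvis carried per level: T1 stands in for head + arms,
# every other level carries a uniform slice; total 0.45 of body mass.
DEFAULT_MASS_FRACTIONS: dict[str, float] = {"T1": 0.13}
DEFAULT_MASS_FRACTIONS.update({lab: 0.02 for lab in CANONICAL_LEVELS[1:-1]})


class FEMError(ValueError):
    """Invalid finite-element input."""


class MechanismError(RuntimeError):
    """The constrained system is singular (unconstrained mechanism)."""


@dataclass(frozen=True)
class SegmentProperties:
    """Per-segment stiffnesses (uniform defaults; N, mm, rad units).

    k_ax N/mm axial; k_sh N/mm shear (both transverse directions);
    k_lb / k_fe / k_tor N*mm/rad lateral-bending / flexion-extension /
    torsional rotational stiffness of a functional spinal unit.
    """

    k_ax: float = 800.0
    k_sh: float = 150.0
    k_lb: float = 1.5e5
    k_fe: float = 1.5e5
    k_tor: float = 2.5e5
    thoracic_stiffening_factor: float = 1.5
    global_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_ax", "k_sh", "k_lb", "k_fe", "k_tor", "global_scale"):
            if getattr(self, name) <= 0:
                raise FEMError(f"{name} must be positive")
        if self.thoracic_stiffening_factor < 1.0:
            raise FEMError("thoracic_stiffening_factor must be >= 1")

    def with_scale(self, s: float) -> "SegmentProperties":
        return replace(self, global_scale=float(s))

    def to_dict(self) -> dict:
        return {
            "k_ax": self.k_ax, "k_sh": self.k_sh, "k_lb": self.k_lb,
            "k_fe": self.k_fe, "k_tor": self.k_tor,
            "thoracic_stiffening_factor": self.thoracic_stiffening_factor,
            "global_scale": self.global_scale,
        }


def _local_beam_matrix(
    L: float, EA: float, GAs: float, GJ: float, EIy: float, EIz: float
) -> np.ndarray:
    """12x12 Timoshenko beam stiffness in the element frame.

    Local dof order per node: (u, v, w, rx, ry, rz) with x along the element
    axis; bending in the x-y plane uses EIz, in the x-z plane EIy.
    """
    K = np.zeros((12, 12))
    # axial
    k = EA / L
    for i, j, s in ((0, 0, 1), (0, 6, -1), (6, 0, -1), (6, 6, 1)):
        K[i, j] += s * k
    # torsion
    k = GJ / L
    for i, j, s in ((3, 3, 1), (3, 9, -1), (9, 3, -1), (9, 9, 1)):
        K[i, j] += s * k

    def bending(EI: float, idx_v1, idx_r1, idx_v2, idx_r2, sign: float) -> None:
        phi = 12.0 * EI / (GAs * L * L)
        c = EI / (L**3 * (1.0 + phi))
        kb = c * np.array(
            [
                [12.0, sign * 6.0 * L, -12.0, sign * 6.0 * L],
                [sign * 6.0 * L, (4.0 + phi) * L * L, sign * -6.0 * L, (2.0 - phi) * L * L],
                [-12.0, sign * -6.0 * L, 12.0, sign * -6.0 * L],
                [sign * 6.0 * L, (2.0 - phi) * L * L, sign * -6.0 * L, (4.0 + phi) * L * L],
            ]
        )
        idx = (idx_v1, idx_r1, idx_v2, idx_r2)
        for a, ia in enumerate(idx):
            for b, ib in enumerate(idx):
                K[ia, ib] += kb[a, b]

    bending(EIz, 1, 5, 7, 11, +1.0)   # x-y plane: v with rz
    bending(EIy, 2, 4, 8, 10, -1.0)   # x-z plane: w with ry (sign convention)
    return K


def _element_axes(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    ex = p2 - p1
    L = np.linalg.norm(ex)
    if L < 1e-9:
        raise FEMError("zero-length element")
    ex = ex / L
    ref = np.array([1.0, 0.0, 0.0])  # global anterior
    if abs(np.dot(ex, ref)) > 1.0 - 1e-6:
        ref = np.array([0.0, 0.0, 1.0])
    ey = ref - np.dot(ref, ex) * ex
    ey = ey / np.linalg.norm(ey)
    ez = np.cross(ex, ey)
    return np.stack([ex, ey, ez])  # rows: local axes in global coords


def beam_element_stiffness(
    p1: np.ndarray,
    p2: np.ndarray,
    k_ax: float,
    k_sh: float,
    k_lb: float,
    k_fe: float,
    k_tor: float,
    scale: float = 1.0,
) -> np.ndarray:
    """Global-frame 12x12 stiffness of one intervertebral beam element.

    Local y is the projection of global anterior onto the plane normal to the
    element axis, so bending about local y is lateral bending (k_lb) and
    bending about local z is flexion-extension (k_fe).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    L = float(np.linalg.norm(p2 - p1))
    R = _element_axes(p1, p2)
    EA = scale * k_ax * L
    GAs = scale * k_sh * L
    GJ = scale * k_tor * L
    EIy = scale * k_lb * L   # bending about local y (anterior-ish axis)
    EIz = scale * k_fe * L   # bending about local z
    K_local = _local_beam_matrix(L, EA, GAs, GJ, EIy, EIz)
    T = np.zeros((12, 12))
    for b in range(4):
        T[3 * b : 3 * b + 3, 3 * b : 3 * b + 3] = R
    K = T.T @ K_local @ T
    return 0.5 * (K + K.T)


def assemble_chain(
    points: np.ndarray, element_props: Sequence[dict]
) -> np.ndarray:
    """Assemble the global stiffness of a serial chain of beam elements.

    ``element_props[i]`` holds k_ax, k_sh, k_lb, k_fe, k_tor and optional
    ``scale`` for the element between points i and i+1.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if len(element_props) != n - 1:
        raise FEMError("need one property set per element")
    K = np.zeros((6 * n, 6 * n))
    for i, props in enumerate(element_props):
        ke = beam_element_stiffness(points[i], points[i + 1], **props)
        sl = np.r_[6 * i : 6 * i + 6, 6 * (i + 1) : 6 * (i + 1) + 6]
        K[np.ix_(sl, sl)] += ke
    return K


def solve_system(
    K: np.ndarray,
    f: np.ndarray,
    prescribed: dict[int, float],
) -> tuple[np.ndarray, dict[int, float], float]:
    """Partitioned solve of K u = f with prescribed dof values.

    Returns (u, reactions at prescribed dofs, free-equation residual norm).
    """
    n = K.shape[0]
    p = np.array(sorted(prescribed), dtype=int)
    if p.size == 0:
        raise MechanismError("no constraints: rigid-body mechanism")
    free = np.setdiff1d(np.arange(n), p)
    u = np.zeros(n)
    u[p] = [prescribed[i] for i in p]
    rhs = f[free] - K[np.ix_(free, p)] @ u[p]
    Kff = K[np.ix_(free, free)]
    try:
        u[free] = scipy.linalg.solve(Kff, rhs, assume_a="sym")
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise MechanismError(f"singular constrained system: {exc}") from exc
    if not np.all(np.isfinite(u)):
        raise MechanismError("singular constrained system (non-finite solution)")
    residual = float(np.linalg.norm(Kff @ u[free] - rhs))
    scale_ref = max(float(np.linalg.norm(f)), float(np.linalg.norm(rhs)), 1.0)
    if residual > 1e-6 * scale_ref + 1e-8:
        raise MechanismError(
            f"ill-conditioned system: residual {residual:.3e} vs load norm {scale_ref:.3e}"
        )
    reactions = {int(i): float(K[i] @ u - f[i]) for i in p}
    return u, reactions, residual


@dataclass
class TrunkFEModel:
    """Assembled trunk model: 18 nodes, 17 beam elements, S1 fully fixed."""

    spine: SpineShape
    props: SegmentProperties
    K: np.ndarray
    constraints: list[tuple[str, int, float]] = field(default_factory=list)
    loads: list[tuple[str, int, float]] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.spine.vertebrae)

    def dof(self, label: str, component: int) -> int:
        if not (0 <= component < 6):
            raise FEMError("dof component must be in 0..5")
        return 6 * LEVEL_INDEX[label] + component

    def to_json(self, path) -> None:
        doc = {
            "props": self.props.to_dict(),
            "constraints": self.constraints,
            "loads": self.loads,
            "nodes": {
                v.label: list(map(float, v.centroid)) for v in self.spine.vertebrae
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)


@dataclass
class SolveResult:
    """Displacements, reactions and the deformed shape of one load case."""

    u: np.ndarray                      # (18, 6)
    reactions: dict[tuple[str, int], float]
    deformed: SpineShape
    residual: float
    prescribed_dofs: dict[tuple[str, int], float] = field(default_factory=dict)

    def reaction_vector(self, label: str) -> np.ndarray:
        """Translational reaction (N) at a node; zeros where unconstrained."""
        return np.array(
            [self.reactions.get((label, c), 0.0) for c in range(3)]
        )


def build_fem(spine: SpineShape, props: Optional[SegmentProperties] = None) -> TrunkFEModel:
    """Assemble the trunk stiffness from the reference posture.

    Thoracic segments (upper node T12..T1) carry the thoracic stiffening
    factor; all segments carry the global scale.  S1 is fully fixed.
    """
    props = props or SegmentProperties()
    element_props = []
    for upper in CANONICAL_LEVELS[1:]:
        factor = props.global_scale * (
            props.thoracic_stiffening_factor if is_thoracic(upper) else 1.0
        )
        element_props.append(
            dict(
                k_ax=props.k_ax, k_sh=props.k_sh, k_lb=props.k_lb,
                k_fe=props.k_fe, k_tor=props.k_tor, scale=factor,
            )
        )
    K = assemble_chain(spine.centroids, element_props)
    rel_asym = np.abs(K - K.T).max() / max(np.abs(K).max(), 1.0)
    if rel_asym > 1e-8:  # pragma: no cover - assembly guarantees symmetry
        raise FEMError(f"assembled stiffness asymmetric: {rel_asym:.2e}")
    constraints = [("S1", c, 0.0) for c in range(6)]
    return TrunkFEModel(spine=spine, props=props, K=K, constraints=constraints)


def _deform_spine(spine: SpineShape, u: np.ndarray) -> SpineShape:
    vertebrae = []
    for i, v in enumerate(spine.vertebrae):
        du, rot = u[i, :3], u[i, 3:]
        if np.linalg.norm(rot) > 0:
            Rm = Rotation.from_rotvec(rot).as_matrix()
        else:
            Rm = np.eye(3)
        vertebrae.append(
            VertebraPose(
                label=v.label,
                centroid=v.centroid + du,
                anterior=Rm @ v.anterior,
                left=Rm @ v.left,
                up=Rm @ v.up,
            )
        )
    return SpineShape(
        patient_id=spine.patient_id,
        posture="simulated",
        vertebrae=tuple(vertebrae),
        body_mass=spine.body_mass,
    )


def solve(
    model: TrunkFEModel,
    loads: Sequence[tuple[str, int, float]] = (),
    prescribed: Sequence[tuple[str, int, float]] = (),
) -> SolveResult:
    """Solve one load case: loads (N / N*mm) plus prescribed dof values (mm / rad).

    The model's permanent constraints (pelvis fixation) always apply.
    """
    n_dof = 6 * model.n_nodes
    f = np.zeros(n_dof)
    for label, comp, value in list(model.loads) + list(loads):
        f[model.dof(label, comp)] += value
    pres: dict[int, float] = {}
    for label, comp, value in list(model.constraints) + list(prescribed):
        idx = model.dof(label, comp)
        if idx in pres and pres[idx] != value:
            raise FEMError(f"conflicting prescriptions at {label} dof {comp}")
        pres[idx] = float(value)
    u_flat, reac, residual = solve_system(model.K, f, pres)
    u = u_flat.reshape(model.n_nodes, 6)
    labels = [v.label for v in model.spine.vertebrae]
    reactions = {(labels[i // 6], i % 6): r for i, r in reac.items()}
    prescribed_map = {(labels[i // 6], i % 6): v for i, v in pres.items()}
    return SolveResult(
        u=u,
        reactions=reactions,
        deformed=_deform_spine(model.spine, u),
        residual=residual,
        prescribed_dofs=prescribed_map,
    )


def apply_gravity(
    model: TrunkFEModel,
    body_mass: float,
    fractions: Optional[dict[str, float]] = None,
) -> list[tuple[str, int, float]]:
    """Downward nodal forces (N) from per-level trunk mass fractions."""
    if body_mass < 0:
        raise FEMError("body mass must be non-negative")
    fractions = DEFAULT_MASS_FRACTIONS if fractions is None else fractions
    total = 0.0
    loads = []
    for label, frac in fractions.items():
        if frac < 0:
            raise FEMError(f"negative mass fraction at {label}")
        total += frac
        force = -frac * body_mass * GRAVITY_M_PER_S2
        if force != 0.0:
            loads.append((label, 2, force))
    if total > 1.0 + 1e-9:
        raise FEMError(f"mass fractions sum to {total:.3f} > 1")
    return loads


def calibrate_global_scale(
    cohort: Sequence[SpineShape],
    target_mean_reduction_pct: float,
    force: float,
    props: Optional[SegmentProperties] = None,
    s_bounds: tuple[float, float] = (0.01, 100.0),
    tol_pct: float = 0.02,
    max_iter: int = 80,
) -> float:
    """Bisect the global stiffness scale so the cohort mean simulated
    manual-correction reduction matches the target (percent of presenting
    thoracic Cobb) within ``tol_pct`` points.

    Exploits linearity: for each spine the manual-correction displacement is
    u(s) = u_force / s + u_righting, with both parts solved once at s = 1.
    """
    from .corrections import manual_correction_parts  # local: avoids a cycle

    if not cohort:
        raise FEMError("cohort must be nonempty")
    base = (props or SegmentProperties()).with_scale(1.0)
    parts = [manual_correction_parts(build_fem(sp, base), force) for sp in cohort]

    def mean_reduction(s: float) -> float:
        return float(np.mean([p.reduction_pct_at_scale(s) for p in parts]))

    lo, hi = s_bounds
    target = float(target_mean_reduction_pct)
    # Reduction grows as s decreases, until an over-soft model over-corrects
    # past straight and the unsigned Cobb rises again.  Scan stiff-to-soft to
    # bracket the crossing on the physical (monotone) branch, then bisect.
    grid = np.geomspace(hi, lo, 25)
    r_prev = mean_reduction(grid[0])
    if r_prev >= target:
        raise FEMError(f"target {target:.1f}% already exceeded at s = {hi}")
    a = b = None
    for s_probe in grid[1:]:
        r = mean_reduction(s_probe)
        if r >= target:
            a, b = s_probe, grid[list(grid).index(s_probe) - 1]  # soft, stiff
            break
        r_prev = r
    if a is None:
        raise FEMError(
            f"target {target:.1f}% unreachable for s in [{lo}, {hi}] "
            f"(reached at most {r_prev:.1f}%)"
        )
    for _ in range(max_iter):
        mid = float(np.sqrt(a * b))  # bisect in log space
        r = mean_reduction(mid)
        if abs(r - target) <= tol_pct:
            return mid
        if r >= target:
            a = mid
        else:
            b = mid
    return float(np.sqrt(a * b))
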
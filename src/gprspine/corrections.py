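"""Manual-correction and self-correction simulations and stiffness indices.

Manual correction: the therapist's equivalent hand force (default 31 N,
patient-leftward +Y) is applied at the thoracic apical node of the reference
model with the pelvis fixed; T1 may slide vertically but is held at its
reference sagittal position and on the CSVL in the coronal plane (a stand-in
for the patient's righting reflex).  Stiffness index = F / delta Cobb.

Self-correction: the transverse (X, Y) positions of T1 and the thoracic and
lumbar apical vertebrae are prescribed to their target values with the pelvis
fixed and the spine free to move vertically; no external loads.  Stiffness
index = transverse reaction at the thoracic apex / delta Cobb.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cohort import SelfCorrectionTargets
from .geometry import (
    ClinicalIndices,
    SpineShape,
    csvl,
    fit_centroid_curve,
    fit_spinal_curve,
    measure_cobb,
    measure_indices,
)
from .fem import SolveResult, TrunkFEModel, solve

__all__ = [
    "ManualCorrectionInput",
    "StiffnessIndex",
    "CorrectionOutcome",
    "stiffness_index",
    "simulate_manual_correction",
    "simulate_self_correction",
    "manual_correction_parts",
]

#: Cobb changes below this (deg) leave the stiffness index undefined
MIN_DELTA_COBB_DEG = 0.25


@dataclass(frozen=True)
class ManualCorrectionInput:
    """Therapist force: magnitude (N), unit direction, application level
    (None = thoracic apex of the reference shape)."""

    force: float
    direction: tuple[float, float, float] = (0.0, 1.0, 0.0)
    level: Optional[str] = None

    def __post_init__(self) -> None:
        if self.force < 0:
            raise ValueError("force must be non-negative")
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-6:
            raise ValueError("direction must be a unit vector")


@dataclass(frozen=True)
class StiffnessIndex:
    """Force per degree of thoracic Cobb reduction.

    ``defined`` is False when the reduction is below 0.25 deg or negative;
    the raw ratio is still carried (logged in table-style reports the way the
    study prints P11's negative index).
    """

    value: Optional[float]
    rounded: Optional[int]
    defined: bool

    def as_cell(self) -> Optional[float]:
        """Table-style value: integer when defined, raw otherwise."""
        if self.defined:
            return float(self.rounded)
        return None if self.value is None else round(self.value, 2)


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def stiffness_index(force_or_reaction: float, delta_cobb: float) -> StiffnessIndex:
    """force / delta-Cobb (N/deg); undefined below a 0.25 deg reduction."""
    if not np.isfinite(delta_cobb):
        raise ValueError("delta_cobb must be finite")
    if abs(delta_cobb) < 1e-12:
        return StiffnessIndex(value=None, rounded=None, defined=False)
    raw = float(force_or_reaction) / float(delta_cobb)
    defined = delta_cobb > MIN_DELTA_COBB_DEG
    return StiffnessIndex(
        value=raw,
        rounded=_round_half_away(raw) if defined else None,
        defined=defined,
    )


@dataclass
class CorrectionOutcome:
    mode: str
    indices_before: ClinicalIndices
    indices_after: ClinicalIndices
    delta_cobb_thoracic: float
    delta_cobb_lumbar: float
    applied_force: float
    reaction_at_apex: Optional[float]
    stiffness: StiffnessIndex
    result: Optional[SolveResult] = None

    @property
    def reduction_pct(self) -> float:
        before = self.indices_before.cobb_thoracic
        return 100.0 * self.delta_cobb_thoracic / before if before > 0 else 0.0

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "indices_before": self.indices_before.to_dict(),
            "indices_after": self.indices_after.to_dict(),
            "delta_cobb_thoracic": self.delta_cobb_thoracic,
            "delta_cobb_lumbar": self.delta_cobb_lumbar,
            "reduction_pct": self.reduction_pct,
            "applied_force": self.applied_force,
            "reaction_at_apex": self.reaction_at_apex,
            "stiffness_index": self.stiffness.as_cell(),
            "stiffness_index_defined": self.stiffness.defined,
            "stiffness_index_raw": self.stiffness.value,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _apex_hints(spine: SpineShape, before: ClinicalIndices) -> dict:
    """z positions of the reference apexes, so the deformed posture is
    measured on the same anatomical arcs."""
    hints = {}
    if before.apex_thoracic is not None:
        hints["thoracic"] = spine.level_z(before.apex_thoracic)
    if before.apex_lumbar is not None:
        hints["lumbar"] = spine.level_z(before.apex_lumbar)
    return hints


def _manual_bcs(model: TrunkFEModel) -> list[tuple[str, int, float]]:
    spine = model.spine
    _, y0 = csvl(spine)
    y_t1 = float(spine.vertebra("T1").centroid[1])
    return [
        ("T1", 0, 0.0),          # sagittal position held at reference
        ("T1", 1, y0 - y_t1),    # coronal position pulled onto the CSVL
    ]


def simulate_manual_correction(
    model: TrunkFEModel, inp: ManualCorrectionInput
) -> CorrectionOutcome:
    """Apply the therapist force at the thoracic apex and re-measure."""
    before = measure_indices(model.spine)
    level = inp.level or before.apex_thoracic
    if level is None:
        raise ValueError("no thoracic apex: specify the application level")
    loads = [
        (level, comp, inp.force * d)
        for comp, d in enumerate(inp.direction)
        if inp.force * d != 0.0
    ]
    res = solve(model, loads=loads, prescribed=_manual_bcs(model))
    after = measure_indices(res.deformed, apex_hints=_apex_hints(model.spine, before))
    delta_t = before.cobb_thoracic - after.cobb_thoracic
    delta_l = before.cobb_lumbar - after.cobb_lumbar
    return CorrectionOutcome(
        mode="manual",
        indices_before=before,
        indices_after=after,
        delta_cobb_thoracic=delta_t,
        delta_cobb_lumbar=delta_l,
        applied_force=inp.force,
        reaction_at_apex=None,
        stiffness=stiffness_index(inp.force, delta_t),
        result=res,
    )


def simulate_self_correction(
    model: TrunkFEModel, targets: SelfCorrectionTargets
) -> CorrectionOutcome:
    """Prescribe transverse target positions at T1 and the apexes and solve."""
    spine = model.spine
    prescribed = []
    for tgt in (targets.t1, targets.thoracic_apex, targets.lumbar_apex):
        ref = spine.vertebra(tgt.level).centroid
        prescribed.append((tgt.level, 0, tgt.x - float(ref[0])))
        prescribed.append((tgt.level, 1, tgt.y - float(ref[1])))
    before = measure_indices(spine)
    res = solve(model, loads=(), prescribed=prescribed)
    after = measure_indices(res.deformed, apex_hints=_apex_hints(spine, before))
    delta_t = before.cobb_thoracic - after.cobb_thoracic
    delta_l = before.cobb_lumbar - after.cobb_lumbar
    apex_label = targets.thoracic_apex.level
    r_vec = res.reaction_vector(apex_label)
    reaction = float(np.hypot(r_vec[0], r_vec[1]))
    return CorrectionOutcome(
        mode="self",
        indices_before=before,
        indices_after=after,
        delta_cobb_thoracic=delta_t,
        delta_cobb_lumbar=delta_l,
        applied_force=0.0,
        reaction_at_apex=reaction,
        stiffness=stiffness_index(reaction, delta_t),
        result=res,
    )


@dataclass
class ManualCorrectionParts:
    """Scale-separated manual-correction response of one spine.

    The deformed shape at global scale s is reference + u_force/s + u_righting,
    since the force response scales inversely with stiffness while the
    prescribed T1 re-centring does not.
    """

    spine: SpineShape
    theta_before: float
    apex_z: float
    u_force: np.ndarray
    u_righting: np.ndarray

    def reduction_pct_at_scale(self, s: float) -> float:
        u = self.u_force[:, :3] / s + self.u_righting[:, :3]
        curve = fit_centroid_curve(self.spine.centroids + u)
        theta = measure_cobb(curve, "thoracic", apex_hint=self.apex_z).angle
        return 100.0 * (self.theta_before - theta) / self.theta_before


def manual_correction_parts(
    model: TrunkFEModel, force: float, direction=(0.0, 1.0, 0.0)
) -> ManualCorrectionParts:
    """Solve the force part (homogeneous BCs) and righting part (no load)
    of the manual correction once, at the model's own scale."""
    before = measure_cobb(fit_spinal_curve(model.spine), "thoracic")
    if before.apex is None:
        raise ValueError("spine has no thoracic apex")
    loads = [
        (before.apex, comp, force * d) for comp, d in enumerate(direction) if d != 0.0
    ]
    homogeneous = [("T1", 0, 0.0), ("T1", 1, 0.0)]
    res_force = solve(model, loads=loads, prescribed=homogeneous)
    res_right = solve(model, loads=(), prescribed=_manual_bcs(model))
    return ManualCorrectionParts(
        spine=model.spine,
        theta_before=before.angle,
        apex_z=model.spine.level_z(before.apex),
        u_force=res_force.u,
        u_righting=res_right.u,
    )
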
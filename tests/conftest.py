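"""Shared geometry builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from gprspine.cohort import CohortParams, generate_cohort, template_z
from gprspine.geometry import SpineShape, VertebraPose
from gprspine.levels import CANONICAL_LEVELS


def identity_axes() -> dict:
    return dict(
        anterior=np.array([1.0, 0.0, 0.0]),
        left=np.array([0.0, 1.0, 0.0]),
        up=np.array([0.0, 0.0, 1.0]),
    )


def spine_from_xy(x, y, patient_id="test", body_mass=None) -> SpineShape:
    """18-level spine on the template z grid with prescribed x(z), y(z)."""
    z = template_z()
    return SpineShape(
        patient_id=patient_id,
        posture="reference",
        vertebrae=tuple(
            VertebraPose(label=lab, centroid=np.array([xi, yi, zi]), **identity_axes())
            for lab, xi, yi, zi in zip(CANONICAL_LEVELS, x, y, z)
        ),
        body_mass=body_mass,
    )


def straight_spine(**kw) -> SpineShape:
    return spine_from_xy(np.zeros(18), np.zeros(18), **kw)


def sine_spine(amplitude: float, wavelength: float = 400.0) -> SpineShape:
    """Coronal sinusoid y = A sin(2 pi z / lambda); closed-form Cobb is
    2*atan(2 pi A / lambda) for an arc bounded by adjacent inflections."""
    z = template_z()
    return spine_from_xy(np.zeros(18), amplitude * np.sin(2 * np.pi * z / wavelength))


def arc_spine(subtended_deg: float) -> SpineShape:
    """Planar coronal circular arc spanning the whole spine; the tangent-angle
    difference between the curve ends equals the subtended angle."""
    beta = np.radians(subtended_deg)
    s = template_z()
    total = s[-1]
    radius = total / beta
    psi = -beta / 2 + beta * s / total
    z = radius * (np.sin(psi) + np.sin(beta / 2))
    y = -radius * np.cos(psi) + radius * np.cos(beta / 2)
    return SpineShape(
        patient_id="arc",
        posture="reference",
        vertebrae=tuple(
            VertebraPose(label=lab, centroid=np.array([0.0, yi, zi]), **identity_axes())
            for lab, yi, zi in zip(CANONICAL_LEVELS, y, z)
        ),
    )


def sagittal_ramp_spine(kyphosis_deg: float) -> SpineShape:
    """Sagittal tangent angle ramping linearly 0 -> K over T12..T1."""
    z = template_z()
    lz = {lab: zi for lab, zi in zip(CANONICAL_LEVELS, z)}
    zg = np.linspace(0.0, z[-1], 800)
    phi = np.clip((zg - lz["T12"]) / (lz["T1"] - lz["T12"]), 0, 1) * np.radians(
        kyphosis_deg
    )
    xg = cumulative_trapezoid(np.tan(phi), zg, initial=0.0)
    return spine_from_xy(np.interp(z, zg, xg), np.zeros(18))


def rotated_vertebra(rotation_deg: float, label: str = "T8") -> VertebraPose:
    """Frame rotated about the vertical axis toward the patient's right."""
    r = np.radians(rotation_deg)
    return VertebraPose(
        label=label,
        centroid=np.zeros(3),
        anterior=np.array([np.cos(r), -np.sin(r), 0.0]),
        left=np.array([np.sin(r), np.cos(r), 0.0]),
        up=np.array([0.0, 0.0, 1.0]),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Four synthetic patients reused across FEM/correction tests."""
    return generate_cohort(CohortParams(n=4, seed=42))


@pytest.fixture(scope="session")
def large_cohort():
    """n = 200 cohort for distribution-recovery checks."""
    return generate_cohort(CohortParams(n=200, seed=7))
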
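"""Study-level statistics: per-patient fixture tables, summary rows,
correlations, stiffness-index recomputation, and the cohort pipeline.

The packaged fixtures transcribe the 16-patient per-patient tables of the
source study (the decimal-comma cell "-0,40" is normalized to -0.40 at
fixture build time).  Fixture mode reproduces the printed summary rows and
correlations; synthetic mode runs the full pipeline — generate a cohort,
calibrate the global stiffness scale, simulate both corrections — and emits a
side-by-side report against the printed summaries.

The study's ANOVA + post-hoc Tukey comparisons are deliberately not
reimplemented; the report carries plain paired mean differences with their
standard deviations instead.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortParams, ParamSpec, generate_cohort, generate_self_correction_targets
from .corrections import (
    ManualCorrectionInput,
    simulate_manual_correction,
    simulate_self_correction,
    stiffness_index,
)
from .fem import SegmentProperties, build_fem, calibrate_global_scale

__all__ = [
    "load_table1",
    "load_table2",
    "round_half_away",
    "SummaryRow",
    "summarize",
    "pearson",
    "consistency_check",
    "recompute_stiffness_indices",
    "paired_difference",
    "run_study",
]

#: actual self-correction reduction fractions: mean 33%, sd ~20%, [-15%, 69%]
SELF_FRACTION_SPEC = ParamSpec(0.333, 0.204, -0.15, 0.69)


def _data_path(name: str):
    return resources.files("gprspine").joinpath("data", name)


def load_table1() -> pd.DataFrame:
    """Manual-correction per-patient table (16 rows P1..P16)."""
    with resources.as_file(_data_path("table1.csv")) as p:
        return pd.read_csv(p)


def load_table2() -> pd.DataFrame:
    """Actual and simulated self-correction per-patient table."""
    with resources.as_file(_data_path("table2.csv")) as p:
        return pd.read_csv(p)


def round_half_away(x: float) -> int:
    """Round half away from zero (the tables' apparent convention)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class SummaryRow:
    """Mean / sample sd / min / max of one table column."""

    mean: float
    sd: float
    minimum: float
    maximum: float

    def __post_init__(self) -> None:
        if not (self.minimum <= self.mean <= self.maximum):
            raise ValueError("min <= mean <= max violated")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    def rounded(self) -> dict:
        return {
            "mean": round_half_away(self.mean),
            "sd": round_half_away(self.sd),
            "min": round_half_away(self.minimum),
            "max": round_half_away(self.maximum),
        }

    def as_text(self) -> str:
        r = self.rounded()
        return f"{r['mean']} ± {r['sd']} [{r['min']}–{r['max']}]"


def summarize(values: Sequence[float]) -> SummaryRow:
    """Arithmetic mean, sample sd (n-1), min and max of a column."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty list")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return SummaryRow(
        mean=float(arr.mean()), sd=sd, minimum=float(arr.min()), maximum=float(arr.max())
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("pearson needs two equal-length samples of size >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("pearson undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def consistency_check(
    df: pd.DataFrame, pres_col: str, post_col: str, pct_col: str
) -> pd.DataFrame:
    """Printed percent reduction vs the percent recomputed from the printed
    Cobb pair; the deviation column exposes rows where the study's percents
    came from unrounded internal values."""
    recomputed = 100.0 * (df[pres_col] - df[post_col]) / df[pres_col]
    return pd.DataFrame(
        {
            "patient": df["patient"],
            "printed_pct": df[pct_col],
            "recomputed_pct": recomputed,
            "deviation_pp": (df[pct_col] - recomputed).abs(),
        }
    )


def recompute_stiffness_indices(mode: str = "manual") -> pd.DataFrame:
    """Stiffness indices recomputed from the printed force and Cobb columns.

    Rows whose integer-rounded recomputation differs from the printed index
    (or where the printed Cobb change is zero or negative) are flagged rather
    than asserted — the study derived those from unrounded internal values.
    """
    if mode == "manual":
        df = load_table1()
        force_col, post_col = "therapist_force", "manual_sim_cobb"
        printed_col = "manual_stiffness_index"
    elif mode == "self":
        df = load_table2()
        force_col, post_col = "apex_reaction_force", "sim_self_cobb"
        printed_col = "self_stiffness_index"
    else:
        raise ValueError("mode must be 'manual' or 'self'")
    rows = []
    for _, r in df.iterrows():
        delta = float(r["presenting_cobb"] - r[post_col])
        si = stiffness_index(float(r[force_col]), delta)
        printed = float(r[printed_col])
        matches = si.defined and si.rounded == round_half_away(printed)
        rows.append(
            {
                "patient": r["patient"],
                "delta_cobb": delta,
                "recomputed": si.value,
                "recomputed_rounded": si.rounded,
                "printed": printed,
                "defined": si.defined,
                "flagged": not matches,
            }
        )
    return pd.DataFrame(rows)


def paired_difference(before: Sequence[float], after: Sequence[float]) -> dict:
    """Plain paired mean difference (before - after) with its sd."""
    d = np.asarray(list(before), dtype=float) - np.asarray(list(after), dtype=float)
    return {"mean": float(d.mean()), "sd": float(d.std(ddof=1)), "n": int(d.size)}


_T1_COLUMNS = [
    "presenting_cobb", "manual_sim_cobb", "manual_reduction_pct",
    "therapist_force", "manual_stiffness_index",
]
_T2_COLUMNS = [
    "actual_self_cobb", "actual_self_reduction_pct", "sim_self_cobb",
    "sim_self_reduction_pct", "apex_reaction_force", "self_stiffness_index",
]


def _fixture_report() -> dict:
    t1, t2 = load_table1(), load_table2()
    summaries = {c: summarize(t1[c]).rounded() for c in _T1_COLUMNS}
    summaries.update({c: summarize(t2[c]).rounded() for c in _T2_COLUMNS})
    correlations = {
        "actual_vs_sim_self_cobb": pearson(t2["actual_self_cobb"], t2["sim_self_cobb"]),
        "force_vs_manual_reduction": pearson(
            t1["therapist_force"], t1["manual_reduction_pct"]
        ),
        "manual_vs_self_sim_reduction": pearson(
            t1["manual_reduction_pct"], t2["sim_self_reduction_pct"]
        ),
    }
    return {
        "mode": "fixture",
        "n": int(len(t1)),
        "summaries": summaries,
        "summary_text": {
            c: summarize((t1 if c in _T1_COLUMNS else t2)[c]).as_text()
            for c in _T1_COLUMNS + _T2_COLUMNS
        },
        "correlations": {k: round(v, 3) for k, v in correlations.items()},
        "correlations_rounded": {k: round(v, 1) for k, v in correlations.items()},
        "mean_actual_self_correction_deg": float(
            (t2["presenting_cobb"] - t2["actual_self_cobb"]).mean()
        ),
        "paired_differences": {
            "manual_sim_vs_presenting": paired_difference(
                t1["presenting_cobb"], t1["manual_sim_cobb"]
            ),
            "actual_self_vs_presenting": paired_difference(
                t2["presenting_cobb"], t2["actual_self_cobb"]
            ),
            "sim_self_vs_presenting": paired_difference(
                t2["presenting_cobb"], t2["sim_self_cobb"]
            ),
        },
        "stiffness_flags": {
            "manual": recompute_stiffness_indices("manual")["flagged"].tolist(),
            "self": recompute_stiffness_indices("self")["flagged"].tolist(),
        },
    }


def _synthetic_report(
    n: int,
    seed: int,
    force: float,
    calibration_target_pct: Optional[float],
    props: Optional[SegmentProperties],
) -> dict:
    if calibration_target_pct is None:
        calibration_target_pct = float(load_table1()["manual_reduction_pct"].mean())
    rng = np.random.default_rng(seed)
    cohort_seed = int(rng.integers(2**31 - 1))
    cohort = generate_cohort(CohortParams(n=n, seed=cohort_seed))
    s = calibrate_global_scale(cohort, calibration_target_pct, force, props=props)
    scaled = (props or SegmentProperties()).with_scale(s)

    frac_sd = SELF_FRACTION_SPEC.effective_sd
    a = (SELF_FRACTION_SPEC.lo - SELF_FRACTION_SPEC.mean) / frac_sd
    b = (SELF_FRACTION_SPEC.hi - SELF_FRACTION_SPEC.mean) / frac_sd
    fractions = stats.truncnorm.rvs(
        a, b, loc=SELF_FRACTION_SPEC.mean, scale=frac_sd, size=n, random_state=rng
    )

    records = []
    for spine, frac in zip(cohort, fractions):
        model = build_fem(spine, scaled)
        manual = simulate_manual_correction(model, ManualCorrectionInput(force=force))
        targets = generate_self_correction_targets(spine, float(frac))
        selfc = simulate_self_correction(model, targets)
        records.append(
            {
                "patient": spine.patient_id,
                "presenting_cobb": manual.indices_before.cobb_thoracic,
                "manual_sim_cobb": manual.indices_after.cobb_thoracic,
                "manual_reduction_pct": manual.reduction_pct,
                "therapist_force": force,
                "manual_stiffness_index": manual.stiffness.as_cell(),
                "target_self_fraction_pct": 100.0 * float(frac),
                "sim_self_cobb": selfc.indices_after.cobb_thoracic,
                "sim_self_reduction_pct": selfc.reduction_pct,
                "apex_reaction_force": selfc.reaction_at_apex,
                "self_stiffness_index": selfc.stiffness.as_cell(),
            }
        )
    df = pd.DataFrame(records)
    printed = _fixture_report()["summaries"]
    side_by_side = {}
    for col, printed_key in [
        ("presenting_cobb", "presenting_cobb"),
        ("manual_sim_cobb", "manual_sim_cobb"),
        ("manual_reduction_pct", "manual_reduction_pct"),
        ("sim_self_cobb", "sim_self_cobb"),
        ("sim_self_reduction_pct", "sim_self_reduction_pct"),
        ("apex_reaction_force", "apex_reaction_force"),
    ]:
        side_by_side[col] = {
            "synthetic_mean": float(df[col].mean()),
            "printed_mean": printed[printed_key]["mean"],
        }
    return {
        "mode": "synthetic",
        "n": n,
        "seed": seed,
        "force": force,
        "calibration_target_pct": calibration_target_pct,
        "calibrated_global_scale": s,
        "patients": records,
        "summaries": {
            c: summarize(df[c].astype(float).fillna(np.nan).dropna()).rounded()
            for c in (
                "presenting_cobb", "manual_sim_cobb", "manual_reduction_pct",
                "sim_self_cobb", "sim_self_reduction_pct", "apex_reaction_force",
            )
        },
        "side_by_side": side_by_side,
    }


def run_study(
    mode: str = "fixture",
    n: int = 16,
    seed: int = 42,
    force: float = 31.0,
    calibration_target_pct: Optional[float] = None,
    props: Optional[SegmentProperties] = None,
) -> dict:
    """Run the study pipeline and return the report as a plain dict.

    ``fixture`` mode reproduces the per-patient tables' summary rows,
    correlations and recomputed stiffness indices.  ``synthetic`` mode runs
    generate -> calibrate -> simulate on a synthetic cohort and reports its
    summaries next to the printed ones; deterministic under ``seed``.
    """
    if mode == "fixture":
        return _fixture_report()
    if mode == "synthetic":
        return _synthetic_report(n, seed, force, calibration_target_pct, props)
    raise ValueError("mode must be 'fixture' or 'synthetic'")


def report_to_json(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)


def report_to_text(report: dict) -> str:
    lines = [f"study report ({report['mode']} mode, n={report['n']})", ""]
    if report["mode"] == "fixture":
        for col, txt in report["summary_text"].items():
            lines.append(f"  {col:32s} {txt}")
        lines.append("")
        for k, v in report["correlations"].items():
            lines.append(f"  r({k}) = {v:.3f}")
    else:
        lines.append(f"  calibrated global scale s = {report['calibrated_global_scale']:.3f}")
        for col, pair in report["side_by_side"].items():
            lines.append(
                f"  {col:28s} synthetic {pair['synthetic_mean']:6.1f}"
                f"   printed {pair['printed_mean']:4d}"
            )
    return "\n".join(lines)
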
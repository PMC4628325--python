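"""Synthetic multi-reader lesion-volume cohorts with known ground truth.

Emulates an NSCLC follow-up study: a handful of patients, one preselected
lung target lesion each, serial CT timepoints, and several readers who
each segment every lesion at every timepoint.  True volumes follow simple
per-patient courses (responding, progressing, stable, respond-then-relapse)
with mild biological wobble; observed volumes multiply the truth by an
independent lognormal reader error with a fixed coefficient of variation,
so volumes stay positive across the full 0.195-381 cm^3 size range.

The generator is the test bed for the response pipeline: the truth table
records true volumes and true categories, so parameter-recovery and
calibration tests need no external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gh_core import DEFAULT_CV, symmetric_thresholds
from .response_pipeline import COHORT_COLUMNS, classify_timepoint

__all__ = ["SyntheticCohortSpec", "generate"]

#: Per-step multiplicative volume changes for each disease course.
_COURSES = {
    "responding": 0.75,
    "progressing": 1.35,
    "stable": 1.0,
    "relapse": None,  # shrink then regrow, handled explicitly
}
_COURSE_CYCLE = ("responding", "progressing", "stable", "relapse")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Study-design parameters of the generated cohort.

    Defaults mirror the validation-study structure: 10 patients with one
    target lesion each, a baseline plus six follow-up scans, six readers,
    reader CV 0.3/1.96 (~15%), and log-uniform baseline volumes spanning
    0.195-380.976 cm^3.
    """

    n_patients: int = 10
    n_timepoints: int = 7
    n_readers: int = 6
    k: float = DEFAULT_CV
    volume_range: tuple[float, float] = (0.195, 380.976)
    trajectory_sd_log: float = 0.05  # biological wobble of each true step

    def __post_init__(self) -> None:
        if min(self.n_patients, self.n_timepoints, self.n_readers) < 1:
            raise ValueError("all counts must be >= 1")
        if self.k < 0:
            raise ValueError(f"CV must be non-negative, got {self.k}")
        lo, hi = self.volume_range
        if not 0 < lo <= hi:
            raise ValueError(f"invalid volume range {self.volume_range}")


def _true_volumes(
    spec: SyntheticCohortSpec, course: str, baseline: float, rng: np.random.Generator
) -> np.ndarray:
    volumes = [baseline]
    midpoint = spec.n_timepoints // 2
    for t in range(1, spec.n_timepoints):
        if course == "relapse":
            step = 0.72 if t <= midpoint else 1.5
        else:
            step = _COURSES[course]
        step *= math.exp(rng.normal(0.0, spec.trajectory_sd_log))
        volumes.append(volumes[-1] * step)
    return np.asarray(volumes)


def generate(
    spec: SyntheticCohortSpec = SyntheticCohortSpec(),
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate an observed cohort table and its ground-truth table.

    Observed volume = true volume x lognormal multiplicative reader error
    with CV ``spec.k`` (moment-matched: log-variance ``ln(1 + k^2)``), drawn
    independently per (timepoint, reader).  Deterministic given ``seed``.

    Returns
    -------
    cohort : DataFrame with the response-pipeline CSV schema
        (patient_id, lesion_id, timepoint_index, reader_id, volume_cm3).
    truth : DataFrame with per (patient, lesion, timepoint) true volume,
        true baseline-referenced ratio and true category.
    """
    rng = np.random.default_rng(seed)
    # Truth categories always use the clinical default thresholds so they are
    # well defined even for a noise-free (k = 0) cohort.
    thresholds = symmetric_thresholds(DEFAULT_CV)
    log_lo, log_hi = (math.log(v) for v in spec.volume_range)
    if spec.k > 0:
        s2 = math.log1p(spec.k**2)
        s = math.sqrt(s2)
    cohort_rows = []
    truth_rows = []
    for p in range(spec.n_patients):
        patient = f"P{p + 1:02d}"
        course = _COURSE_CYCLE[p % len(_COURSE_CYCLE)]
        baseline = math.exp(rng.uniform(log_lo, log_hi))
        true = _true_volumes(spec, course, baseline, rng)
        for t, v_true in enumerate(true):
            ratio = v_true / true[0]
            category = classify_timepoint(ratio - 1.0, thresholds)
            truth_rows.append(
                {
                    "patient_id": patient,
                    "lesion_id": "L1",
                    "timepoint_index": t,
                    "course": course,
                    "true_volume_cm3": v_true,
                    "true_ratio_from_baseline": ratio,
                    "true_category": category,
                }
            )
            if spec.k > 0:
                errors = rng.lognormal(mean=-s2 / 2.0, sigma=s, size=spec.n_readers)
            else:
                errors = np.ones(spec.n_readers)
            for r in range(spec.n_readers):
                cohort_rows.append(
                    {
                        "patient_id": patient,
                        "lesion_id": "L1",
                        "timepoint_index": t,
                        "reader_id": f"R{r + 1}",
                        "volume_cm3": v_true * errors[r],
                    }
                )
    cohort = pd.DataFrame(cohort_rows, columns=list(COHORT_COLUMNS))
    truth = pd.DataFrame(truth_rows)
    return cohort, truth
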
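"""Classification of longitudinal multi-reader lesion measurements.

Takes a tidy table of per-reader volume measurements (patient, lesion,
timepoint, reader, volume in cm^3), computes relative changes against a
baseline or nadir reference, assigns PR / SD / PD categories from a
:class:`~volratio.gh_core.ThresholdSet`, and tests whether the scatter of
the readers' assessments at each timepoint falls inside the confidence
band the ratio model predicts from the measurement CV.

The agreement band for a reader group with mean relative change ``m`` is
``[(1+m)*A_L - 1, (1+m)*A_U - 1]`` where ``A_L, A_U`` are the
multiplicative confidence-interval factors of the ratio model at the given
CV and level: the group mean anchors the band, each reader's change is
tested for membership, and the overall within-band fraction comes with an
exact (Clopper-Pearson) binomial confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .gh_core import ThresholdSet, ratio_confidence_interval

__all__ = [
    "COHORT_COLUMNS",
    "ReaderAssessment",
    "AgreementReport",
    "read_cohort",
    "relative_change",
    "nadir_volume",
    "classify_timepoint",
    "two_way_evaluation",
    "reader_agreement",
]

#: Required columns of the cohort CSV schema.
COHORT_COLUMNS = ("patient_id", "lesion_id", "timepoint_index", "reader_id", "volume_cm3")

_CATEGORIES = ("PR", "SD", "PD")


@dataclass(frozen=True)
class ReaderAssessment:
    """One reader's classified relative change at one timepoint."""

    patient_id: str
    lesion_id: str
    timepoint_index: int
    reader_id: str
    reference: str  # baseline | nadir
    reference_volume: float
    volume: float
    relative_change: float
    category: str


@dataclass
class AgreementReport:
    """Within-band summary of reader scatter across all grouped timepoints."""

    n_assessments: int
    n_within_band: int
    fraction_within: float
    ci_low: float
    ci_high: float
    level: float
    k: float
    detail: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "n_assessments": self.n_assessments,
            "n_within_band": self.n_within_band,
            "fraction_within": self.fraction_within,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level,
            "k": self.k,
        }


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV (UTF-8, '.' decimal, header required)."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    df = df.copy()
    df["timepoint_index"] = df["timepoint_index"].astype(int)
    df["volume_cm3"] = df["volume_cm3"].astype(float)
    return validate_cohort(df)


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    if (df["volume_cm3"] <= 0).any():
        bad = df.loc[df["volume_cm3"] <= 0]
        raise ValueError(
            f"non-positive volumes in {len(bad)} rows, e.g. "
            f"{bad.iloc[0][list(COHORT_COLUMNS)].to_dict()}"
        )
    if (df["timepoint_index"] < 0).any():
        raise ValueError("timepoint_index must be >= 0 (0 = baseline)")
    key = ["patient_id", "lesion_id", "timepoint_index", "reader_id"]
    dup = df.duplicated(subset=key)
    if dup.any():
        raise ValueError(
            f"duplicate (patient, lesion, timepoint, reader) rows: "
            f"{df.loc[dup, key].head().to_dict('records')}"
        )
    return df


def relative_change(reference_volume: float, current_volume: float) -> float:
    """Signed fractional change (X2 - X1)/X1 = X2/X1 - 1."""
    if reference_volume <= 0:
        raise ValueError(
            f"reference volume must be positive, got {reference_volume}"
        )
    return current_volume / reference_volume - 1.0


def nadir_volume(volumes_by_timepoint: pd.Series, timepoint: int) -> float:
    """Smallest volume strictly before ``timepoint`` (baseline included).

    ``volumes_by_timepoint`` is indexed by timepoint_index for a single
    (patient, lesion, reader) series.
    """
    if timepoint <= 0:
        raise ValueError("no reference exists before the baseline timepoint")
    prior = volumes_by_timepoint[volumes_by_timepoint.index < timepoint]
    if prior.empty:
        raise ValueError(f"no timepoints observed before index {timepoint}")
    return float(prior.min())


def classify_timepoint(change: float, thresholds: ThresholdSet) -> str:
    """PR / SD / PD from a signed fractional change and percent thresholds.

    A change exactly on a threshold is stable disease (non-rejection).
    """
    if change <= -1.0:
        raise ValueError(
            f"relative change must exceed -1 (volumes are positive), got {change}"
        )
    if change < thresholds.lower_pct / 100.0:
        return "PR"
    if change > thresholds.upper_pct / 100.0:
        return "PD"
    return "SD"


def two_way_evaluation(
    cohort: pd.DataFrame, thresholds: ThresholdSet
) -> pd.DataFrame:
    """Baseline- and nadir-referenced assessments for every follow-up row.

    Every (patient, lesion, reader) series must include a baseline
    (timepoint 0); each later timepoint yields two assessments, one per
    reference mode.  The nadir is per reader, over that reader's own prior
    measurements.
    """
    cohort = validate_cohort(cohort)
    missing = []
    rows = []
    for (patient, lesion, reader), grp in cohort.groupby(
        ["patient_id", "lesion_id", "reader_id"], sort=True
    ):
        series = grp.set_index("timepoint_index")["volume_cm3"].sort_index()
        if 0 not in series.index:
            missing.append((patient, lesion, reader))
            continue
        baseline = float(series.loc[0])
        for t in series.index[series.index > 0]:
            volume = float(series.loc[t])
            for reference, ref_volume in (
                ("baseline", baseline),
                ("nadir", nadir_volume(series, int(t))),
            ):
                change = relative_change(ref_volume, volume)
                rows.append(
                    {
                        "patient_id": patient,
                        "lesion_id": lesion,
                        "timepoint_index": int(t),
                        "reader_id": reader,
                        "reference": reference,
                        "reference_volume": ref_volume,
                        "volume_cm3": volume,
                        "relative_change": change,
                        "category": classify_timepoint(change, thresholds),
                    }
                )
    if missing:
        raise ValueError(
            "series without a baseline (timepoint 0) measurement: "
            f"{missing}"
        )
    return pd.DataFrame(rows)


def reader_agreement(
    assessments: pd.DataFrame,
    k: float,
    level: float = 0.95,
    leave_one_out: bool = False,
    min_readers: int = 2,
) -> AgreementReport:
    """Test reader scatter against the model's predicted confidence band.

    Groups assessments by (patient, lesion, timepoint, reference).  For
    each group the band ``[(1+m)*A_L - 1, (1+m)*A_U - 1]`` is anchored at
    the group-mean change ``m`` (including the reader under test unless
    ``leave_one_out``), with ``A_L, A_U`` the multiplicative CI factors of
    the ratio model at CV ``k``; ``k = 0`` degenerates to the exact band
    ``[m, m]``.  Groups with fewer than ``min_readers`` readers are
    excluded with a warning.
    """
    if k < 0:
        raise ValueError(f"CV must be non-negative, got {k}")
    ci = ratio_confidence_interval(1.0, 1.0, k, k, rho=0.0, level=level)
    a_low, a_high = ci.lower, ci.upper

    keys = ["patient_id", "lesion_id", "timepoint_index", "reference"]
    records = []
    n_excluded = 0
    for group_key, grp in assessments.groupby(keys, sort=True):
        changes = grp["relative_change"].to_numpy(dtype=float)
        if len(changes) < min_readers:
            n_excluded += 1
            continue
        for i, (_, row) in enumerate(grp.iterrows()):
            if leave_one_out:
                m = float(np.delete(changes, i).mean())
            else:
                m = float(changes.mean())
            lo = (1.0 + m) * a_low - 1.0
            hi = (1.0 + m) * a_high - 1.0
            # few-ulp slack so a degenerate (k=0) band still contains its
            # own anchor despite floating-point averaging
            tol = 1e-12 * (1.0 + abs(m))
            records.append(
                {
                    **dict(zip(keys, group_key)),
                    "reader_id": row["reader_id"],
                    "relative_change": row["relative_change"],
                    "group_mean_change": m,
                    "band_low": lo,
                    "band_high": hi,
                    "within_band": bool(
                        lo - tol <= row["relative_change"] <= hi + tol
                    ),
                }
            )
    if n_excluded:
        warnings.warn(
            f"excluded {n_excluded} group(s) with fewer than "
            f"{min_readers} readers",
            stacklevel=2,
        )
    detail = pd.DataFrame(records)
    if detail.empty:
        raise ValueError("no groups with enough readers to assess agreement")
    n = len(detail)
    n_within = int(detail["within_band"].sum())
    ci_binom = binomtest(n_within, n).proportion_ci(
        confidence_level=0.95, method="exact"
    )
    return AgreementReport(
        n_assessments=n,
        n_within_band=n_within,
        fraction_within=n_within / n,
        ci_low=float(ci_binom.low),
        ci_high=float(ci_binom.high),
        level=level,
        k=k,
        detail=detail,
    )
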
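"""Volume / effective-diameter conversions.

The effective diameter of a lesion is the diameter of the sphere whose
volume equals the measured volume, ``d = 2 * (3V / 4pi)^(1/3)``.  Relative
changes therefore map between the two scales by cubing / cube-rooting the
ratio, which lets the volume decision thresholds be restated on the
diameter scale and compared with the one-dimensional RECIST thresholds
(-30% partial response, +20% progression).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .gh_core import ThresholdSet, round_half_away

__all__ = [
    "DiameterThresholdSet",
    "effective_diameter",
    "volume_from_diameter",
    "volume_ratio_to_diameter_ratio",
    "diameter_ratio_to_volume_ratio",
    "diameter_thresholds",
    "recist_volume_thresholds",
    "RECIST_DIAMETER_PCTS",
]

#: RECIST 1.1 thresholds on the longest-diameter scale (percent change).
RECIST_DIAMETER_PCTS = (-30, 20)


@dataclass(frozen=True)
class DiameterThresholdSet:
    """Volume decision thresholds restated as effective-diameter changes."""

    lower_pct: int
    upper_pct: int
    source_volume_thresholds: ThresholdSet


def effective_diameter(volume_cm3: float) -> float:
    """Diameter (mm) of the sphere with the given volume (cm^3)."""
    if volume_cm3 <= 0:
        raise ValueError(f"volume must be positive, got {volume_cm3}")
    return 10.0 * (6.0 * volume_cm3 / math.pi) ** (1.0 / 3.0)


def volume_from_diameter(diameter_mm: float) -> float:
    """Volume (cm^3) of the sphere with the given diameter (mm)."""
    if diameter_mm <= 0:
        raise ValueError(f"diameter must be positive, got {diameter_mm}")
    d_cm = diameter_mm / 10.0
    return math.pi * d_cm**3 / 6.0


def volume_ratio_to_diameter_ratio(v_ratio: float) -> float:
    """Cube root: the diameter ratio implied by a volume ratio."""
    if v_ratio <= 0:
        raise ValueError(f"ratio must be positive, got {v_ratio}")
    return v_ratio ** (1.0 / 3.0)


def diameter_ratio_to_volume_ratio(d_ratio: float) -> float:
    """Cube: the volume ratio implied by a diameter ratio."""
    if d_ratio <= 0:
        raise ValueError(f"ratio must be positive, got {d_ratio}")
    return d_ratio**3


def diameter_thresholds(thresholds: ThresholdSet) -> DiameterThresholdSet:
    """Restate volume thresholds on the effective-diameter scale.

    Uses the reported integer-percent volume thresholds (e.g. 0.65 / 1.55)
    as the ratios to convert, and rounds the resulting diameter changes
    half-away-from-zero; the default volume pair (-35%, +55%) maps to
    (-13%, +16%).
    """
    lo = volume_ratio_to_diameter_ratio(thresholds.lower_ratio_rounded)
    hi = volume_ratio_to_diameter_ratio(thresholds.upper_ratio_rounded)
    return DiameterThresholdSet(
        lower_pct=round_half_away(100.0 * (lo - 1.0)),
        upper_pct=round_half_away(100.0 * (hi - 1.0)),
        source_volume_thresholds=thresholds,
    )


def recist_volume_thresholds(
    diameter_pcts: tuple[int, int] = RECIST_DIAMETER_PCTS,
) -> tuple[int, int]:
    """Extrapolate diameter-scale thresholds to the volume scale by cubing.

    RECIST's (-30%, +20%) becomes approximately (-66%, +73%) in volume
    (the exact lower value is -65.7%, sometimes quoted truncated as -65%).
    """
    out = []
    for pct in diameter_pcts:
        v_ratio = diameter_ratio_to_volume_ratio(1.0 + pct / 100.0)
        out.append(round_half_away(100.0 * (v_ratio - 1.0)))
    return tuple(out)
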
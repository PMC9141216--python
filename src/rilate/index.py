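"""RILATE — Risk Index of Lateral Thermal Expansion — and group summaries.

RILATE relates irreversible damage to the potentially damaged region::

    RILATE = (necrosis-zone extent / critical-zone (>50 °C) extent) * 100

and is classified low (≤ 30 %), moderate (30–60 %], or high (> 60 %).  The
published class boundaries leave gaps (30–31 and 60–61 on the printed
percent scale); the closed rule [0, 30], (30, 60], (60, ∞) is adopted — it is
exhaustive, ordered, and consistent with every published class assignment.

Group-level indices use the ratio of group means (mean necrosis / mean
critical), which is how the published group values were formed; the mean of
per-sample ratios is also reported since the two differ (e.g. 18.5 vs 17.8
for marSeal above).  Indices are carried at full precision; rounding to the
published 1–2 decimals happens only in reports.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import validate_measurements


class RiskClass(str, enum.Enum):
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"


def rilate(necrosis_um: float, critical_um: float) -> float:
    """Per-sample risk index (%), full precision.

    ``critical_um`` must be positive and the necrosis extent cannot exceed the
    critical extent (the necrosis zone lies inside the >50 °C zone).
    """
    if not critical_um > 0:
        raise ValidationError("critical extent must be > 0 for index computation")
    if necrosis_um < 0:
        raise ValidationError("necrosis extent must be >= 0")
    if necrosis_um > critical_um:
        raise ValidationError(
            f"necrosis extent {necrosis_um} µm exceeds critical extent {critical_um} µm"
        )
    return 100.0 * necrosis_um / critical_um


def classify(index_percent: float) -> RiskClass:
    """Risk class of an index value: low ≤ 30 < moderate ≤ 60 < high."""
    if index_percent < 0:
        raise ValidationError("index must be >= 0")
    if index_percent <= 30.0:
        return RiskClass.LOW
    if index_percent <= 60.0:
        return RiskClass.MODERATE
    return RiskClass.HIGH


@dataclass(frozen=True)
class GroupSummary:
    """Per-instrument, per-side descriptive statistics.

    SDs use the n−1 (sample) denominator and are None for n < 2.
    ``group_rilate`` is the ratio-of-means index; ``mean_of_ratios`` averages
    the per-sample indices instead.
    """

    instrument_id: str
    side: str
    n: int
    critical_mean_um: float
    critical_sd_um: float | None
    necrosis_mean_um: float
    necrosis_sd_um: float | None
    frontier_mean_C: float
    frontier_sd_C: float | None
    group_rilate: float
    risk_class: RiskClass
    per_sample_rilate: np.ndarray
    mean_of_ratios: float


def per_sample_rilate(table: pd.DataFrame) -> pd.Series:
    """Per-row RILATE values of a measurement table (full precision)."""
    return pd.Series(
        [rilate(n, c) for n, c in zip(table["necrosis_extent_um"],
                                      table["critical_extent_um"])],
        index=table.index, name="rilate",
    )


def summarize_group(table: pd.DataFrame, instrument_id: str, side: str) -> GroupSummary:
    """Descriptive summary of one (instrument, side) group."""
    table = validate_measurements(table)
    g = table[(table["instrument_id"] == instrument_id) & (table["side"] == side)]
    if g.empty:
        raise ValidationError(f"no rows for ({instrument_id}, {side})")
    n = len(g)

    def _sd(col: str) -> float | None:
        return float(g[col].std(ddof=1)) if n >= 2 else None

    ratios = per_sample_rilate(g).to_numpy()
    group_idx = rilate(float(g["necrosis_extent_um"].mean()),
                       float(g["critical_extent_um"].mean()))
    return GroupSummary(
        instrument_id=instrument_id,
        side=side,
        n=n,
        critical_mean_um=float(g["critical_extent_um"].mean()),
        critical_sd_um=_sd("critical_extent_um"),
        necrosis_mean_um=float(g["necrosis_extent_um"].mean()),
        necrosis_sd_um=_sd("necrosis_extent_um"),
        frontier_mean_C=float(g["frontier_temp_C"].mean()),
        frontier_sd_C=_sd("frontier_temp_C"),
        group_rilate=group_idx,
        risk_class=classify(group_idx),
        per_sample_rilate=ratios,
        mean_of_ratios=float(ratios.mean()),
    )


def summarize_all(table: pd.DataFrame) -> list[GroupSummary]:
    """Summaries for every (instrument, side) group, in table order."""
    table = validate_measurements(table)
    seen: list[tuple[str, str]] = []
    for _, row in table.iterrows():
        key = (row["instrument_id"], row["side"])
        if key not in seen:
            seen.append(key)
    return [summarize_group(table, inst, side) for inst, side in seen]
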
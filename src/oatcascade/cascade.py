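"""Four-stage cascade-of-care classification and stratified tabulation.

Patients are staged by their longest retention in treatment: under 90 days,
90–365 days, one to two years, or over two years. The verbal stage labels
overlap at the year boundaries, so the implemented partition is
[0, 90) / [90, 365] / (365, 730] / (730, inf), with one year = 365 days and
leap days ignored. Tables stratify the stage mix by year of first treatment
initiation or by geographic region.
"""

from __future__ import annotations

from enum import Enum

import pandas as pd

from ._util import percent, round_half_up


class CascadeStage(str, Enum):
    LT_90 = "LT_90"
    D90_365 = "D90_365"
    Y1_2 = "Y1_2"
    GT_2Y = "GT_2Y"

    @property
    def label(self) -> str:
        return _LABELS[self]


_LABELS = {
    CascadeStage.LT_90: "Less than 90 days",
    CascadeStage.D90_365: "90 to 365 days",
    CascadeStage.Y1_2: "One to two years",
    CascadeStage.GT_2Y: "Over two years",
}

STAGE_ORDER: list[CascadeStage] = [
    CascadeStage.LT_90,
    CascadeStage.D90_365,
    CascadeStage.Y1_2,
    CascadeStage.GT_2Y,
]

#: Non-reference stages modelled against the "< 90 days" baseline.
NONREF_STAGES: list[CascadeStage] = STAGE_ORDER[1:]

REGIONS = ("Northern_rural", "Northern_urban", "Southern_rural", "Southern_urban")


def classify_stage(longest_retention_days: int) -> CascadeStage:
    """Map a longest-retention duration (days) to its cascade stage."""
    d = longest_retention_days
    if d < 0:
        raise ValueError(f"duration must be nonnegative, got {d}")
    if d < 90:
        return CascadeStage.LT_90
    if d <= 365:
        return CascadeStage.D90_365
    if d <= 730:
        return CascadeStage.Y1_2
    return CascadeStage.GT_2Y


def _table_for(stages: pd.Series, stratum: str) -> pd.DataFrame:
    counts = stages.value_counts()
    total = int(counts.sum())
    rows = []
    for stage in STAGE_ORDER:
        n = int(counts.get(stage.value, 0))
        rows.append(
            {
                "stratum": stratum,
                "stage": stage.value,
                "stage_label": stage.label,
                "count": n,
                "proportion": n / total if total else float("nan"),
                "total": total,
            }
        )
    return pd.DataFrame(rows)


def cascade_table(histories: pd.DataFrame, stratum: str = "overall") -> pd.DataFrame:
    """Stage counts and proportions for one stratum of patients."""
    stages = histories["longest_retention_days"].map(lambda d: classify_stage(int(d)).value)
    return _table_for(stages, stratum)


def cascade_by_year(histories: pd.DataFrame) -> pd.DataFrame:
    """Stage mix per calendar year of first initiation (one block per year)."""
    if len(histories) == 0:
        raise ValueError("histories table is empty")
    df = histories.copy()
    df["year"] = pd.to_datetime(df["first_initiation_date"]).dt.year
    blocks = [
        cascade_table(grp, stratum=str(year)) for year, grp in df.groupby("year", sort=True)
    ]
    return pd.concat(blocks, ignore_index=True)


def cascade_by_region(histories: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Stage mix per region; patients with missing region are excluded.

    Returns the stacked tables and the excluded-for-missing-region count —
    mirrors the subgroup design in which patients whose postal codes could
    not be geocoded drop out of the geographic analysis only.
    """
    missing = histories["region"].isna()
    known = histories[~missing]
    bad = ~known["region"].isin(REGIONS)
    if bad.any():
        raise ValueError(f"unknown region label(s): {sorted(known.loc[bad, 'region'].unique())}")
    blocks = [
        cascade_table(grp, stratum=str(region))
        for region, grp in known.groupby("region", sort=True)
    ]
    return pd.concat(blocks, ignore_index=True), int(missing.sum())


def yearly_percent(count: int, total: int) -> float:
    """Integer percent (half-up), the rounding used in the yearly cascade."""
    return percent(count, total, decimals=0)


def table_percent(count: int, total: int) -> float:
    """One-decimal percent (half-up), the rounding used in report tables."""
    return percent(count, total, decimals=1)


def display_proportions(table: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    out = table.copy()
    out["percent"] = [
        round_half_up(100 * p, decimals) for p in out["proportion"]
    ]
    return out
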
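"""Per-patient covariate derivation: demographics, geography, urine-drug-screen
positivity quadrants, and dose summaries.

Geography follows the Ontario conventions: "Northern" means health regions
(LHINs) 13 or 14, and "rural" means a Rurality Index of Ontario (RIO) score
of 40 or higher, giving four strata. Urine drug screens (UDS) are summarised
per drug class as the proportion of positive tests over the whole study
window and binned into quadrants (0–25 / 26–50 / 51–75 / 76–100 percent).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import DAYS_PER_MONTH
from .cascade import classify_stage
from .episode_builder import PatientTreatmentHistory
from .errors import SchemaError

logger = logging.getLogger(__name__)

DRUG_CLASSES = (
    "amphetamine_type_stimulant",
    "fentanyl",
    "cocaine",
    "cannabis",
    "other_opioid",
)

QUADRANTS = ("Q0_25", "Q26_50", "Q51_75", "Q76_100")

QUADRANT_LABELS = {
    "Q0_25": "0-25%",
    "Q26_50": "26-50%",
    "Q51_75": "51-75%",
    "Q76_100": "76-100%",
}

AGE_GROUPS = ("<25", "25-45", "46-65", "65+")

SEXES = ("F", "M", "missing")

UDS_COLUMNS = ["patient_id", "date", "drug_class", "result"]
DEMOGRAPHIC_COLUMNS = ["patient_id", "sex", "birth_year", "rio_score", "health_region_code"]


def uds_quadrant(proportion_positive: float) -> str:
    """Bin a positive-test proportion into its quadrant.

    Quarter bins closed on the right: p <= 0.25 is the first quadrant, so a
    patient at exactly one-in-four positives sits with the low-use group and
    26% falls in the second bin, matching the printed labels.
    """
    p = proportion_positive
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion must be in [0, 1], got {p}")
    if p <= 0.25:
        return "Q0_25"
    if p <= 0.50:
        return "Q26_50"
    if p <= 0.75:
        return "Q51_75"
    return "Q76_100"


def avg_monthly_uds(n_tests: int, days_in_treatment: int) -> float:
    """Average screens per month: total tests over total treatment time,
    converted at 30.4375 days/month (insensitive to calendar alignment)."""
    if days_in_treatment < 1:
        raise ValueError("days_in_treatment must be >= 1")
    return n_tests / (days_in_treatment / DAYS_PER_MONTH)


def classify_region(rio_score, health_region_code) -> str | None:
    """Four-way geography label, or None when either input is missing.

    Northern iff the health-region (LHIN) code is 13 or 14; rural iff the
    RIO score is at least 40.
    """
    if pd.isna(rio_score) or pd.isna(health_region_code):
        return None
    code = int(health_region_code)
    if not 1 <= code <= 14:
        raise ValueError(f"health_region_code must be 1-14, got {code}")
    if rio_score < 0:
        raise ValueError(f"rio_score must be >= 0, got {rio_score}")
    ns = "Northern" if code in (13, 14) else "Southern"
    ru = "rural" if rio_score >= 40 else "urban"
    return f"{ns}_{ru}"


def age_group(age_years: float) -> str:
    """Age-group partition; exactly-65-year-olds go with 46-65."""
    a = age_years
    if a < 0:
        raise ValueError(f"age must be nonnegative, got {a}")
    if a < 25:
        return "<25"
    if a <= 45:
        return "25-45"
    if a <= 65:
        return "46-65"
    return "65+"


@dataclass
class DoseSummary:
    starting_dose_mg: float
    peak_dose_mg: float
    start_above_median: bool
    peak_above_median: bool


def dose_summaries(histories: dict[str, PatientTreatmentHistory]) -> pd.DataFrame:
    """Start/peak dose per patient plus above-cohort-median indicators.

    The start dose is the first dose of episode 1; the peak is the maximum
    dose across all of the patient's episodes of the starting medication.
    Medians of the peak dose are taken per medication over the cohort, and
    both indicators compare strictly against that median peak dose (so a
    single-patient cohort gets False for both).
    """
    rows = []
    for pid, h in histories.items():
        med = h.starting_medication
        peak = max(
            (e.peak_dose_mg for e in h.episodes if e.starting_medication == med),
            default=h.episodes[0].peak_dose_mg,
        )
        rows.append(
            {
                "patient_id": pid,
                "starting_medication": med,
                "start_dose_mg": h.episodes[0].start_dose_mg,
                "peak_dose_mg": peak,
            }
        )
    df = pd.DataFrame(rows)
    med_peak = df.groupby("starting_medication")["peak_dose_mg"].transform("median")
    df["median_peak_dose_mg"] = med_peak
    df["start_above_median"] = df["start_dose_mg"] > med_peak
    df["peak_above_median"] = df["peak_dose_mg"] > med_peak
    return df


def uds_summaries(uds: pd.DataFrame, known_patients: set[str]) -> tuple[pd.DataFrame, int]:
    """Per-patient, per-class positivity proportions and quadrants.

    Patients with zero tests of a class get proportion 0 (first quadrant)
    with ``n_tests`` 0 so the flag is recoverable. UDS rows for patients not
    in the dose table are excluded with a warning; the count is returned.
    """
    missing = [c for c in UDS_COLUMNS if c not in uds.columns]
    if missing:
        raise SchemaError(f"UDS table missing required column(s): {missing}")
    bad_class = ~uds["drug_class"].isin(DRUG_CLASSES)
    if bad_class.any():
        raise SchemaError(
            f"unknown drug_class value(s): {sorted(uds.loc[bad_class, 'drug_class'].unique())}"
        )
    unmatched = ~uds["patient_id"].astype(str).isin(known_patients)
    n_unmatched = int(unmatched.sum())
    if n_unmatched:
        logger.warning("excluding %d UDS row(s) for patients with no dose records", n_unmatched)
    df = uds[~unmatched].copy()
    df["positive"] = (df["result"] == "positive").astype(int)

    grouped = df.groupby(["patient_id", "drug_class"]).agg(
        n_tests=("positive", "size"), n_positive=("positive", "sum")
    )
    out = []
    for pid in sorted(known_patients):
        row: dict = {"patient_id": pid}
        for cls in DRUG_CLASSES:
            try:
                n, npos = grouped.loc[(pid, cls)]
            except KeyError:
                n, npos = 0, 0
            prop = npos / n if n else 0.0
            row[f"uds_n_{cls}"] = int(n)
            row[f"uds_prop_{cls}"] = prop
            row[f"uds_quadrant_{cls}"] = uds_quadrant(prop)
        # distinct test dates = test visits, across all classes
        pid_rows = df[df["patient_id"] == pid]
        row["uds_n_visits"] = int(pid_rows["date"].nunique())
        out.append(row)
    return pd.DataFrame(out), n_unmatched


def build_patient_summaries(
    histories: dict[str, PatientTreatmentHistory],
    uds: pd.DataFrame,
    demographics: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Assemble the one-row-per-patient analysis table.

    Joins retention summaries, dose summaries, UDS quadrants and
    demographics on patient_id. Missing sex and region are preserved as
    explicit missing categories; the returned info dict counts unmatched UDS
    rows and missing-geography patients.
    """
    missing_cols = [c for c in DEMOGRAPHIC_COLUMNS if c not in demographics.columns]
    if missing_cols:
        raise SchemaError(f"demographics table missing column(s): {missing_cols}")

    hist_rows = []
    for pid, h in histories.items():
        total_days = sum(e.duration_days for e in h.episodes)
        hist_rows.append(
            {
                "patient_id": pid,
                "n_attempts": h.n_attempts,
                "longest_retention_days": h.longest_retention_days,
                "days_in_treatment": total_days,
                "first_initiation_date": pd.Timestamp(h.first_initiation_date),
                "stage": classify_stage(h.longest_retention_days).value,
            }
        )
    base = pd.DataFrame(hist_rows)

    uds_df, n_unmatched_uds = uds_summaries(uds, set(histories))
    dose_df = dose_summaries(histories)
    demo = demographics.copy()
    demo["patient_id"] = demo["patient_id"].astype(str)

    df = base.merge(dose_df, on="patient_id", how="left")
    df = df.merge(uds_df, on="patient_id", how="left")
    df = df.merge(demo, on="patient_id", how="left")

    df["avg_monthly_uds"] = [
        avg_monthly_uds(int(n), int(d))
        for n, d in zip(df["uds_n_visits"].fillna(0), df["days_in_treatment"])
    ]
    df["sex"] = df["sex"].where(df["sex"].isin(["F", "M"]), "missing")
    df["age_at_initiation"] = (
        df["first_initiation_date"].dt.year - df["birth_year"]
    ).astype(float)
    df["age_group"] = [
        age_group(a) if not np.isnan(a) else None for a in df["age_at_initiation"]
    ]
    df["region"] = [
        classify_region(r, c) for r, c in zip(df["rio_score"], df["health_region_code"])
    ]
    info = {
        "uds_rows_unmatched": n_unmatched_uds,
        "missing_region": int(df["region"].isna().sum()),
        "missing_sex": int((df["sex"] == "missing").sum()),
        "n_patients": len(df),
    }
    return df, info
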
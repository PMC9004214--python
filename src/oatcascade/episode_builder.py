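"""Reconstruct treatment episodes from dispensed-dose records.

A treatment episode (clinically, a "treatment window") is a maximal run of
opioid-agonist dosing not interrupted by a disqualifying dose-free gap.
Clinical guidelines call for re-induction at starting doses after 5 days
without methadone or 6 days without buprenorphine/naloxone, so those gaps
define the end of an episode: a run of at least ``gap`` whole calendar days
with no dose splits the record into two episodes (attempts). Everything
downstream — retention staging, attempt counts, administrative loss to
follow-up — derives from this segmentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .errors import RowValidationError, SchemaError

logger = logging.getLogger(__name__)

MEDICATIONS = ("methadone", "buprenorphine_naloxone")

DOSE_COLUMNS = ["patient_id", "date", "medication", "dose_mg"]

EPISODE_COLUMNS = [
    "patient_id",
    "episode_index",
    "start_date",
    "end_date",
    "duration_days",
    "starting_medication",
    "start_dose_mg",
    "peak_dose_mg",
]


@dataclass(frozen=True)
class GapRule:
    """Medication-specific disqualifying dose-free gaps, in whole days.

    An episode ends once the patient has ``methadone_gap_days`` days without
    a methadone dose (default 5) or ``buprenorphine_gap_days`` days without a
    buprenorphine dose (default 6); the applicable gap is that of the most
    recent dose's medication.
    """

    methadone_gap_days: int = 5
    buprenorphine_gap_days: int = 6

    def __post_init__(self) -> None:
        if self.methadone_gap_days < 1 or self.buprenorphine_gap_days < 1:
            raise ValueError("gap days must be >= 1")

    def gap_for(self, medication: str) -> int:
        if medication == "methadone":
            return self.methadone_gap_days
        if medication == "buprenorphine_naloxone":
            return self.buprenorphine_gap_days
        raise RowValidationError(f"unknown medication: {medication!r}")


@dataclass(frozen=True)
class TreatmentEpisode:
    """One maximal dosing run for a patient.

    ``duration_days`` counts both endpoints (a single-dose episode lasts one
    day); ``starting_medication`` is the medication of the first dose, and
    medication switches inside an episode neither split it nor are tracked.
    """

    patient_id: str
    episode_index: int
    start_date: date
    end_date: date
    duration_days: int
    starting_medication: str
    start_dose_mg: float
    peak_dose_mg: float


@dataclass
class PatientTreatmentHistory:
    patient_id: str
    episodes: list[TreatmentEpisode] = field(default_factory=list)

    @property
    def n_attempts(self) -> int:
        return len(self.episodes)

    @property
    def longest_retention_days(self) -> int:
        return max(e.duration_days for e in self.episodes)

    @property
    def first_initiation_date(self) -> date:
        return self.episodes[0].start_date

    @property
    def starting_medication(self) -> str:
        return self.episodes[0].starting_medication

    def admin_ltfu(self, study_end: date) -> bool:
        """Administrative loss to follow-up: the last treatment window ended
        before the study window closed and no later window was started."""
        return self.episodes[-1].end_date < study_end


def _as_date(x) -> date:
    if isinstance(x, date) and not isinstance(x, pd.Timestamp):
        return x
    return pd.Timestamp(x).date()


def _prepare_doses(doses: pd.DataFrame) -> pd.DataFrame:
    """Validate, collapse duplicates (max dose wins), and sort by date."""
    missing = [c for c in ("date", "medication", "dose_mg") if c not in doses.columns]
    if missing:
        raise SchemaError(f"dose table missing required column(s): {missing}")
    bad = ~doses["medication"].isin(MEDICATIONS)
    if bad.any():
        rows = doses.index[bad].tolist()[:5]
        raise RowValidationError(
            f"unknown medication in {int(bad.sum())} row(s), e.g. rows {rows}: "
            f"{sorted(doses.loc[bad, 'medication'].unique())}"
        )
    df = doses.copy()
    df["date"] = pd.to_datetime(df["date"])
    n_before = len(df)
    df = (
        df.groupby(["date", "medication"], as_index=False)
        .agg(dose_mg=("dose_mg", "max"))
        .sort_values(["date", "medication"], kind="mergesort")
        .reset_index(drop=True)
    )
    n_dupes = n_before - len(df)
    if n_dupes:
        logger.warning("collapsed %d duplicate (date, medication) dose row(s)", n_dupes)
    return df


def build_episodes(doses: pd.DataFrame, rule: GapRule | None = None) -> list[TreatmentEpisode]:
    """Segment one patient's dose records into treatment episodes.

    Input row order is irrelevant (records are sorted internally) and
    duplicate (date, medication) rows are collapsed keeping the maximum dose.
    The dose-free span between two consecutive doses is
    ``next_date - last_date - 1`` whole days; the episode splits when that
    span reaches the gap of the most recent dose's medication. When two
    medications are dosed on the same day, the more permissive (larger) gap
    applies.

    Returns an empty list for an empty input.
    """
    rule = rule or GapRule()
    if len(doses) == 0:
        return []
    pid = str(doses["patient_id"].iloc[0]) if "patient_id" in doses.columns else ""
    df = _prepare_doses(doses)

    # Per-day gap clock: collapse same-day rows, remembering the larger gap.
    gap_map = {m: rule.gap_for(m) for m in MEDICATIONS}
    df["_gap"] = df["medication"].map(gap_map)
    day = df.groupby("date", sort=True).agg(
        gap=("_gap", "max"),
        first_med=("medication", "first"),
        first_dose=("dose_mg", "first"),
        max_dose=("dose_mg", "max"),
    )
    ordinals = day.index.to_numpy().astype("datetime64[D]").astype(np.int64)
    gaps = day["gap"].to_numpy()
    dose_free = np.diff(ordinals) - 1
    breaks = np.flatnonzero(dose_free >= gaps[:-1])
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(ordinals) - 1]))
    peaks = np.maximum.reduceat(day["max_dose"].to_numpy(), starts)

    dates = day.index
    episodes: list[TreatmentEpisode] = []
    for idx, (s, e) in enumerate(zip(starts, ends), start=1):
        start_d, end_d = dates[s].date(), dates[e].date()
        episodes.append(
            TreatmentEpisode(
                patient_id=pid,
                episode_index=idx,
                start_date=start_d,
                end_date=end_d,
                duration_days=(end_d - start_d).days + 1,
                starting_medication=day["first_med"].iloc[s],
                start_dose_mg=float(day["first_dose"].iloc[s]),
                peak_dose_mg=float(peaks[idx - 1]),
            )
        )
    return episodes


def summarize_history(
    episodes: list[TreatmentEpisode], study_end: date | None = None
) -> PatientTreatmentHistory:
    """Collapse a patient's episode list into attempt/retention summaries."""
    if not episodes:
        raise ValueError("a patient with no episodes is not in the cohort")
    hist = PatientTreatmentHistory(patient_id=episodes[0].patient_id, episodes=list(episodes))
    return hist


def build_all_histories(
    doses: pd.DataFrame,
    rule: GapRule | None = None,
    study_start: date | None = None,
    study_end: date | None = None,
) -> dict[str, PatientTreatmentHistory]:
    """Build per-patient histories for a whole dose table.

    Doses after ``study_end`` are dropped with a logged warning (episodes are
    right-truncated at the study boundary); doses before ``study_start`` are
    dropped likewise when a start is given.
    """
    rule = rule or GapRule()
    df = doses.copy()
    df["date"] = pd.to_datetime(df["date"])
    if study_end is not None:
        after = df["date"].dt.date > _as_date(study_end)
        if after.any():
            logger.warning("dropping %d dose(s) after study_end", int(after.sum()))
            df = df[~after]
    if study_start is not None:
        before = df["date"].dt.date < _as_date(study_start)
        if before.any():
            logger.warning("dropping %d dose(s) before study_start", int(before.sum()))
            df = df[~before]
    histories: dict[str, PatientTreatmentHistory] = {}
    for pid, grp in df.groupby("patient_id", sort=True):
        eps = build_episodes(grp, rule)
        if eps:
            eps = [
                TreatmentEpisode(str(pid), e.episode_index, e.start_date, e.end_date,
                                 e.duration_days, e.starting_medication,
                                 e.start_dose_mg, e.peak_dose_mg)
                for e in eps
            ]
            histories[str(pid)] = summarize_history(eps)
    return histories


def histories_frame(
    histories: dict[str, PatientTreatmentHistory], study_end: date | None = None
) -> pd.DataFrame:
    """One-row-per-patient summary frame of attempt and retention measures."""
    rows = []
    for pid, h in histories.items():
        rows.append(
            {
                "patient_id": pid,
                "n_attempts": h.n_attempts,
                "longest_retention_days": h.longest_retention_days,
                "first_initiation_date": h.first_initiation_date,
                "starting_medication": h.starting_medication,
                "admin_ltfu": h.admin_ltfu(_as_date(study_end)) if study_end is not None else None,
            }
        )
    return pd.DataFrame(rows)


def read_dose_records(path) -> pd.DataFrame:
    """Read ``dose_records.csv`` (patient_id, date ISO-8601, medication, dose_mg).

    Malformed dates are reported with their (1-based, header-exclusive) row
    numbers; duplicated (patient, date, medication) rows are collapsed with a
    logged warning count.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in DOSE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")
    parsed = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & df["date"].notna()
    if bad.any():
        rows = (df.index[bad] + 1).tolist()
        raise RowValidationError(
            f"{path}: {int(bad.sum())} unparseable date(s) at row(s) {rows[:10]}"
        )
    df["date"] = parsed
    bad_med = ~df["medication"].isin(MEDICATIONS)
    if bad_med.any():
        rows = (df.index[bad_med] + 1).tolist()
        raise RowValidationError(
            f"{path}: unknown medication at row(s) {rows[:10]}"
        )
    n_before = len(df)
    df = (
        df.groupby(["patient_id", "date", "medication"], as_index=False)
        .agg(dose_mg=("dose_mg", "max"))
    )
    n_dupes = n_before - len(df)
    if n_dupes:
        logger.warning("%s: deduplicated %d row(s)", path, n_dupes)
    return df.sort_values(["patient_id", "date", "medication"], kind="mergesort").reset_index(drop=True)


def episodes_frame(histories: dict[str, PatientTreatmentHistory]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": e.patient_id,
            "episode_index": e.episode_index,
            "start_date": e.start_date.isoformat(),
            "end_date": e.end_date.isoformat(),
            "duration_days": e.duration_days,
            "starting_medication": e.starting_medication,
            "start_dose_mg": e.start_dose_mg,
            "peak_dose_mg": e.peak_dose_mg,
        }
        for h in histories.values()
        for e in h.episodes
    ]
    return pd.DataFrame(rows, columns=EPISODE_COLUMNS)


def write_episodes(path, histories: dict[str, PatientTreatmentHistory]) -> pd.DataFrame:
    df = episodes_frame(histories)
    df.to_csv(path, index=False)
    return df
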
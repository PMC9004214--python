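"""Shared fixtures and the independent day-scan oracle for episode splitting."""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from oatcascade.episode_builder import GapRule

DAY0 = date(2015, 1, 1)


def doses_frame(day_offsets, medication="methadone", dose_mg=50.0, patient_id="p1"):
    """Dose table at integer day offsets from a fixed anchor date.

    ``day_offsets`` may be ints or (int, medication) pairs to mix drugs.
    """
    rows = []
    for item in day_offsets:
        if isinstance(item, tuple):
            off, med = item
        else:
            off, med = item, medication
        rows.append(
            {
                "patient_id": patient_id,
                "date": DAY0 + timedelta(days=int(off)),
                "medication": med,
                "dose_mg": dose_mg,
            }
        )
    return pd.DataFrame(rows)


def day_scan_oracle(dose_days, rule: GapRule):
    """Brute-force reference segmentation: walk every calendar day between the
    first and last dose, tracking the dose-free run, and split whenever the
    run reaches the gap of the most recent dose's medication (the larger gap
    on days with both drugs). Returns (start_offset, end_offset) pairs.

    Deliberately day-by-day and stateful — independent of the vectorized
    implementation under test.
    """
    day_meds: dict[int, list[str]] = {}
    for item in dose_days:
        off, med = item if isinstance(item, tuple) else (item, "methadone")
        day_meds.setdefault(int(off), []).append(med)
    lo, hi = min(day_meds), max(day_meds)
    episodes = []
    cur_start = None
    last_dose = None
    cur_gap = None
    for d in range(lo, hi + 1):
        if d not in day_meds:
            continue
        gap = max(rule.gap_for(m) for m in day_meds[d])
        if cur_start is None:
            cur_start = d
        elif d - last_dose - 1 >= cur_gap:
            episodes.append((cur_start, last_dose))
            cur_start = d
        last_dose = d
        cur_gap = gap
    episodes.append((cur_start, last_dose))
    return episodes


def episodes_to_offsets(episodes):
    """Implementation episodes -> (start_offset, end_offset) pairs."""
    return [
        ((e.start_date - DAY0).days, (e.end_date - DAY0).days) for e in episodes
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic 60-patient synthetic cohort shared across tests."""
    from oatcascade import CohortConfig, generate_cohort

    cfg = CohortConfig(n_patients=60, seed=20240901)
    return cfg, generate_cohort(cfg)
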
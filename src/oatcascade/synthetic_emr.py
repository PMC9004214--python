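"""Seeded synthetic EMR cohorts with known ground truth.

The study data this pipeline targets — clinic dose logs, urine-drug-screen
results and demographics for tens of thousands of opioid-agonist-treatment
patients — are not publicly available, so this module generates cohorts
with the same shape: daily/near-daily dosing runs separated by planted
dose-free gaps, per-drug UDS positivity, and a demographic mix over four
Ontario-style geographic strata. Every planted quantity (episode
boundaries, attempt counts, stage, region, positivity rates) is returned as
ground truth, so episode reconstruction and model estimation have exact
recovery tests.

Two structural guarantees make planted episodes recoverable by the gap-rule
segmentation: inter-episode gaps are drawn at (or clamped to) at least the
disqualifying gap of the episode's medication, and within-episode runs of
missed dosing days are capped strictly below that gap. Default parameter
values mirror the published cohort's headline characteristics (77.6%
methadone starts, mean 2.17 treatment attempts, ~6 screens per month,
61.4% male, mean age 35.6, region mix 4.3/17.9/3.4/74.4 percent with
~14.5% missing geography).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import DAYS_PER_MONTH
from .cascade import REGIONS, classify_stage
from .covariates import DRUG_CLASSES
from .episode_builder import GapRule
from .errors import CohortConfigError


def _default_uds_positivity() -> dict[str, float]:
    return {
        "amphetamine_type_stimulant": 0.15,
        "fentanyl": 0.15,
        "cocaine": 0.25,
        "cannabis": 0.35,
        "other_opioid": 0.20,
    }


def _default_region_mix() -> dict[str, float]:
    return {
        "Northern_rural": 0.043,
        "Northern_urban": 0.179,
        "Southern_rural": 0.034,
        "Southern_urban": 0.744,
    }


def _default_sex_mix() -> dict[str, float]:
    return {"F": 0.385, "M": 0.614, "missing": 0.001}


@dataclass
class CohortConfig:
    """Knobs of the synthetic cohort; defaults emulate the published cohort."""

    n_patients: int = 100
    study_start: date = date(2014, 1, 1)
    study_end: date = date(2020, 12, 31)
    #: probability that a patient's starting medication is methadone
    medication_mix: float = 0.776
    #: episode length in days; lognormal median/sigma spreads patients
    #: across all four retention stages
    episode_length_distribution: dict = field(
        default_factory=lambda: {"name": "lognormal", "median": 400.0, "sigma": 1.5}
    )
    #: dose-free gap between consecutive episodes (days); clamped up to the
    #: medication's disqualifying gap so attempts stay recoverable
    inter_episode_gap_distribution: dict = field(
        default_factory=lambda: {"name": "uniform_int", "low": 7, "high": 90}
    )
    #: number of planted episodes per patient
    attempts_distribution: dict = field(
        default_factory=lambda: {"name": "one_plus_poisson", "lam": 1.17}
    )
    #: per-day probability of a skipped dose inside an episode (take-home
    #: doses etc.); consecutive missed runs are capped below the gap rule
    dosing_miss_probability: float = 0.10
    uds_rate_per_month: float = 6.0
    uds_positivity: dict = field(default_factory=_default_uds_positivity)
    region_mix: dict = field(default_factory=_default_region_mix)
    region_missing_probability: float = 0.145
    sex_mix: dict = field(default_factory=_default_sex_mix)
    age_distribution: dict = field(
        default_factory=lambda: {"name": "normal", "mean": 35.6, "sd": 10.7, "min": 18, "max": 85}
    )
    gap_rule: GapRule = field(default_factory=GapRule)
    #: (start_mg, peak_mg) per medication; doses ramp linearly to peak
    dose_profile: dict = field(
        default_factory=lambda: {
            "methadone": (30.0, 80.0),
            "buprenorphine_naloxone": (8.0, 24.0),
        }
    )
    dose_ramp_days: int = 42
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise CohortConfigError("n_patients must be nonnegative")
        if self.study_end < self.study_start:
            raise CohortConfigError("study_end is before study_start")
        for name in ("medication_mix", "dosing_miss_probability", "region_missing_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CohortConfigError(f"{name} must be in [0, 1], got {v}")
        if self.uds_rate_per_month < 0:
            raise CohortConfigError("uds_rate_per_month must be nonnegative")
        for cls, p in self.uds_positivity.items():
            if cls not in DRUG_CLASSES:
                raise CohortConfigError(f"uds_positivity: unknown drug class {cls!r}")
            if not 0.0 <= p <= 1.0:
                raise CohortConfigError(f"uds_positivity[{cls!r}] must be in [0, 1]")
        if set(self.region_mix) != set(REGIONS):
            raise CohortConfigError("region_mix must cover exactly the four regions")
        if any(p < 0 for p in self.region_mix.values()):
            raise CohortConfigError("region_mix probabilities must be nonnegative")
        if abs(sum(self.region_mix.values()) - 1.0) > 1e-9:
            raise CohortConfigError("region_mix must sum to 1 within 1e-9")
        if any(p < 0 for p in self.sex_mix.values()):
            raise CohortConfigError("sex_mix probabilities must be nonnegative")
        if abs(sum(self.sex_mix.values()) - 1.0) > 1e-9:
            raise CohortConfigError("sex_mix must sum to 1 within 1e-9")
        gap_floor = min(self.gap_rule.methadone_gap_days, self.gap_rule.buprenorphine_gap_days)
        d = self.inter_episode_gap_distribution
        if d.get("name") == "uniform_int" and d.get("low", gap_floor) < 1:
            raise CohortConfigError("inter_episode_gap_distribution low bound must be >= 1")


@dataclass
class GroundTruth:
    """Planted per-patient truth: episodes, stage, region, UDS rates."""

    patients: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.patients, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        return cls(patients=json.loads(Path(path).read_text()))


def _draw_days(dist: dict, rng: np.random.Generator) -> int:
    name = dist.get("name")
    if name == "fixed":
        return int(dist["value"])
    if name == "uniform_int":
        return int(rng.integers(dist["low"], dist["high"] + 1))
    if name == "lognormal":
        return max(1, int(round(np.exp(rng.normal(np.log(dist["median"]), dist["sigma"])))))
    if name == "one_plus_poisson":
        return 1 + int(rng.poisson(dist["lam"]))
    raise CohortConfigError(f"unknown distribution name {name!r}")


def _dose_ramp(duration: int, start: float, peak: float, ramp: int) -> np.ndarray:
    """Daily dose values: linear ramp from start to peak, then constant."""
    ramp = max(1, min(ramp, duration))
    vals = np.full(duration, peak)
    if ramp > 1:
        frac = np.arange(ramp - 1) / (ramp - 1)
        vals[: ramp - 1] = start + frac * (peak - start)
    return np.round(vals, 1)


def _miss_mask(duration: int, p: float, cap: int, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask of skipped dosing days; endpoints always dosed and
    consecutive missed runs truncated at ``cap`` days (a forced dose breaks
    every run that would reach cap + 1)."""
    if duration <= 2 or p <= 0.0:
        return np.zeros(duration, dtype=bool)
    miss = rng.random(duration) < p
    miss[0] = miss[-1] = False
    idx = np.flatnonzero(miss)
    if idx.size:
        new_run = np.concatenate(([True], np.diff(idx) > 1))
        run_starts = idx[new_run]
        run_id = np.cumsum(new_run) - 1
        pos = idx - run_starts[run_id]
        miss[idx[(pos + 1) % (cap + 1) == 0]] = False
    return miss


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (dose_records, uds_records, demographics, ground_truth).

    Identical (config, seed) gives identical outputs; every dose date lies
    inside the study window and every patient has at least one dose.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    window_days = (config.study_end - config.study_start).days + 1
    epoch = date(1970, 1, 1).toordinal()

    dose_pid, dose_day, dose_med, dose_mg = [], [], [], []
    uds_pid, uds_day, uds_cls, uds_res = [], [], [], []
    demo_rows: list[dict] = []
    truth = GroundTruth()
    width = max(4, len(str(max(config.n_patients, 1))))
    regions = list(REGIONS)
    region_p = np.array([config.region_mix[r] for r in regions])
    sexes = list(config.sex_mix)
    sex_p = np.array([config.sex_mix[s] for s in sexes])

    for i in range(config.n_patients):
        pid = f"P{i + 1:0{width}d}"
        medication = (
            "methadone" if rng.random() < config.medication_mix else "buprenorphine_naloxone"
        )
        gap_rule_days = config.gap_rule.gap_for(medication)
        n_episodes = _draw_days(config.attempts_distribution, rng)
        start_offset = int(rng.integers(0, window_days))
        cursor = config.study_start + timedelta(days=start_offset)

        factor = float(np.exp(rng.normal(0.0, 0.25)))
        base_start, base_peak = config.dose_profile[medication]
        start_mg, peak_mg = base_start * factor, base_peak * factor

        episodes: list[tuple[date, date]] = []
        dosed_parts: list[np.ndarray] = []  # day ordinals relative to epoch
        dose_parts: list[np.ndarray] = []
        for _ in range(n_episodes):
            if cursor > config.study_end:
                break
            duration = _draw_days(config.episode_length_distribution, rng)
            end = min(cursor + timedelta(days=duration - 1), config.study_end)
            duration = (end - cursor).days + 1
            episodes.append((cursor, end))
            # daily dosing with capped missed-day runs; endpoints always dosed
            miss = _miss_mask(duration, config.dosing_miss_probability, gap_rule_days - 1, rng)
            dosed = np.flatnonzero(~miss)
            day0 = cursor.toordinal() - epoch
            dosed_parts.append(day0 + dosed)
            dose_parts.append(
                _dose_ramp(duration, start_mg, peak_mg, config.dose_ramp_days)[dosed]
            )
            gap = max(_draw_days(config.inter_episode_gap_distribution, rng), gap_rule_days)
            cursor = end + timedelta(days=gap + 1)

        dosed_days = np.concatenate(dosed_parts)
        dose_pid.append(np.repeat(pid, len(dosed_days)))
        dose_day.append(dosed_days)
        dose_med.append(np.repeat(medication, len(dosed_days)))
        dose_mg.append(np.concatenate(dose_parts))

        total_days = sum((e - s).days + 1 for s, e in episodes)
        longest = max((e - s).days + 1 for s, e in episodes)

        # UDS visits on dosed days, all classes screened per visit
        n_visits = int(rng.poisson(config.uds_rate_per_month * total_days / DAYS_PER_MONTH))
        n_visits = min(n_visits, len(dosed_days))
        if n_visits:
            visit_days = dosed_days[
                np.sort(rng.choice(len(dosed_days), size=n_visits, replace=False))
            ]
            p_vec = np.array([config.uds_positivity.get(c, 0.0) for c in DRUG_CLASSES])
            positive = rng.random((n_visits, len(DRUG_CLASSES))) < p_vec
            uds_pid.append(np.repeat(pid, n_visits * len(DRUG_CLASSES)))
            uds_day.append(np.repeat(visit_days, len(DRUG_CLASSES)))
            uds_cls.append(np.tile(np.array(DRUG_CLASSES), n_visits))
            uds_res.append(np.where(positive.ravel(), "positive", "negative"))

        sex = sexes[rng.choice(len(sexes), p=sex_p)]
        ad = config.age_distribution
        age = float(np.clip(rng.normal(ad["mean"], ad["sd"]), ad["min"], ad["max"]))
        birth_year = episodes[0][0].year - int(round(age))
        if rng.random() < config.region_missing_probability:
            region, rio, code = None, np.nan, np.nan
        else:
            region = regions[rng.choice(len(regions), p=region_p)]
            north, rural = region.startswith("Northern"), region.endswith("rural")
            code = int(rng.integers(13, 15)) if north else int(rng.integers(1, 13))
            rio = int(rng.integers(40, 101)) if rural else int(rng.integers(0, 40))
        demo_rows.append(
            {
                "patient_id": pid,
                "sex": sex,
                "birth_year": birth_year,
                "rio_score": rio,
                "health_region_code": code,
            }
        )

        truth.patients[pid] = {
            "episodes": [
                {"start": s.isoformat(), "end": e.isoformat(), "medication": medication}
                for s, e in episodes
            ],
            "n_attempts": len(episodes),
            "longest_retention_days": longest,
            "stage": classify_stage(longest).value,
            "region": region,
            "uds_positivity": dict(config.uds_positivity),
        }

    def _dates(parts: list[np.ndarray]) -> np.ndarray:
        if not parts:
            return np.array([], dtype=str)
        days = np.concatenate(parts).astype("datetime64[D]")
        return np.datetime_as_string(days)

    def _cat(parts: list[np.ndarray]) -> np.ndarray:
        return np.concatenate(parts) if parts else np.array([], dtype=str)

    doses = pd.DataFrame(
        {
            "patient_id": _cat(dose_pid),
            "date": _dates(dose_day),
            "medication": _cat(dose_med),
            "dose_mg": _cat(dose_mg) if dose_mg else np.array([], dtype=float),
        }
    )
    uds = pd.DataFrame(
        {
            "patient_id": _cat(uds_pid),
            "date": _dates(uds_day),
            "drug_class": _cat(uds_cls),
            "result": _cat(uds_res),
        }
    )
    demographics = pd.DataFrame(
        demo_rows, columns=["patient_id", "sex", "birth_year", "rio_score", "health_region_code"]
    )
    return doses, uds, demographics, truth


def write_cohort(outdir, doses, uds, demographics, truth: GroundTruth) -> dict[str, str]:
    """Write the three CSV inputs plus the ground-truth JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "dose_records": str(outdir / "dose_records.csv"),
        "uds": str(outdir / "uds.csv"),
        "patients": str(outdir / "patients.csv"),
        "ground_truth": str(outdir / "ground_truth.json"),
    }
    doses.to_csv(paths["dose_records"], index=False)
    uds.to_csv(paths["uds"], index=False)
    demographics.to_csv(paths["patients"], index=False)
    truth.to_json(paths["ground_truth"])
    return paths


# ---------------------------------------------------------------------------
# Stage-odds simulator for regression recovery tests


def generate_stage_odds_cohort(
    stage_log_odds: dict[str, dict[str, float]],
    n: int,
    seed: int,
    intercepts: dict[str, float] | None = None,
    covariate_prob: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Draw patient stages from a known baseline-category logit.

    ``stage_log_odds`` maps binary covariate name -> {stage code: log-OR}
    relative to the "< 90 days" reference stage; covariates are independent
    Bernoulli(covariate_prob). Returns the patient table (covariates plus
    ``stage``) and the generating coefficients for recovery tests. ``n = 0``
    yields an empty table.
    """
    from .cascade import NONREF_STAGES

    intercepts = intercepts or {}
    for cov, coefs in stage_log_odds.items():
        for stage, beta in coefs.items():
            if not np.isfinite(beta):
                raise ValueError(f"non-finite coefficient for {cov!r}, stage {stage!r}")
    for stage, b in intercepts.items():
        if not np.isfinite(b):
            raise ValueError(f"non-finite intercept for stage {stage!r}")

    cov_names = list(stage_log_odds)
    columns = cov_names + ["stage"]
    if n == 0:
        return pd.DataFrame(columns=columns), {"coefficients": dict(stage_log_odds)}

    rng = np.random.default_rng(seed)
    X = (rng.random((n, len(cov_names))) < covariate_prob).astype(int)
    eta = np.zeros((n, 4))  # column 0 = reference
    for j, stage in enumerate(NONREF_STAGES, start=1):
        eta[:, j] = intercepts.get(stage.value, 0.0)
        for k, cov in enumerate(cov_names):
            eta[:, j] += stage_log_odds[cov].get(stage.value, 0.0) * X[:, k]
    prob = np.exp(eta - eta.max(axis=1, keepdims=True))
    prob /= prob.sum(axis=1, keepdims=True)
    u = rng.random(n)
    cum = prob.cumsum(axis=1)
    idx = (u[:, None] > cum).sum(axis=1)
    from .cascade import STAGE_ORDER

    stages = [STAGE_ORDER[i].value for i in idx]
    df = pd.DataFrame(X, columns=cov_names)
    df["stage"] = stages
    truth = {"coefficients": {c: dict(v) for c, v in stage_log_odds.items()},
             "intercepts": dict(intercepts)}
    return df, truth


#: Synthetic postal-prefix lookup (prefix -> RIO score, health-region code)
#: for interface tests only; bears no relation to real Ontario geocoding.
SYNTHETIC_POSTAL_LOOKUP: dict[str, tuple[int, int]] = {
    "P0A": (68, 13),  # Northern rural
    "P3E": (22, 13),  # Northern urban
    "K0H": (55, 10),  # Southern rural
    "M5V": (0, 7),    # Southern urban
    "N2L": (12, 3),
    "P7B": (30, 14),
}


def lookup_postal_prefix(prefix: str) -> tuple[int, int]:
    """Map a synthetic postal prefix to (rio_score, health_region_code)."""
    try:
        return SYNTHETIC_POSTAL_LOOKUP[prefix]
    except KeyError:
        raise KeyError(f"prefix {prefix!r} not in synthetic lookup table") from None
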
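"""End-to-end pipeline orchestration.

Runs ingest (or simulation) -> episode reconstruction -> patient summaries
-> cascade tables -> crude/adjusted odds-ratio models, writes every
artifact as CSV plus a JSON manifest, and keeps an exclusion ledger. The
two exclusion counts are tracked separately because they apply to
different analyses: patients missing geography drop out of the regional
tables only, while patients missing any modelled covariate drop out of the
regression only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd
import yaml

from .cascade import cascade_by_region, cascade_by_year, cascade_table
from .covariates import build_patient_summaries
from .episode_builder import GapRule, build_all_histories, episodes_frame, read_dose_records
from .regression import ModelSpec, fit_multinomial, characteristics_table, table2_covariates
from .synthetic_emr import CohortConfig, generate_cohort, write_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline configuration: either three input CSV paths or a simulation."""

    output_dir: str
    doses_path: str | None = None
    uds_path: str | None = None
    patients_path: str | None = None
    simulate: CohortConfig | None = None
    gap_rule: GapRule = field(default_factory=GapRule)
    study_start: date | None = None
    study_end: date = date(2020, 12, 31)
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        have_paths = all(p is not None for p in (self.doses_path, self.uds_path, self.patients_path))
        if have_paths == (self.simulate is not None):
            raise ValueError("supply exactly one of (three input paths) or (simulation config)")
        if self.study_start is not None and self.study_end < self.study_start:
            raise ValueError("study window is not well-ordered")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulate", None)
        gap = raw.pop("gap_rule", None)
        for key in ("study_start", "study_end"):
            if key in raw and raw[key] is not None:
                raw[key] = pd.Timestamp(raw[key]).date()
        cfg = cls(**raw)
        if sim is not None:
            for key in ("study_start", "study_end"):
                if key in sim:
                    sim[key] = pd.Timestamp(sim[key]).date()
            cfg.simulate = CohortConfig(**sim)
        if gap is not None:
            cfg.gap_rule = GapRule(**gap)
        return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a manifest of artifacts and the
    exclusion ledger. Deterministic given inputs and seed."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"artifacts": {}, "exclusions": {}, "stage_failed": None}

    def _record(name: str, path: Path, n_rows: int) -> None:
        manifest["artifacts"][name] = {"path": str(path), "rows": n_rows}

    try:
        stage = "ingest"
        if config.simulate is not None:
            sim = config.simulate
            sim.seed = config.seed
            doses, uds, demographics, truth = generate_cohort(sim)
            paths = write_cohort(outdir / "inputs", doses, uds, demographics, truth)
            for name, p in paths.items():
                _record(f"input_{name}", Path(p), -1)
            doses["date"] = pd.to_datetime(doses["date"])
        else:
            doses = read_dose_records(config.doses_path)
            uds = pd.read_csv(config.uds_path, dtype={"patient_id": str})
            demographics = pd.read_csv(config.patients_path, dtype={"patient_id": str})

        stage = "episodes"
        histories = build_all_histories(
            doses, config.gap_rule, study_start=config.study_start, study_end=config.study_end
        )
        eps = episodes_frame(histories)
        eps_path = outdir / "episodes.csv"
        eps.to_csv(eps_path, index=False)
        _record("episodes", eps_path, len(eps))

        stage = "summaries"
        summaries, info = build_patient_summaries(histories, uds, demographics)
        sum_path = outdir / "patient_summaries.csv"
        summaries.to_csv(sum_path, index=False)
        _record("patient_summaries", sum_path, len(summaries))
        manifest["exclusions"]["uds_rows_unmatched"] = info["uds_rows_unmatched"]
        manifest["exclusions"]["regional_excluded_missing_geography"] = info["missing_region"]

        stage = "cascade"
        overall = cascade_table(summaries)
        by_year = cascade_by_year(summaries)
        by_region, n_region_excl = cascade_by_region(summaries)
        for name, tbl in (
            ("cascade_overall", overall),
            ("cascade_by_year", by_year),
            ("cascade_by_region", by_region),
        ):
            p = outdir / f"{name}.csv"
            tbl.to_csv(p, index=False)
            _record(name, p, len(tbl))
        manifest["exclusions"]["regional_excluded_missing_geography"] = n_region_excl

        stage = "models"
        covs = table2_covariates()
        table1 = characteristics_table(summaries, covs)
        t1_path = outdir / "table1.csv"
        table1.to_csv(t1_path, index=False)
        _record("table1", t1_path, len(table1))

        or_frames = []
        for mode in ("crude", "adjusted"):
            tab, fit_info = fit_multinomial(
                summaries, ModelSpec(covariates=covs, mode=mode, alpha=config.alpha)
            )
            or_frames.append(tab)
            manifest["exclusions"][f"model_excluded_missing_covariates_{mode}"] = fit_info[
                "excluded_missing"
            ]
        or_table = pd.concat(or_frames, ignore_index=True)
        or_path = outdir / "or_table.csv"
        or_table.to_csv(or_path, index=False)
        _record("or_table", or_path, len(or_table))
    except Exception:
        manifest["stage_failed"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info(
        "pipeline complete: %d artifacts, exclusions %s",
        len(manifest["artifacts"]), manifest["exclusions"],
    )
    return manifest
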
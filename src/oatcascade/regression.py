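"""Crude and adjusted baseline-category multinomial models of cascade stage.

The outcome is the four-stage cascade with "< 90 days" as the reference
stage; each covariate's association with longer retention is reported as an
odds ratio with a Wald 95% confidence interval per non-reference stage.
"Crude" fits one single-covariate model per covariate; "adjusted" fits all
declared covariates simultaneously. For a single categorical covariate the
model is saturated, so the fitted crude ORs must equal the closed-form
contingency cross-product ratios — ``crude_or_from_counts`` provides that
closed form and serves as an independent oracle for the iterative fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from ._util import round_half_up
from .cascade import NONREF_STAGES, STAGE_ORDER, CascadeStage
from .errors import ConvergenceError

logger = logging.getLogger(__name__)

OR_COLUMNS = ["covariate", "level", "stage", "mode", "OR", "ci_low", "ci_high", "n", "converged"]


@dataclass(frozen=True)
class Covariate:
    """One model term: binary (0/1), categorical with a declared reference
    level, or continuous."""

    name: str
    kind: str  # "binary" | "categorical" | "continuous"
    reference: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "categorical", "continuous"):
            raise ValueError(f"unknown covariate kind: {self.kind!r}")
        if self.kind == "categorical" and self.reference is None:
            raise ValueError(f"categorical covariate {self.name!r} needs a reference level")


@dataclass
class ModelSpec:
    covariates: list[Covariate] = field(default_factory=list)
    mode: str = "crude"  # "crude" | "adjusted"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.mode not in ("crude", "adjusted"):
            raise ValueError(f"mode must be 'crude' or 'adjusted', got {self.mode!r}")


def table2_covariates() -> list[Covariate]:
    """The default adjusted-model covariate list (demographics, geography,
    starting medication, attempts, screening frequency, UDS quadrants, dose
    indicators)."""
    covs = [
        Covariate("sex", "categorical", "M"),
        Covariate("age_group", "categorical", "65+"),
        Covariate("region", "categorical", "Southern_urban"),
        Covariate("starting_medication", "categorical", "buprenorphine_naloxone"),
        Covariate("n_attempts", "continuous"),
        Covariate("avg_monthly_uds", "continuous"),
    ]
    from .covariates import DRUG_CLASSES

    covs += [Covariate(f"uds_quadrant_{c}", "categorical", "Q0_25") for c in DRUG_CLASSES]
    covs += [
        Covariate("start_above_median", "binary"),
        Covariate("peak_above_median", "binary"),
    ]
    return covs


# ---------------------------------------------------------------------------
# Closed-form contingency oracle


def crude_or_from_counts(
    counts: pd.DataFrame, ref_level: str, alpha: float = 0.05, covariate: str = "covariate"
) -> pd.DataFrame:
    """Crude odds ratios from a levels-by-stages contingency table.

    ``counts`` is indexed by covariate level with one column per stage code
    in cascade order; the reference stage is "< 90 days". For level l and
    stage s, OR = (n[l,s] * n[ref,LT90]) / (n[l,LT90] * n[ref,s]) with the
    Wald interval exp(log OR +/- z * sqrt(sum of reciprocal cells)). A zero
    in any of the four cells yields a flagged row (OR = NaN) rather than a
    silent continuity correction.
    """
    stage_codes = [s.value for s in STAGE_ORDER]
    missing = [c for c in stage_codes if c not in counts.columns]
    if missing:
        raise ValueError(f"counts table missing stage column(s): {missing}")
    if ref_level not in counts.index:
        raise ValueError(f"reference level {ref_level!r} not in counts index")
    if (counts[stage_codes] < 0).any().any():
        raise ValueError("counts must be nonnegative")

    z = st.norm.ppf(1 - alpha / 2)
    ref_lt90 = float(counts.loc[ref_level, CascadeStage.LT_90.value])
    rows = []
    for level in counts.index:
        if level == ref_level:
            continue
        lvl_lt90 = float(counts.loc[level, CascadeStage.LT_90.value])
        for stage in NONREF_STAGES:
            a = float(counts.loc[level, stage.value])
            b = float(counts.loc[ref_level, stage.value])
            cells = np.array([a, ref_lt90, lvl_lt90, b])
            if (cells == 0).any():
                logger.warning(
                    "zero cell for %s=%s, stage %s: OR undefined without continuity correction",
                    covariate, level, stage.value,
                )
                odds_ratio, lo, hi = np.nan, np.nan, np.nan
            else:
                log_or = np.log(a * ref_lt90 / (lvl_lt90 * b))
                se = np.sqrt((1 / cells).sum())
                odds_ratio = np.exp(log_or)
                lo, hi = np.exp(log_or - z * se), np.exp(log_or + z * se)
            rows.append(
                {
                    "covariate": covariate,
                    "level": level,
                    "stage": stage.value,
                    "mode": "crude",
                    "OR": odds_ratio,
                    "ci_low": lo,
                    "ci_high": hi,
                    "n": int(counts[stage_codes].to_numpy().sum()),
                    "converged": True,
                }
            )
    return pd.DataFrame(rows, columns=OR_COLUMNS)


def expand_counts_to_rows(counts: pd.DataFrame, covariate: str) -> pd.DataFrame:
    """Expand a levels-by-stages count table into one row per patient."""
    stage_codes = [s.value for s in STAGE_ORDER]
    records = []
    for level in counts.index:
        for code in stage_codes:
            records.append(
                pd.DataFrame(
                    {covariate: level, "stage": code},
                    index=range(int(counts.loc[level, code])),
                )
            )
    return pd.concat(records, ignore_index=True)


# ---------------------------------------------------------------------------
# Maximum-likelihood multinomial fit


def _design_matrix(
    df: pd.DataFrame, covariates: list[Covariate]
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Build the design matrix (with intercept) and (covariate, level) labels
    for every non-intercept column."""
    cols: list[np.ndarray] = [np.ones(len(df))]
    labels: list[tuple[str, str]] = [("_intercept", "")]
    for cov in covariates:
        x = df[cov.name]
        if cov.kind == "continuous":
            cols.append(x.to_numpy(dtype=float))
            labels.append((cov.name, cov.name))
        elif cov.kind == "binary":
            cols.append(x.astype(bool).to_numpy(dtype=float))
            labels.append((cov.name, cov.name))
        else:
            levels = [lv for lv in pd.unique(x.dropna()) if lv != cov.reference]
            if cov.reference not in set(x.dropna()):
                raise ValueError(
                    f"reference level {cov.reference!r} absent for covariate {cov.name!r}"
                )
            for lv in sorted(map(str, levels)):
                cols.append((x.astype(str) == lv).to_numpy(dtype=float))
                labels.append((cov.name, lv))
    return np.column_stack(cols), labels


def fit_multinomial(
    summaries: pd.DataFrame, spec: ModelSpec, strict: bool = False
) -> tuple[pd.DataFrame, dict]:
    """Fit baseline-category multinomial logit(s) of cascade stage.

    Rows with missing values in any modelled covariate are dropped
    (complete-case) and counted in the returned diagnostics. In crude mode
    one single-covariate model is fitted per declared covariate; in adjusted
    mode all covariates enter one model. A failed fit (perfect separation,
    singular Hessian) is surfaced explicitly, never clipped: with
    ``strict=True`` it raises ConvergenceError naming the covariate block;
    otherwise the affected rows are emitted with OR NaN and
    ``converged=False`` plus a logged warning.
    """
    if spec.mode == "crude":
        frames, infos = [], []
        for cov in spec.covariates:
            tab, info = _fit_one(summaries, [cov], "crude", spec.alpha, strict)
            frames.append(tab)
            infos.append(info)
        table = pd.concat(frames, ignore_index=True)
        info = {
            "mode": "crude",
            "fits": infos,
            "excluded_missing": max(i["excluded_missing"] for i in infos),
        }
        return table, info
    return _fit_one(summaries, spec.covariates, "adjusted", spec.alpha, strict)


def _observed_labels(df: pd.DataFrame, covariates: list[Covariate]) -> list[tuple[str, str]]:
    labels: list[tuple[str, str]] = []
    for cov in covariates:
        if cov.kind in ("continuous", "binary"):
            labels.append((cov.name, cov.name))
        else:
            observed = set(df[cov.name].dropna().astype(str)) - {cov.reference}
            labels.extend((cov.name, lv) for lv in sorted(observed))
    return labels


def _flagged_table(
    df: pd.DataFrame, covariates: list[Covariate], mode: str
) -> pd.DataFrame:
    labels = _observed_labels(df, covariates)
    rows = [
        {
            "covariate": cov_name, "level": level, "stage": stage.value, "mode": mode,
            "OR": np.nan, "ci_low": np.nan, "ci_high": np.nan,
            "n": len(df), "converged": False,
        }
        for stage in NONREF_STAGES
        for cov_name, level in labels
        if cov_name != "_intercept"
    ]
    return pd.DataFrame(rows, columns=OR_COLUMNS)


def _fit_one(
    summaries: pd.DataFrame, covariates: list[Covariate], mode: str, alpha: float,
    strict: bool = False,
) -> tuple[pd.DataFrame, dict]:
    names = [c.name for c in covariates]
    df = summaries.copy()
    # sex "missing" is a bookkeeping category, not a modelled level
    if "sex" in names:
        df["sex"] = df["sex"].replace("missing", np.nan)
    modelled = df[names + ["stage"]]
    keep = modelled.notna().all(axis=1)
    n_excluded = int((~keep).sum())
    df = df[keep]
    if len(df) == 0:
        raise ValueError("no complete-case rows to fit")

    stage_codes = {s.value: i for i, s in enumerate(STAGE_ORDER)}
    present = set(df["stage"])
    absent = [s for s in stage_codes if s not in present]
    if absent:
        raise ValueError(f"stage(s) {absent} absent from data; cannot fit 4-stage model")
    y = df["stage"].map(stage_codes).to_numpy()

    fail_reason = None
    try:
        X, labels = _design_matrix(df, covariates)
        with warnings.catch_warnings():
            # a diverging Newton path emits overflow/convergence warnings;
            # failure is surfaced explicitly below instead
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", ConvergenceWarning)
            res = sm.MNLogit(y, X).fit(method="newton", maxiter=200, tol=1e-10, disp=False)
        if not bool(res.mle_retvals.get("converged", False)):
            fail_reason = "optimizer did not converge (possible separation or sparse cells)"
    except Exception as exc:  # separation, singular Hessian, absent reference level
        fail_reason = str(exc)
    if fail_reason is not None:
        msg = f"multinomial fit failed for covariates {names}: {fail_reason}"
        if strict:
            raise ConvergenceError(msg)
        logger.warning("%s; emitting flagged rows", msg)
        table = _flagged_table(df, covariates, mode)
        info = {
            "mode": mode, "covariates": names, "n": len(df),
            "excluded_missing": n_excluded, "llf": np.nan, "converged": False,
            "failure": fail_reason,
        }
        return table, info
    converged = True

    z = st.norm.ppf(1 - alpha / 2)
    params = np.asarray(res.params)  # (k_exog, 3), columns = stages 1..3
    bse = np.asarray(res.bse)
    rows = []
    for j, stage in enumerate(NONREF_STAGES):
        for k, (cov_name, level) in enumerate(labels):
            if cov_name == "_intercept":
                continue
            beta, se = params[k, j], bse[k, j]
            rows.append(
                {
                    "covariate": cov_name,
                    "level": level,
                    "stage": stage.value,
                    "mode": mode,
                    "OR": float(np.exp(beta)),
                    "ci_low": float(np.exp(beta - z * se)),
                    "ci_high": float(np.exp(beta + z * se)),
                    "n": len(df),
                    "converged": converged,
                }
            )
    table = pd.DataFrame(rows, columns=OR_COLUMNS).sort_values(
        ["covariate", "level", "stage"], kind="mergesort"
    ).reset_index(drop=True)
    info = {
        "mode": mode,
        "covariates": names,
        "n": len(df),
        "excluded_missing": n_excluded,
        "llf": float(res.llf),
        "converged": converged,
    }
    return table, info


def display_or(table: pd.DataFrame) -> pd.DataFrame:
    """Printed form: ORs and CI bounds to two decimals, half-up."""
    out = table.copy()
    for col in ("OR", "ci_low", "ci_high"):
        out[col] = [round_half_up(v, 2) if np.isfinite(v) else v for v in out[col]]
    return out


# ---------------------------------------------------------------------------
# Characteristics ("Table 1"-style) report


def characteristics_table(
    summaries: pd.DataFrame, covariates: list[Covariate] | None = None
) -> pd.DataFrame:
    """Per-stage cohort characteristics with tests of independence.

    Categorical covariates get per-stage counts and column percentages with
    a chi-square test across the four stages; continuous covariates get
    per-stage mean and SD with a one-way ANOVA. Levels absent everywhere
    are dropped with a note in the log.
    """
    covariates = covariates if covariates is not None else table2_covariates()
    stage_codes = [s.value for s in STAGE_ORDER]
    strata = ["overall"] + stage_codes
    groups = {"overall": summaries}
    for code in stage_codes:
        groups[code] = summaries[summaries["stage"] == code]

    rows = []
    for cov in covariates:
        if cov.kind == "continuous":
            samples = [
                groups[c][cov.name].dropna().to_numpy(dtype=float) for c in stage_codes
            ]
            p = float(st.f_oneway(*samples).pvalue) if all(len(s) > 1 for s in samples) else np.nan
            for stratum in strata:
                x = groups[stratum][cov.name].dropna()
                rows.append(
                    {
                        "covariate": cov.name,
                        "level": "",
                        "stratum": stratum,
                        "n": int(x.count()),
                        "percent": np.nan,
                        "mean": float(x.mean()),
                        "sd": float(x.std(ddof=1)),
                        "p_value": p,
                    }
                )
        else:
            col = summaries[cov.name]
            if cov.kind == "binary":
                col = col.astype(bool).map({True: "yes", False: "no"})
            levels = [lv for lv in pd.unique(col.dropna())]
            if not levels:
                logger.warning("covariate %s has no observed levels; dropped", cov.name)
                continue
            ct = pd.crosstab(col, summaries["stage"])
            ct = ct.reindex(columns=stage_codes, fill_value=0)
            nonzero = ct.sum(axis=1) > 0
            if (~nonzero).any():
                logger.warning(
                    "dropping empty level(s) of %s: %s", cov.name, list(ct.index[~nonzero])
                )
                ct = ct[nonzero]
            p = float(st.chi2_contingency(ct.to_numpy())[1]) if ct.shape[0] > 1 else np.nan
            for lv in ct.index:
                for stratum in strata:
                    sub = groups[stratum]
                    n = int((sub[cov.name].astype(str) == str(lv)).sum()) if cov.kind != "binary" else int(
                        (sub[cov.name].astype(bool).map({True: "yes", False: "no"}) == lv).sum()
                    )
                    total = len(sub)
                    rows.append(
                        {
                            "covariate": cov.name,
                            "level": str(lv),
                            "stratum": stratum,
                            "n": n,
                            "percent": round_half_up(100 * n / total, 1) if total else np.nan,
                            "mean": np.nan,
                            "sd": np.nan,
                            "p_value": p,
                        }
                    )
    return pd.DataFrame(rows)
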
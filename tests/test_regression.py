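"""Odds-ratio estimation: closed-form oracle, ML fit agreement, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from oatcascade.cascade import NONREF_STAGES, STAGE_ORDER
from oatcascade.errors import ConvergenceError
from oatcascade.regression import (
    Covariate,
    ModelSpec,
    characteristics_table,
    crude_or_from_counts,
    display_or,
    expand_counts_to_rows,
    fit_multinomial,
)

STAGES = [s.value for s in STAGE_ORDER]

# Published sex-by-stage contingency counts used as a worked example
SEX_COUNTS = pd.DataFrame(
    {
        "LT_90": [2227, 3833],
        "D90_365": [2707, 4535],
        "Y1_2": [2080, 3331],
        "GT_2Y": [5485, 8255],
    },
    index=["F", "M"],
)


def _rand_counts(rng, levels=2, low=20, high=400):
    return pd.DataFrame(
        rng.integers(low, high, size=(levels, 4)),
        index=[f"L{i}" for i in range(levels)],
        columns=STAGES,
    )


class TestClosedForm:
    def test_proportional_rows_give_unit_ors(self):
        counts = pd.DataFrame(
            {"LT_90": [10, 30], "D90_365": [20, 60], "Y1_2": [40, 120], "GT_2Y": [5, 15]},
            index=["a", "b"],
        )
        tab = crude_or_from_counts(counts, ref_level="b")
        assert np.allclose(tab["OR"], 1.0)

    def test_wald_interval_brackets_or(self):
        rng = np.random.default_rng(11)
        tab = crude_or_from_counts(_rand_counts(rng), ref_level="L0")
        assert ((tab["ci_low"] <= tab["OR"]) & (tab["OR"] <= tab["ci_high"])).all()
        assert (tab["OR"] > 0).all()

    def test_zero_cell_is_flagged_not_corrected(self, caplog):
        counts = _rand_counts(np.random.default_rng(1))
        counts.loc["L1", "Y1_2"] = 0
        with caplog.at_level("WARNING"):
            tab = crude_or_from_counts(counts, ref_level="L0")
        flagged = tab[tab.stage == "Y1_2"]
        assert flagged["OR"].isna().all()
        assert any("zero cell" in r.message for r in caplog.records)

    def test_reference_stage_relabel_identity(self):
        """Changing the reference stage divides ORs by the new reference's OR."""
        counts = _rand_counts(np.random.default_rng(7))
        tab = crude_or_from_counts(counts, ref_level="L0").set_index("stage")["OR"]
        # recompute with D90_365 as the reference stage by renaming columns
        remap = {"D90_365": "LT_90", "LT_90": "D90_365"}
        swapped = counts.rename(columns=remap)
        tab2 = crude_or_from_counts(swapped, ref_level="L0").set_index("stage")["OR"]
        assert tab2["GT_2Y"] == pytest.approx(tab["GT_2Y"] / tab["D90_365"], rel=1e-12)


class TestFitAgreesWithOracle:
    def test_sex_worked_example(self):
        oracle = crude_or_from_counts(SEX_COUNTS, ref_level="M", covariate="sex")
        rows = expand_counts_to_rows(SEX_COUNTS, "sex")
        fitted, info = fit_multinomial(
            rows, ModelSpec([Covariate("sex", "categorical", "M")], mode="crude"), strict=True
        )
        merged = fitted.merge(oracle, on=["level", "stage"], suffixes=("_fit", "_cf"))
        assert np.allclose(merged["OR_fit"], merged["OR_cf"], rtol=1e-6)
        shown = display_or(fitted).set_index("stage")
        assert shown.loc["GT_2Y", "OR"] == 1.14
        assert shown.loc["Y1_2", "OR"] == 1.07

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        counts = _rand_counts(rng, levels=3)
        oracle = crude_or_from_counts(counts, ref_level="L0", covariate="g")
        rows = expand_counts_to_rows(counts, "g")
        fitted, _ = fit_multinomial(
            rows, ModelSpec([Covariate("g", "categorical", "L0")], mode="crude"), strict=True
        )
        merged = fitted.merge(oracle, on=["level", "stage"], suffixes=("_fit", "_cf"))
        assert np.allclose(merged["OR_fit"], merged["OR_cf"], rtol=1e-6)

    def test_row_order_invariance(self):
        rows = expand_counts_to_rows(SEX_COUNTS, "sex")
        shuffled = rows.sample(frac=1.0, random_state=3).reset_index(drop=True)
        spec = ModelSpec([Covariate("sex", "categorical", "M")], mode="crude")
        t1, _ = fit_multinomial(rows, spec, strict=True)
        t2, _ = fit_multinomial(shuffled, spec, strict=True)
        pd.testing.assert_frame_equal(t1, t2)


class TestParameterRecovery:
    def test_binary_log_or_recovered(self):
        from oatcascade.synthetic_emr import generate_stage_odds_cohort

        df, _ = generate_stage_odds_cohort({"x": {"GT_2Y": np.log(2.0)}}, n=20_000, seed=101)
        tab, _ = fit_multinomial(
            df, ModelSpec([Covariate("x", "binary")], mode="crude"), strict=True
        )
        fitted = tab.set_index("stage").loc["GT_2Y", "OR"]
        assert 1.8 < fitted < 2.2


class TestDiagnostics:
    def test_missing_covariates_are_dropped_and_counted(self):
        rows = expand_counts_to_rows(SEX_COUNTS, "sex")
        rows.loc[:99, "sex"] = np.nan
        _, info = fit_multinomial(
            rows, ModelSpec([Covariate("sex", "categorical", "M")], mode="crude"), strict=True
        )
        assert info["excluded_missing"] == 100

    def test_separation_raises_in_strict_mode(self):
        n = 400
        df = pd.DataFrame(
            {
                "x": np.repeat([0, 1], n // 2),
                "stage": ["LT_90", "D90_365", "Y1_2", "GT_2Y"] * (n // 4),
            }
        )
        df.loc[df.x == 1, "stage"] = "GT_2Y"  # x=1 perfectly predicts the top stage
        spec = ModelSpec([Covariate("x", "binary")], mode="crude")
        with pytest.raises(ConvergenceError, match="x"):
            fit_multinomial(df, spec, strict=True)
        tab, info = fit_multinomial(df, spec)  # non-strict: flagged, not clipped
        assert not tab["converged"].any()
        assert tab["OR"].isna().all()

    def test_adjusted_mode_fits_all_covariates_at_once(self):
        rng = np.random.default_rng(5)
        n = 2000
        df = pd.DataFrame(
            {
                "x": rng.integers(0, 2, n),
                "z": rng.normal(size=n),
                "stage": rng.choice(STAGES, n),
            }
        )
        spec = ModelSpec(
            [Covariate("x", "binary"), Covariate("z", "continuous")], mode="adjusted"
        )
        tab, info = fit_multinomial(df, spec, strict=True)
        assert set(tab["covariate"]) == {"x", "z"}
        assert len(tab) == 6  # 2 covariates x 3 non-reference stages
        assert info["converged"]


class TestCharacteristicsTable:
    def _summaries(self, n=1000, seed=4):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "stage": rng.choice(STAGES, n),
                "sex": rng.choice(["F", "M"], n),
                "n_attempts": rng.poisson(2, n).astype(float),
            }
        )

    def test_counts_and_percentages(self):
        df = self._summaries()
        covs = [Covariate("sex", "categorical", "M"), Covariate("n_attempts", "continuous")]
        tab = characteristics_table(df, covs)
        overall_m = tab[(tab.covariate == "sex") & (tab.level == "M") & (tab.stratum == "overall")]
        assert overall_m["n"].iloc[0] == (df["sex"] == "M").sum()
        cont = tab[(tab.covariate == "n_attempts") & (tab.stratum == "overall")]
        assert cont["mean"].iloc[0] == pytest.approx(df["n_attempts"].mean())
        assert cont["sd"].iloc[0] == pytest.approx(df["n_attempts"].std(ddof=1))

    def test_identical_distributions_give_p_near_one(self):
        # same sex split in every stage -> chi-square p == 1 up to float
        df = pd.DataFrame(
            {
                "stage": np.repeat(STAGES, 100),
                "sex": np.tile(np.repeat(["F", "M"], 50), 4),
            }
        )
        tab = characteristics_table(df, [Covariate("sex", "categorical", "M")])
        assert tab["p_value"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_male_percent_matches_published_style(self):
        tab = characteristics_table(
            expand_counts_to_rows(SEX_COUNTS, "sex"),
            [Covariate("sex", "categorical", "M")],
        )
        m = tab[(tab.level == "M") & (tab.stratum == "overall")]
        assert m["percent"].iloc[0] == pytest.approx(61.5, abs=0.1)
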
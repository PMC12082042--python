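"""Design matrices, OLS, BH adjustment, and the analysis driver."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from ighrep import (
    ConfigError,
    ContractError,
    DataError,
    ModelError,
    bh_adjust,
    build_design,
    default_cohort_config,
    fit_linear,
    run_analysis,
    simulate_cohort,
    tier_of,
)
from oracles import bh_direct, ols_direct


def toy_metadata(n_per_group=8, seed=7) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for group in ("former", "never", "vaping", "cigarette", "dual"):
        for _ in range(n_per_group):
            rows.append(
                dict(
                    participant_id=f"P{i:03d}",
                    exposure_group=group,
                    age=float(rng.normal(64, 8)),
                    sex=int(rng.integers(0, 2)),
                    race=int(rng.integers(0, 2)),
                    pack_years=0.0 if group == "never"
                    else float(rng.uniform(10, 80)),
                    gold_group=str(
                        rng.choice(["normal", "gold1", "gold2_4", "prism"])
                    ),
                    ics_use=bool(rng.integers(0, 2)),
                    income_level=int(rng.integers(1, 6)),
                    deprivation_index=float(rng.uniform(1, 100)),
                    ct_wall_area_pct=float(rng.normal(50, 8)),
                    ct_scanner=str(rng.choice(["modelA", "modelB"])),
                )
            )
            i += 1
    return pd.DataFrame(rows)


class TestBuildDesign:
    def test_exposure_dummies_against_former_reference(self):
        X = build_design(toy_metadata(), ("exposure_group",))
        assert list(X.columns) == [
            "intercept",
            "exposure_group:never",
            "exposure_group:cigarette",
            "exposure_group:vaping",
            "exposure_group:dual",
        ]

    def test_missing_covariate_named(self):
        meta = toy_metadata().drop(columns=["ics_use"])
        with pytest.raises(ModelError, match="ics_use"):
            build_design(meta, ("age", "ics_use"))

    def test_cohort_like_primary_design_full_rank(self):
        meta = toy_metadata(n_per_group=12)
        X = build_design(
            meta,
            ("age", "sex", "race", "exposure_group", "gold_group",
             "pack_years", "ics_use"),
        )
        expected = {
            "intercept", "age", "sex", "race", "pack_years", "ics_use",
            "exposure_group:never", "exposure_group:vaping",
            "exposure_group:cigarette", "exposure_group:dual",
            "gold_group:gold1", "gold_group:gold2_4", "gold_group:prism",
        }
        assert set(X.columns) == expected
        assert np.linalg.matrix_rank(X.to_numpy()) == X.shape[1]

    def test_reference_level_absent_is_error(self):
        meta = toy_metadata()
        meta = meta[meta["exposure_group"] != "former"]
        with pytest.raises(ModelError, match="former"):
            build_design(meta, ("exposure_group",))

    def test_rank_deficiency_detected(self):
        meta = toy_metadata()
        meta["copy_of_age"] = meta["age"]
        with pytest.raises(ModelError, match="rank"):
            build_design(meta, ("age", "copy_of_age"))

    def test_missing_rows_dropped(self):
        meta = toy_metadata()
        meta.loc[meta.index[:4], "deprivation_index"] = np.nan
        X = build_design(meta, ("age", "deprivation_index"))
        assert len(X) == len(meta) - 4


class TestFitLinear:
    def test_noiseless_line_recovered_exactly(self):
        x = np.arange(10.0)
        X = pd.DataFrame({"intercept": 1.0, "x": x})
        fit = fit_linear(X, 2.0 * x + 1.0)
        beta = fit.set_index("term")["beta"]
        assert beta["x"] == pytest.approx(2.0, abs=1e-12)
        assert beta["intercept"] == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_covariate_beta_zero(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        X = pd.DataFrame({"intercept": 1.0, "x": x})
        fit = fit_linear(X, np.array([1.0, 1.0, 1.0, 1.0, 1.0]))
        assert fit.set_index("term")["beta"]["x"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        X.insert(0, "intercept", 1.0)
        y = rng.normal(size=50)
        fit = fit_linear(X, y)
        beta, se, p = ols_direct(X.to_numpy(), y)
        np.testing.assert_allclose(fit["beta"], beta, atol=1e-8)
        np.testing.assert_allclose(fit["se"], se, atol=1e-8)
        np.testing.assert_allclose(fit["p"], p, atol=1e-8)

    def test_underdetermined_rejected(self):
        X = pd.DataFrame(np.eye(3), columns=list("abc"))
        with pytest.raises(ModelError):
            fit_linear(X, np.zeros(3))


class TestBhAdjust:
    def test_worked_four_value_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_identical_pvalues_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_single_pvalue(self):
        assert bh_adjust([0.031]) == pytest.approx([0.031])

    def test_family_larger_than_vector(self):
        # q_(1) = min(10*0.01/1, 10*0.04/2) = 0.1; q_(2) = 10*0.04/2 = 0.2
        assert bh_adjust([0.01, 0.04], m=10) == pytest.approx([0.1, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ContractError):
            bh_adjust([0.5, 1.2])

    def test_matches_direct_and_statsmodels(self, rng):
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            q = bh_adjust(p)
            assert q == pytest.approx(bh_direct(p))
            assert q == pytest.approx(
                multipletests(p, method="fdr_bh")[1], abs=1e-12
            )
            assert (q >= p - 1e-15).all()

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
    def test_order_preserving(self, p):
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(np.asarray(q)[order]) >= -1e-15).all()

    def test_tiers(self):
        tiers = tier_of([0.001, 0.05, 0.049999, 0.09, 0.1, 0.9])
        assert list(tiers) == [
            "significant", "suggestive", "significant",
            "suggestive", "null", "null",
        ]


def measure_matrix_for(meta, rng, effects=None, sd=1.0):
    """Gaussian measures, optionally with additive group effects."""
    effects = effects or {}
    base = rng.normal(0.0, sd, size=len(meta))
    shift = meta["exposure_group"].map(
        lambda g: effects.get(g, 0.0)
    ).to_numpy()
    return pd.DataFrame(
        {"m1": base + shift, "m2": rng.normal(size=len(meta))},
        index=meta["participant_id"],
    )


class TestRunAnalysis:
    def test_single_measure_single_term_q_equals_p(self, rng):
        meta = toy_metadata()
        matrix = measure_matrix_for(meta, rng)[["m1"]]
        res = run_analysis(matrix, meta, "univariable_ct")
        assert len(res) == 1
        assert res["q"].iloc[0] == pytest.approx(res["p"].iloc[0])

    def test_unknown_family_rejected(self):
        with pytest.raises(ConfigError, match="unknown"):
            run_analysis(pd.DataFrame(), pd.DataFrame(), "bogus_family")

    def test_alignment_mismatch_lists_participants(self, rng):
        meta = toy_metadata()
        matrix = measure_matrix_for(meta, rng)
        with pytest.raises(DataError, match="P000"):
            run_analysis(matrix, meta[meta["participant_id"] != "P000"], "primary")

    def test_oral_steroid_users_excluded(self, rng):
        meta = toy_metadata()
        meta["oral_steroids"] = [True] * 5 + [False] * (len(meta) - 5)
        matrix = measure_matrix_for(meta, rng)
        matrix = matrix.loc[meta.loc[~meta["oral_steroids"], "participant_id"]]
        res = run_analysis(matrix, meta, "primary")
        assert (res["n_used"] == len(meta) - 5).all()

    def test_interaction_family_reports_cross_products(self, rng):
        meta = toy_metadata(n_per_group=14, seed=3)
        matrix = measure_matrix_for(meta, rng)
        res = run_analysis(matrix, meta, "interaction")
        assert set(res["term"]) == {
            "race*exposure_group:never", "race*exposure_group:vaping",
            "race*exposure_group:cigarette", "race*exposure_group:dual",
        }

    def test_strong_group_effect_recovered(self, rng):
        meta = toy_metadata(n_per_group=20, seed=11)
        matrix = measure_matrix_for(meta, rng, effects={"dual": 3.0}, sd=1.0)
        res = run_analysis(matrix, meta, "primary")
        hit = res[(res["measure"] == "m1") & (res["term"] == "exposure_group:dual")]
        assert hit["tier"].iloc[0] == "significant"
        assert hit["beta"].iloc[0] > 0

    def test_parameter_recovery_unbiased(self, rng):
        """Mean recovered effect over replicates is within 3 sigma/sqrt(n)."""
        meta = toy_metadata(n_per_group=20, seed=5)
        betas = []
        for _ in range(100):
            matrix = measure_matrix_for(meta, rng, effects={"dual": 0.8}, sd=1.0)
            X = build_design(
                meta, ("age", "sex", "race", "exposure_group", "gold_group",
                       "pack_years", "ics_use"),
            )
            fit = fit_linear(X, matrix["m1"].loc[X.index])
            betas.append(
                fit.set_index("term")["beta"]["exposure_group:dual"]
            )
        n = len(meta)
        assert np.mean(betas) == pytest.approx(0.8, abs=3.0 * 1.0 / np.sqrt(n))

    def test_adjustment_shrinks_confounded_exposure_betas(self):
        """When pack-years drives IgA usage and differs by group, adjusting
        for pack-years pulls the exposure coefficients toward zero."""
        cfg = default_cohort_config(
            seed=42,
            n_per_group={g: 25 for g in ("former", "never", "cigarette", "dual")},
            n_clones_mean=120,
            null_effects=True,
            pack_years_iga_slope=0.10,
        )
        from ighrep import assign_clones, collapse_clones, summarize_cohort

        meta, rearr = simulate_cohort(cfg)
        clones = collapse_clones(rearr, assign_clones(rearr))
        matrix, _ = summarize_cohort(clones)
        y = matrix["IgA2 usage"]

        with_py = build_design(meta, ("age", "exposure_group", "pack_years"))
        without_py = build_design(meta, ("age", "exposure_group"))
        exp_terms = [c for c in with_py.columns if c.startswith("exposure_group")]
        fit_adj = fit_linear(with_py, y.loc[with_py.index]).set_index("term")
        fit_raw = fit_linear(without_py, y.loc[without_py.index]).set_index("term")
        adj = fit_adj.loc[exp_terms, "beta"].abs().sum()
        raw = fit_raw.loc[exp_terms, "beta"].abs().sum()
        assert adj < raw
        # the never-smoker contrast carries the confounding (pack-years 0)
        assert abs(fit_adj.loc["exposure_group:never", "beta"]) < abs(
            fit_raw.loc["exposure_group:never", "beta"]
        )
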
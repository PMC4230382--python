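"""ΔHarvest regression: design construction, estimation, bootstrap CIs."""

import numpy as np
import pandas as pd
import pytest

from commonpool.harvest_regression import (
    DesignError,
    build_design,
    fit_model,
    fit_trial_table,
    summarize_fit,
)

MODEL1_TRUTH = {
    "const": 1.5,
    "treatment": -0.8,
    "own_prev_harvest": -0.6,
    "resource_before": 0.02,
    "over_present": 0.9,
    "treatment:own_prev_harvest": 0.3,
    "treatment:resource_before": -0.005,
    "treatment:over_present": -0.4,
}

MODEL2_TRUTH = {
    "const": 1.5,
    "treatment": -0.8,
    "own_prev_harvest": -0.6,
    "resource_before": 0.02,
    "over_present": 0.9,
    "rank": -9.0,
    "rank2": 18.0,
    "rank3": -12.0,
    "treatment:rank": 7.0,
    "treatment:rank2": -14.0,
    "treatment:rank3": 9.0,
}


def make_rows(truth, n_participants=8, n_trials=40, noise_sd=0.0, seed=0):
    """Tidy trial rows whose ΔHarvest is exactly linear in the regressors."""
    rng = np.random.default_rng(seed)
    frames = []
    for g, treatment in enumerate(("T_plus", "T_minus")):
        t = float(g)
        for i in range(n_participants):
            pid = f"{treatment}_{i}"
            prev = rng.integers(0, 21, size=n_trials).astype(float)
            resource = rng.integers(20, 400, size=n_trials).astype(float)
            over = rng.integers(0, 2, size=n_trials).astype(float)
            rank = rng.uniform(0, 1, size=n_trials)
            delta = (
                truth.get("const", 0.0)
                + truth.get("treatment", 0.0) * t
                + truth.get("own_prev_harvest", 0.0) * prev
                + truth.get("resource_before", 0.0) * resource
                + truth.get("over_present", 0.0) * over
                + truth.get("rank", 0.0) * rank
                + truth.get("rank2", 0.0) * rank**2
                + truth.get("rank3", 0.0) * rank**3
                + truth.get("treatment:own_prev_harvest", 0.0) * t * prev
                + truth.get("treatment:resource_before", 0.0) * t * resource
                + truth.get("treatment:over_present", 0.0) * t * over
                + truth.get("treatment:rank", 0.0) * t * rank
                + truth.get("treatment:rank2", 0.0) * t * rank**2
                + truth.get("treatment:rank3", 0.0) * t * rank**3
                + rng.normal(0, noise_sd, size=n_trials)
            )
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": pid,
                        "treatment": treatment,
                        "own_harvest": prev + delta,
                        "own_prev_harvest": prev,
                        "delta_harvest": delta,
                        "resource_before": resource,
                        "over_present": over,
                        "rank": rank,
                        "rank2": rank**2,
                        "rank3": rank**3,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


class TestBuildDesign:
    def test_model1_columns(self):
        X, y, clusters = build_design(make_rows(MODEL1_TRUTH), "model1")
        assert list(X.columns) == [
            "const", "treatment", "own_prev_harvest", "resource_before",
            "over_present", "treatment:own_prev_harvest",
            "treatment:resource_before", "treatment:over_present",
        ]
        assert y.name == "delta_harvest"
        assert len(X) == len(y) == len(clusters)

    def test_model2_columns(self):
        X, _, _ = build_design(make_rows(MODEL2_TRUTH), "model2")
        assert list(X.columns) == [
            "const", "treatment", "own_prev_harvest", "resource_before",
            "over_present", "rank", "treatment:rank", "rank2",
            "treatment:rank2", "rank3", "treatment:rank3",
        ]

    def test_first_trial_rows_dropped(self):
        rows = make_rows(MODEL1_TRUTH)
        rows.loc[rows.index[:10], ["own_prev_harvest", "delta_harvest", "rank"]] = np.nan
        X, _, _ = build_design(rows, "model1")
        assert len(X) == len(rows) - 10

    def test_all_first_trials_is_error(self):
        rows = make_rows(MODEL1_TRUTH)
        rows[["own_prev_harvest", "delta_harvest", "rank"]] = np.nan
        with pytest.raises(DesignError, match="no usable rows"):
            build_design(rows, "model1")

    def test_truncated_requests_excluded(self):
        rows = make_rows(MODEL1_TRUTH)
        rows["own_request"] = rows["own_harvest"]
        rows.loc[rows.index[:7], "own_request"] = rows["own_harvest"] + 3
        X, _, _ = build_design(rows, "model1")
        assert len(X) == len(rows) - 7

    def test_single_treatment_rejected(self):
        rows = make_rows(MODEL1_TRUTH)
        rows = rows[rows.treatment == "T_plus"]
        with pytest.raises(DesignError, match="both groups"):
            build_design(rows, "model1")

    def test_missing_column_rejected(self):
        rows = make_rows(MODEL1_TRUTH).drop(columns=["rank2"])
        with pytest.raises(DesignError, match="rank2"):
            build_design(rows, "model1")

    def test_unknown_model_tag_rejected(self):
        with pytest.raises(DesignError):
            build_design(make_rows(MODEL1_TRUTH), "model3")


class TestFitModel:
    @pytest.mark.parametrize(
        "tag,truth", [("model1", MODEL1_TRUTH), ("model2", MODEL2_TRUTH)]
    )
    def test_noiseless_exact_recovery(self, tag, truth):
        rows = make_rows(truth)
        result = fit_trial_table(rows, tag, n_boot=10, seed=0)
        est = result.table.set_index("term")["estimate"]
        for term, value in truth.items():
            assert est[term] == pytest.approx(value, abs=1e-8)

    def test_duplicated_participants_leave_estimates_unchanged(self):
        rows = make_rows(MODEL1_TRUTH, noise_sd=1.0)
        dup = rows.copy()
        dup["participant_id"] = dup["participant_id"] + "_copy"
        both = pd.concat([rows, dup], ignore_index=True)
        est1 = fit_trial_table(rows, "model1", n_boot=5, seed=0).table.estimate
        est2 = fit_trial_table(both, "model1", n_boot=5, seed=0).table.estimate
        assert np.allclose(est1, est2, atol=1e-8)

    def test_row_permutation_invariance(self):
        rows = make_rows(MODEL1_TRUTH, noise_sd=1.0)
        shuffled = rows.sample(frac=1.0, random_state=4).reset_index(drop=True)
        est1 = fit_trial_table(rows, "model1", n_boot=5, seed=0).table.estimate
        est2 = fit_trial_table(shuffled, "model1", n_boot=5, seed=0).table.estimate
        assert np.allclose(est1, est2, atol=1e-8)

    def test_ci_brackets_estimate(self):
        rows = make_rows(MODEL2_TRUTH, noise_sd=2.0)
        for method in ("bootstrap-t", "percentile"):
            X, y, clusters = build_design(rows, "model2")
            result = fit_model(X, y, clusters, n_boot=50, seed=3,
                               model_tag="model2", ci_method=method)
            tab = result.table
            assert (tab.ci_low <= tab.estimate).all()
            assert (tab.estimate <= tab.ci_high).all()

    def test_standardized_coefficient_invariant_to_affine_rescale(self):
        rows = make_rows(MODEL1_TRUTH, noise_sd=1.0)
        scaled = rows.copy()
        scaled["resource_before"] = scaled["resource_before"] * 3.7 + 12.0
        std1 = fit_trial_table(rows, "model1", n_boot=5, seed=0).term(
            "resource_before"
        )["estimate_std"]
        std2 = fit_trial_table(scaled, "model1", n_boot=5, seed=0).term(
            "resource_before"
        )["estimate_std"]
        assert std1 == pytest.approx(std2, abs=1e-8)

    def test_rank_deficient_design_names_terms(self):
        rows = make_rows(MODEL1_TRUTH)
        rows["over_present"] = 0.0
        with pytest.raises(DesignError, match="over_present"):
            fit_trial_table(rows, "model1", n_boot=5, seed=0)

    def test_too_few_clusters_rejected(self):
        rows = make_rows(MODEL1_TRUTH, n_participants=1)
        rows["participant_id"] = "same"
        X, y, clusters = build_design(rows, "model1")
        with pytest.raises(ValueError, match="clusters"):
            fit_model(X, y, clusters, n_boot=5, seed=0)

    def test_invalid_n_boot_rejected(self):
        rows = make_rows(MODEL1_TRUTH)
        X, y, clusters = build_design(rows, "model1")
        with pytest.raises(ValueError):
            fit_model(X, y, clusters, n_boot=0, seed=0)

    def test_noise_widens_bootstrap_cis(self):
        """Average CI width grows with the response noise level."""
        widths = []
        for sd in (0.5, 4.0):
            rows = make_rows(MODEL1_TRUTH, noise_sd=sd, seed=9)
            tab = fit_trial_table(rows, "model1", n_boot=100, seed=1).table
            widths.append((tab.ci_high - tab.ci_low).mean())
        assert widths[0] < widths[1]


class TestSummarizeFit:
    def test_model_reports_have_expected_rows(self):
        rows = make_rows(MODEL2_TRUTH, noise_sd=1.0)
        rep1 = summarize_fit(fit_trial_table(rows, "model1", n_boot=5, seed=0))
        rep2 = summarize_fit(fit_trial_table(rows, "model2", n_boot=5, seed=0))
        assert {"own_prev_harvest", "resource_before", "over_present",
                "treatment"} <= set(rep1.term)
        assert {"rank", "rank2", "rank3", "treatment:rank3"} <= set(rep2.term)
        assert {"formatted", "formatted_std", "stars"} <= set(rep1.columns)

    def test_group_observation_counts(self):
        rows = make_rows(MODEL1_TRUTH, n_participants=3, n_trials=11)
        result = fit_trial_table(rows, "model1", n_boot=5, seed=0)
        assert result.n_obs == {"T_plus": 33, "T_minus": 33}
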
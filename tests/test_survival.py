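import numpy as np
import pandas as pd
import pytest

from melaband import survival, synthetic
from melaband.survival import (
    UndefinedConcordanceError,
    ValidationError,
    bootstrap_c_ci,
    breslow_partial_loglik,
    cox_fit,
    harrell_c,
    loocv_c,
    multivariable_models,
    multivariable_table,
    summarize_cohort,
    univariate_screen,
)


def brute_force_c(scores, time, event):
    """O(n^2) pair-enumeration oracle for Harrell's C."""
    conc = ties = comp = 0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i]:
                comp += 1
                if scores[i] > scores[j]:
                    conc += 1
                elif scores[i] == scores[j]:
                    ties += 1
    return (conc + 0.5 * ties) / comp


def grid_search_beta(x, time, event, lo=-5.0, hi=5.0, n=200001):
    grid = np.linspace(lo, hi, n)
    lls = [breslow_partial_loglik([b], x, time, event) for b in grid]
    return grid[int(np.argmax(lls))]


SMALL_FIXTURES = [
    # (covariate, times, events)
    ([0, 1, 0, 1, 1, 0], [1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 1]),
    ([0.2, -1.3, 0.7, 2.0, -0.5, 0.0, 1.1, -2.0],
     [3, 1, 4, 1.5, 9, 2.6, 5, 3.5], [1, 0, 1, 1, 0, 1, 1, 1]),
    ([1, 1, 0, 0, 1], [2, 2, 3, 5, 7], [1, 1, 1, 0, 1]),  # tied event times
]


class TestCoxFit:
    @pytest.mark.parametrize("x,t,e", SMALL_FIXTURES)
    def test_matches_grid_search_oracle(self, x, t, e):
        x = np.asarray(x, float)[:, None]
        fit = cox_fit(x, t, e)
        oracle = grid_search_beta(x, np.asarray(t, float), np.asarray(e, bool))
        assert fit.coef[0] == pytest.approx(oracle, abs=1e-4)

    def test_location_shift_invariance(self, planted_cohort):
        X = planted_cohort.features[["f"]].to_numpy()
        t = planted_cohort.survival["time_months"].to_numpy()
        e = planted_cohort.survival["event"].to_numpy()
        fit = cox_fit(X, t, e)
        fit_shifted = cox_fit(X + 57.0, t, e)
        assert fit_shifted.coef[0] == pytest.approx(fit.coef[0], rel=1e-8)
        assert fit_shifted.se[0] == pytest.approx(fit.se[0], rel=1e-8)
        assert harrell_c((X + 57.0) @ fit_shifted.coef, t, e) == pytest.approx(
            harrell_c(X @ fit.coef, t, e)
        )

    def test_agrees_with_lifelines_on_untied_data(self, planted_cohort):
        from lifelines import CoxPHFitter

        X = planted_cohort.features[["f"]].to_numpy()
        t = planted_cohort.survival["time_months"].to_numpy()
        e = planted_cohort.survival["event"].to_numpy()
        fit = cox_fit(X, t, e)
        df = pd.DataFrame({"f": X[:, 0], "t": t, "e": e.astype(int)})
        cph = CoxPHFitter().fit(df, "t", "e")  # Efron == Breslow when untied
        assert fit.coef[0] == pytest.approx(cph.params_.iloc[0], abs=1e-5)
        assert fit.se[0] == pytest.approx(cph.standard_errors_.iloc[0], abs=1e-5)

    def test_null_covariate_is_rarely_significant(self):
        hits = 0
        reps = 100
        for s in range(reps):
            sample = synthetic.generate_cohort(
                synthetic.CohortSimConfig(n_patients=300, seed=1000 + s)
            )
            fit = cox_fit(
                sample.features[["factor_1"]].to_numpy(),
                sample.survival["time_months"],
                sample.survival["event"],
            )
            if abs(fit.coef[0]) >= 2 * fit.se[0]:
                hits += 1
        assert reps - hits >= 90

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            cox_fit(np.ones((10, 1)), np.arange(1, 11), np.ones(10, bool))

    def test_separation_is_flagged_not_raised(self):
        # covariate perfectly ordered with event times -> monotone likelihood
        x = np.arange(20.0)[:, None]
        t = np.arange(20.0, 0.0, -1.0)
        e = np.ones(20, bool)
        fit = cox_fit(x, t, e)
        assert not fit.converged
        assert "monotone" in fit.diagnostics or "singular" in fit.diagnostics


class TestHarrellC:
    def test_textbook_examples(self):
        t, e = [1, 2, 3], [1, 1, 1]
        assert harrell_c([3, 2, 1], t, e) == 1.0
        assert harrell_c([1, 2, 3], t, e) == 0.0
        assert harrell_c([1, 1, 1], t, e) == 0.5

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_pair_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        scores = np.round(rng.normal(0, 1, n), 1)  # induce some score ties
        time = np.round(rng.exponential(10, n), 0)  # and time ties
        event = rng.random(n) < 0.7
        if not event[np.argsort(time)][0]:
            event[np.argsort(time)[0]] = True
        assert harrell_c(scores, time, event) == pytest.approx(
            brute_force_c(scores, time, event), abs=1e-12
        )

    def test_no_comparable_pairs_is_an_error(self):
        with pytest.raises(UndefinedConcordanceError):
            harrell_c([1, 2], [5, 5], [1, 1])


class TestBootstrap:
    def test_fixed_seed_is_deterministic(self, planted_cohort):
        X = planted_cohort.features[["f"]].to_numpy()[:120]
        t = planted_cohort.survival["time_months"].to_numpy()[:120]
        e = planted_cohort.survival["event"].to_numpy()[:120]
        a = bootstrap_c_ci(X, t, e, B=150, seed=5)
        b = bootstrap_c_ci(X, t, e, B=150, seed=5)
        assert a == b

    def test_strong_signal_ci_excludes_chance(self):
        sample = synthetic.generate_cohort(
            synthetic.CohortSimConfig(n_patients=200, beta={"f": 1.0}, seed=3)
        )
        _, (lo, hi) = bootstrap_c_ci(
            sample.features[["f"]].to_numpy(),
            sample.survival["time_months"].to_numpy(),
            sample.survival["event"].to_numpy(),
            B=200,
            seed=1,
        )
        assert lo > 0.5

    def test_small_b_rejected(self, planted_cohort):
        X = planted_cohort.features[["f"]].to_numpy()
        with pytest.raises(ValueError):
            bootstrap_c_ci(
                X,
                planted_cohort.survival["time_months"],
                planted_cohort.survival["event"],
                B=50,
            )


class TestLoocv:
    def test_minimal_n_runs(self):
        c, (lo, hi) = loocv_c(
            np.array([[0.0], [1.0], [2.0], [0.5]]),
            [4.0, 3.0, 1.0, 2.0],
            [1, 1, 1, 1],
            B=100,
            seed=0,
        )
        assert 0.0 <= c <= 1.0 and 0.0 <= lo <= hi <= 1.0

    def test_null_cohort_is_near_chance(self):
        sample = synthetic.generate_cohort(
            synthetic.CohortSimConfig(n_patients=100, seed=21)
        )
        c, _ = loocv_c(
            sample.features[["factor_1"]].to_numpy(),
            sample.survival["time_months"].to_numpy(),
            sample.survival["event"].to_numpy(),
            B=100,
            seed=2,
        )
        assert c == pytest.approx(0.5, abs=0.07)


@pytest.fixture(scope="module")
def screen_cohort():
    cfg = synthetic.CohortSimConfig(
        n_patients=200,
        beta={"invasive_mean_nuclei_size": 0.5},
        feature_means={
            "invasive_mean_nuclei_size": 0.0,
            "mitosis": 3.0,
            "thickness_mm": 3.0,
            "invasive_mean_tumor_nuclei_size": 0.0,
        },
        seed=8,
    )
    sample = synthetic.generate_cohort(cfg)
    return sample.features.merge(sample.survival, on="patient_id")


class TestScreens:
    def test_planted_factor_is_recovered(self, screen_cohort):
        table = univariate_screen(
            screen_cohort,
            factors=["invasive_mean_nuclei_size", "mitosis", "thickness_mm"],
            B=150,
            seed=4,
        )
        row = table.set_index("factor").loc["invasive_mean_nuclei_size"]
        assert row["HR"] > 1.0 and row["p"] < 0.05

    def test_factor_order_independence(self, screen_cohort):
        factors = ["invasive_mean_nuclei_size", "mitosis", "thickness_mm"]
        a = univariate_screen(screen_cohort, factors=factors, B=150, seed=4)
        b = univariate_screen(screen_cohort, factors=factors[::-1], B=150, seed=4)
        a = a.set_index("factor")[["HR", "p"]].sort_index()
        b = b.set_index("factor")[["HR", "p"]].sort_index()
        pd.testing.assert_frame_equal(a, b)

    def test_mostly_missing_factor_excluded_with_warning(self, screen_cohort):
        df = screen_cohort.copy()
        df["sparse"] = np.nan
        df.loc[: len(df) // 4, "sparse"] = 1.0
        with pytest.warns(UserWarning, match="sparse"):
            table = univariate_screen(df, factors=["sparse", "mitosis"], B=150, seed=0)
        assert "sparse" not in set(table["factor"])

    def test_multivariable_schema_and_collinearity(self, screen_cohort):
        results = multivariable_models(
            screen_cohort,
            size_factors=("invasive_mean_nuclei_size",),
            B=150,
            seed=9,
        )
        assert [r.model_id for r in results] == ["base", "invasive_mean_nuclei_size"]
        table = multivariable_table(results)
        assert {
            "model",
            "covariate",
            "HR",
            "ci_lower",
            "ci_upper",
            "p",
            "c_index",
            "loocv_c_index",
        } <= set(table.columns)
        # a duplicated covariate is perfectly collinear
        dup = screen_cohort.copy()
        dup["invasive_mean_nuclei_size"] = dup["thickness_mm"]
        with pytest.raises(ValidationError, match="collinear"):
            multivariable_models(
                dup, size_factors=("invasive_mean_nuclei_size",), B=150, seed=0
            )

    def test_noise_covariate_barely_moves_apparent_c(self, screen_cohort):
        rng = np.random.default_rng(0)
        df = screen_cohort.copy()
        df["noise"] = rng.normal(0, 1, len(df))
        base_factors = ("invasive_mean_nuclei_size", "mitosis")
        base = multivariable_models(
            df, size_factors=(), base_factors=base_factors, B=150, seed=1
        )[0]
        with_noise = multivariable_models(
            df, size_factors=("noise",), base_factors=base_factors, B=150, seed=1
        )[1]
        assert abs(with_noise.c_index - base.c_index) < 0.05


class TestCohortSummary:
    @staticmethod
    def _clinical(n_os_events=16, n_pfs_events=18):
        rows = []
        for ep, n_events, med in (("OS", n_os_events, 35.5), ("PFS", n_pfs_events, 27.5)):
            for i in range(26):
                rows.append(
                    {
                        "patient_id": f"P{i}",
                        "age": [62.0, 63.0][i % 2],
                        "sex": "M" if i < 20 else "F",
                        "mitosis": 3,
                        "thickness_mm": 2.5,
                        "time_months": med + (i - 13),
                        "event": i < n_events,
                        "endpoint": ep,
                    }
                )
        return pd.DataFrame(rows)

    def test_event_percentages_match_cohort_arithmetic(self):
        summary = summarize_cohort(self._clinical())
        assert summary["n"] == 52
        assert summary["endpoints"]["OS"]["events"] == 16
        assert summary["endpoints"]["OS"]["event_percent"] == 61.5
        assert summary["endpoints"]["PFS"]["events"] == 18
        assert summary["endpoints"]["PFS"]["event_percent"] == 69.2
        assert summary["sex"]["M"]["percent"] == 76.9

    def test_singleton(self):
        df = self._clinical().iloc[[0]]
        summary = summarize_cohort(df)
        assert summary["median_age"] == df["age"].iloc[0]
        assert summary["age_range"] == (df["age"].iloc[0], df["age"].iloc[0])

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            summarize_cohort(pd.DataFrame(columns=["age", "event"]))
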
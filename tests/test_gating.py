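import math

import numpy as np
import pytest
from scipy import stats

from melaband import gating, synthetic
from melaband.gating import (
    DegenerateInputError,
    GateError,
    LogMixture,
    fit_log_mixture,
    gate_marker,
    mixture_intersection,
    otsu_threshold,
    split_t0_t1,
)


def brute_force_otsu(values, n_bins=256):
    """Independent oracle: maximize the between-class variance over every
    histogram bin boundary by direct enumeration on the raw values."""
    values = np.asarray(values, dtype=float)
    lo, hi = np.percentile(values, [1.0, 99.0])
    if hi <= lo:
        lo, hi = values.min(), values.max()
    clamped = np.clip(values, lo, hi)
    edges = np.linspace(lo, hi, n_bins + 1)
    # histogram bin assignment, so boundary semantics match exactly
    bins = np.minimum(np.digitize(clamped, edges) - 1, n_bins - 1)
    best, tied = -np.inf, []
    n = values.size
    for b in range(n_bins - 1):  # boundary between bin b and b+1
        left = clamped[bins <= b]
        right = clamped[bins > b]
        if left.size == 0 or right.size == 0:
            continue
        sb2 = (left.size / n) * (right.size / n) * (left.mean() - right.mean()) ** 2
        if sb2 > best:
            best, tied = sb2, [edges[b + 1]]
        elif sb2 == best:
            tied.append(edges[b + 1])
    return (tied[0] + tied[-1]) / 2.0, best


class TestOtsu:
    def test_symmetric_two_delta_splits_in_the_middle(self):
        values = np.array([0.0] * 500 + [10.0] * 500)
        split = otsu_threshold(values, n_bins=256)
        bin_width = 10.0 / 256
        assert abs(split.threshold - 5.0) <= bin_width
        assert split.omega0 == pytest.approx(0.5)
        assert split.omega1 == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = np.concatenate(
            [rng.normal(2.0, 0.8, 600), rng.normal(7.0, 1.2, 400)]
        )
        split = otsu_threshold(values)
        t_oracle, sb2_oracle = brute_force_otsu(values)
        assert split.threshold == pytest.approx(t_oracle, abs=1e-12)
        assert split.between_class_variance == pytest.approx(sb2_oracle, rel=1e-12)

    def test_outlier_robust_under_percentile_binning(self, rng):
        values = np.concatenate([rng.normal(2.0, 0.5, 800), rng.normal(6.0, 0.5, 200)])
        base = otsu_threshold(values).threshold
        with_outlier = otsu_threshold(np.append(values, 10 * values.max())).threshold
        bin_width = (np.percentile(values, 99) - np.percentile(values, 1)) / 256
        assert abs(base - with_outlier) <= bin_width

    def test_class_probabilities_sum_to_one(self, rng):
        split = otsu_threshold(rng.exponential(3.0, 500))
        assert split.omega0 + split.omega1 == pytest.approx(1.0, abs=1e-9)
        assert split.between_class_variance > 0

    def test_identical_values_rejected(self):
        with pytest.raises(DegenerateInputError):
            otsu_threshold(np.full(100, 3.0))


class TestSplit:
    def test_two_delta_foreground(self):
        values = np.array([0.0] * 500 + [10.0] * 500)
        split = otsu_threshold(values)
        t0, t1 = split_t0_t1(values, split)
        assert np.all(t1 == 10.0) and t1.size == 500

    @pytest.mark.parametrize("seed", range(3))
    def test_partition_conserves_counts(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.lognormal(1.0, 1.0, 777)
        split = otsu_threshold(values)
        t0, t1 = split_t0_t1(values, split)
        assert t0.size + t1.size == values.size
        assert t1.size > 0


class TestLogMixture:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(5)
        n = 2000
        comp = rng.random(n) < 0.6
        x = np.where(comp, rng.normal(3.0, 0.3, n), rng.normal(1.0, 0.3, n))
        mix = fit_log_mixture(np.exp(x))
        assert mix.means[0] == pytest.approx(1.0, abs=0.1)
        assert mix.means[1] == pytest.approx(3.0, abs=0.1)
        assert mix.weights[0] == pytest.approx(0.4, abs=0.05)
        assert mix.weights[1] == pytest.approx(0.6, abs=0.05)

    def test_identical_values_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_log_mixture(np.full(100, 2.0))

    def test_too_few_values_rejected(self):
        with pytest.raises(GateError):
            fit_log_mixture(np.arange(1.0, 9.0))

    @pytest.mark.parametrize("seed", range(4))
    def test_objective_trace_is_non_decreasing(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.lognormal(rng.uniform(0, 2), rng.uniform(0.3, 1.0), 500)
        mix = fit_log_mixture(values)
        trace = np.array(mix.objective_trace)
        assert np.all(np.diff(trace) >= -1e-8)

    def test_nonpositive_values_are_dropped(self, caplog):
        rng = np.random.default_rng(1)
        values = np.concatenate([rng.lognormal(1, 0.5, 200), [-1.0, 0.0]])
        mix = fit_log_mixture(values)
        assert mix.means[0] < mix.means[1]

    def test_agrees_with_sklearn_bgmm_on_separated_data(self):
        from sklearn.mixture import BayesianGaussianMixture

        rng = np.random.default_rng(2)
        n = 1500
        comp = rng.random(n) < 0.5
        x = np.where(comp, rng.normal(4.0, 0.4, n), rng.normal(0.0, 0.4, n))
        mix = fit_log_mixture(np.exp(x))
        ref = BayesianGaussianMixture(
            n_components=2, max_iter=3000, tol=1e-6, random_state=0
        ).fit(x.reshape(-1, 1))
        order = np.argsort(ref.means_.ravel())
        np.testing.assert_allclose(mix.means, ref.means_.ravel()[order], atol=0.05)
        np.testing.assert_allclose(mix.weights, ref.weights_[order], atol=0.03)
        np.testing.assert_allclose(
            mix.sds, np.sqrt(ref.covariances_.ravel()[order]), atol=0.05
        )


class TestIntersection:
    def test_symmetric_case_is_the_midpoint(self):
        mix = LogMixture((0.5, 0.5), (0.0, 4.0), (1.0, 1.0), 1, True)
        x, fallback = mixture_intersection(mix)
        assert not fallback
        assert x == pytest.approx(2.0, abs=1e-10)

    @pytest.mark.parametrize(
        "weights,means,sds",
        [
            ((0.5, 0.5), (0.0, 4.0), (1.0, 2.0)),
            ((0.3, 0.7), (0.0, 4.0), (0.8, 1.5)),
            ((0.7, 0.3), (1.0, 3.0), (0.5, 0.9)),
        ],
    )
    def test_matches_bisection_oracle(self, weights, means, sds):
        from scipy.optimize import brentq

        mix = LogMixture(weights, means, sds, 1, True)
        x, fallback = mixture_intersection(mix)
        assert not fallback

        def diff(t):
            return weights[0] * stats.norm.pdf(t, means[0], sds[0]) - weights[
                1
            ] * stats.norm.pdf(t, means[1], sds[1])

        oracle = brentq(diff, means[0] + 1e-9, means[1] - 1e-9)
        assert x == pytest.approx(oracle, abs=1e-8)

    def test_weighted_densities_agree_at_the_root(self):
        mix = LogMixture((0.3, 0.7), (0.0, 3.0), (0.7, 1.1), 1, True)
        x, fallback = mixture_intersection(mix)
        assert not fallback
        gap = abs(
            mix.weights[0] * stats.norm.pdf(x, mix.means[0], mix.sds[0])
            - mix.weights[1] * stats.norm.pdf(x, mix.means[1], mix.sds[1])
        )
        assert gap < 1e-8

    def test_extreme_imbalance_uses_fallback_inside_the_interval(self):
        mix = LogMixture((0.999, 0.001), (0.0, 1.0), (1.0, 1.0), 1, True)
        x, fallback = mixture_intersection(mix)
        assert fallback
        assert 0.0 <= x <= 1.0


class TestGateMarker:
    def test_six_sd_separation_recovers_latent_labels(self):
        mix = {
            "dapi": synthetic.MarkerMix(2.0, 0.4, 4.0, 0.4, 0.95),
            "ki67": synthetic.MarkerMix(1.0, 0.5, 4.0, 0.5, 0.5),
            "s100": synthetic.MarkerMix(1.0, 0.5, 4.0, 0.5, 0.5),
        }
        cfg = synthetic.SlideSimConfig(seed=1, marker_mix=mix)
        _, cells, truth = synthetic.generate_slide(cfg, "S")
        for marker in ("ki67", "s100"):
            gate, flags = gate_marker(cells, marker)
            agreement = (flags.to_numpy() == truth[f"{marker}_pos"].to_numpy()).mean()
            assert not gate.failed
            assert agreement >= 0.99

    def test_multiplicative_rescale_leaves_positive_set_unchanged(self, default_slide):
        _, _, cells, _ = default_slide
        _, flags = gate_marker(cells, "ki67")
        scaled = cells.copy()
        scaled["ki67_nucleus_mean"] = scaled["ki67_nucleus_mean"] * 3.7
        _, flags_scaled = gate_marker(scaled, "ki67")
        assert (flags == flags_scaled).all()

    def test_positive_fraction_non_increasing_in_threshold(self, default_slide):
        _, _, cells, _ = default_slide
        gate, flags = gate_marker(cells, "ki67")
        values = cells[f"ki67_{gate.compartment}_mean"].to_numpy()
        base_frac = flags.mean()
        for factor in (1.1, 1.5, 2.0):
            raised = (values > math.exp(gate.otsu.threshold)) & (
                values >= gate.final_threshold * factor
            )
            assert raised.mean() <= base_frac

    def test_empty_cells_give_failed_gate_and_empty_flags(self, default_slide):
        _, _, cells, _ = default_slide
        gate, flags = gate_marker(cells.iloc[:0], "ki67")
        assert gate.failed
        assert len(flags) == 0

    def test_failed_gate_marks_all_negative(self, default_slide):
        _, _, cells, _ = default_slide
        broken = cells.copy()
        broken["ki67_nucleus_mean"] = 1.0  # degenerate: no structure at all
        gate, flags = gate_marker(broken, "ki67")
        assert gate.failed
        assert not flags.any()
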
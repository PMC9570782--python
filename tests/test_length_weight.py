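import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fishmetrics import (
    LengthWeightTable,
    SimConfig,
    fit_gmm,
    gen_population,
    contaminate_lengths,
    knn_weight,
    mask_length,
    nongaussianity,
    posterior_membership,
    relative_error,
    run_length_weight_pipeline,
    select_model,
    single_fish_component,
)
from fishmetrics.length_weight import (
    GmmFit,
    InsufficientDataError,
    hard_assignments,
)


def _brute_force_length(mask, w, h):
    vs, us = np.nonzero(mask)
    best = 0.0
    for i in range(len(us)):
        for j in range(i + 1, len(us)):
            d = np.hypot((us[i] - us[j]) * w, (vs[i] - vs[j]) * h)
            best = max(best, d)
    return best


class TestMaskLength:
    def test_horizontal_run(self):
        mask = np.zeros((5, 20), dtype=bool)
        mask[2, 3:14] = True  # 11 pixels
        assert mask_length(mask, (0.5, 0.5)) == pytest.approx(5.0)

    def test_single_pixel_has_zero_length(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        assert mask_length(mask, (0.5, 0.5)) == 0.0

    def test_l_shape_matches_all_pairs_oracle(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[1, 1:9] = True
        mask[1:9, 1] = True
        mask[5, 5] = True  # 20 pixels total, anisotropic footprint
        w, h = 0.583, 0.549
        assert mask_length(mask, (w, h)) == pytest.approx(_brute_force_length(mask, w, h))

    def test_random_masks_match_exhaustive_oracle(self, rng):
        for _ in range(15):
            mask = np.zeros((20, 20), dtype=bool)
            n = rng.integers(2, 200)
            idx = rng.choice(400, size=n, replace=False)
            mask.ravel()[idx] = True
            assert mask_length(mask, (0.7, 0.3)) == pytest.approx(
                _brute_force_length(mask, 0.7, 0.3), rel=1e-12
            )

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            mask_length(np.zeros((4, 4), dtype=bool), (1, 1))


class TestFitGmm:
    def test_single_component_closed_form(self, rng):
        x = rng.normal(20, 2, size=500)
        fit = fit_gmm(x, c=1)
        assert fit.weights == pytest.approx([1.0])
        assert fit.means[0] == pytest.approx(x.mean(), rel=1e-9)
        assert fit.variances[0] == pytest.approx(x.var(), rel=1e-6)  # ML, denominator n

    def test_separated_clusters_recovered(self, rng):
        x = np.concatenate([rng.normal(10, 1, 300), rng.normal(30, 1, 300)])
        fit = fit_gmm(x, c=2, seed=0)
        assert fit.means == pytest.approx([10, 30], abs=0.5)

    def test_loglik_non_decreasing(self, rng):
        x = np.concatenate([rng.normal(10, 1, 100), rng.normal(16, 2, 150)])
        fit = fit_gmm(x, c=2, seed=0)
        diffs = np.diff(fit.loglik_trace)
        assert (diffs >= -1e-8).all()

    def test_matches_sklearn_oracle_on_separated_data(self, rng):
        from sklearn.mixture import GaussianMixture

        x = np.concatenate([rng.normal(12, 1.5, 400), rng.normal(35, 2, 200)])
        ours = fit_gmm(x, c=2, seed=0)
        ref = GaussianMixture(2, n_init=5, random_state=0).fit(x.reshape(-1, 1))
        order = np.argsort(ref.means_.ravel())
        assert ours.means == pytest.approx(ref.means_.ravel()[order], abs=0.05)
        assert ours.weights == pytest.approx(ref.weights_[order], abs=0.01)

    def test_insufficient_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_gmm([1.0, 2.0], c=3)

    def test_responsibilities_rows_sum_to_one(self, rng):
        x = rng.normal(20, 3, size=200)
        fit = fit_gmm(x, c=3, seed=1)
        assert fit.responsibilities.sum(axis=1) == pytest.approx(np.ones(200))
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-9)


class TestPosterior:
    def test_single_component_certain(self, rng):
        fit = fit_gmm(rng.normal(0, 1, 50), c=1)
        assert posterior_membership(0.3, fit) == pytest.approx([1.0])

    def test_symmetric_midpoint_is_fifty_fifty(self):
        fit = GmmFit(
            c=2,
            weights=np.array([0.5, 0.5]),
            means=np.array([10.0, 30.0]),
            variances=np.array([4.0, 4.0]),
            samples=np.array([10.0, 10.0, 30.0, 30.0]),
            responsibilities=np.full((4, 2), 0.5),
            loglik_trace=np.array([0.0]),
        )
        assert posterior_membership(20.0, fit) == pytest.approx([0.5, 0.5])

    def test_matches_scalar_formula_oracle(self):
        w = np.array([0.3, 0.7])
        mu = np.array([5.0, 12.0])
        var = np.array([2.0, 6.0])
        fit = GmmFit(
            c=2,
            weights=w,
            means=mu,
            variances=var,
            samples=np.array([5.0, 5, 12, 12]),
            responsibilities=np.full((4, 2), 0.5),
            loglik_trace=np.array([0.0]),
        )
        x = 8.3
        dens = w * np.exp(-((x - mu) ** 2) / (2 * var)) / np.sqrt(2 * np.pi * var)
        assert posterior_membership(x, fit) == pytest.approx(dens / dens.sum(), rel=1e-12)


class TestNonGaussianity:
    def test_zero_on_symmetric_kurtosis_three_sample(self):
        # {-a, 0, 0, 0, 0, a} has skewness 0 and kurtosis exactly 3
        a = 2.5
        x = np.array([-a, 0.0, 0.0, 0.0, 0.0, a])
        fit = fit_gmm(x, c=1)
        assert nongaussianity(fit) == pytest.approx(0.0, abs=1e-12)

    def test_small_on_large_normal_sample(self):
        x = np.random.default_rng(99).standard_normal(10_000)
        fit = fit_gmm(x, c=1)
        assert nongaussianity(fit) < 0.1

    def test_matches_hand_loop_on_assigned_sample(self):
        x = np.array([1.0, 2.0, 2.5, 3.0, 4.0, 9.0])
        fit = fit_gmm(x, c=1)
        mu, sd = fit.means[0], np.sqrt(fit.variances[0])
        z = (x - mu) / sd
        expected = abs((z ** 3).mean()) + abs((z ** 4).mean() - 3)
        assert nongaussianity(fit) == pytest.approx(expected, rel=1e-12)

    def test_component_below_four_members_disqualified(self, rng):
        x = np.concatenate([rng.normal(10, 0.5, 50), [100.0, 101.0]])
        fit = fit_gmm(x, c=2, seed=0)
        assert nongaussianity(fit) == np.inf


class TestModelSelection:
    def test_unimodal_selects_one_component(self, rng):
        x = rng.normal(22, 2, size=800)
        assert select_model(x, seed=0).c == 1

    def test_bimodal_selects_two_components(self, rng):
        x = np.concatenate([rng.normal(22, 1.5, 700), rng.normal(44, 2, 300)])
        assert select_model(x, seed=0).c == 2

    def test_needs_five_samples(self):
        with pytest.raises(InsufficientDataError):
            select_model([1.0, 2.0, 3.0, 4.0])


class TestSingleFishComponent:
    def test_largest_weight_wins(self):
        fit = GmmFit(
            c=2,
            weights=np.array([0.7, 0.3]),
            means=np.array([20.0, 40.0]),
            variances=np.array([1.0, 1.0]),
            samples=np.zeros(8),
            responsibilities=np.full((8, 2), 0.5),
            loglik_trace=np.array([0.0]),
        )
        assert single_fish_component(fit) == 0

    def test_tie_breaks_to_smaller_mean(self):
        fit = GmmFit(
            c=2,
            weights=np.array([0.5, 0.5]),
            means=np.array([40.0, 20.0]),
            variances=np.array([1.0, 1.0]),
            samples=np.zeros(8),
            responsibilities=np.full((8, 2), 0.5),
            loglik_trace=np.array([0.0]),
        )
        assert single_fish_component(fit) == 1

    def test_single_component(self, rng):
        assert single_fish_component(fit_gmm(rng.normal(0, 1, 30), c=1)) == 0

    def test_contaminated_population_mean_recovered_within_5pct(self):
        cfg = SimConfig(seed=42, n_fish=800)
        lengths, _, _ = gen_population(cfg)
        inst, _ = contaminate_lengths(lengths, cfg)
        fit = select_model(inst, seed=0)
        star = single_fish_component(fit)
        assert abs(fit.means[star] - cfg.mean_length_cm) / cfg.mean_length_cm < 0.05


class TestKnnWeight:
    def test_constant_table(self):
        table = LengthWeightTable(np.arange(1, 6, dtype=float), np.full(5, 200.0))
        assert knn_weight(10.0, table) == 200.0

    def test_matches_brute_force_sort(self, rng):
        lengths = rng.uniform(10, 30, size=40)
        weights = rng.uniform(100, 400, size=40)
        table = LengthWeightTable(lengths, weights)
        q = 21.3
        order = sorted(range(40), key=lambda i: (abs(lengths[i] - q), lengths[i]))
        expected = np.mean([weights[i] for i in order[:5]])
        assert knn_weight(q, table) == pytest.approx(expected)

    def test_tie_at_kth_distance_prefers_smaller_length(self):
        # query 20: distances 0,1,1,2,2,3 — the K=5th slot is tied between 18 and 22
        lengths = np.array([20.0, 19.0, 21.0, 22.0, 18.0, 23.0])
        weights = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0])
        got = knn_weight(20.0, LengthWeightTable(lengths, weights))
        assert got == pytest.approx(np.mean([1, 2, 4, 16, 8]))

    def test_allometric_grid_interior_accuracy(self):
        L = np.linspace(10, 30, 300)
        table = LengthWeightTable(L, 0.02 * L ** 3)
        for q in [12.0, 18.5, 25.0, 28.0]:
            assert knn_weight(q, table) == pytest.approx(0.02 * q ** 3, rel=0.05)

    def test_table_too_small(self):
        table = LengthWeightTable([1.0, 2.0], [10.0, 20.0])
        with pytest.raises(InsufficientDataError):
            knn_weight(1.5, table)


class TestRelativeError:
    @pytest.mark.parametrize(
        "estimate,manual,expected",
        [(22.63, 21.98, 0.03), (220.32, 286.37, 0.23), (18.90, 18.01, 0.05), (17.98, 15.46, 0.16)],
    )
    def test_reference_pairs_round_to_reported_values(self, estimate, manual, expected):
        assert round(relative_error(estimate, manual), 2) == expected

    def test_exact_estimate_has_zero_error(self):
        assert relative_error(7.7, 7.7) == 0.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_error(1.0, 0.0)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(0.1, 1e4), st.floats(0.1, 1e4))
    def test_symmetric_in_deviation_sign(self, manual, dev):
        over = relative_error(manual + dev, manual)
        under = relative_error(manual - dev, manual)
        assert over == pytest.approx(under)
        assert over == pytest.approx(dev / manual, rel=1e-9)


class TestPipeline:
    def test_gmm_filter_beats_raw_estimate_under_contamination(self):
        cfg = SimConfig(seed=7, n_fish=600, merged_fraction=0.3, partial_fraction=0.0)
        lengths, weights, table = gen_population(cfg)
        inst, _ = contaminate_lengths(lengths, cfg)
        summary = run_length_weight_pipeline(
            inst, (0.583, 0.549), table,
            manual_length=cfg.mean_length_cm, manual_weight=float(weights.mean()), seed=0,
        )
        assert summary.eps_length_gmm < summary.eps_length_raw
        assert summary.n_single <= summary.n_instances

    def test_no_contamination_limit_agrees_with_raw(self):
        cfg = SimConfig(seed=8, n_fish=400, merged_fraction=0.0, partial_fraction=0.0)
        lengths, _, table = gen_population(cfg)
        summary = run_length_weight_pipeline(lengths, (0.583, 0.549), table, seed=0)
        assert summary.mean_length_gmm == pytest.approx(summary.mean_length_raw, rel=0.05)

    def test_too_few_instances_rejected(self):
        table = LengthWeightTable(np.arange(1, 11, dtype=float), np.arange(1, 11, dtype=float))
        with pytest.raises(InsufficientDataError):
            run_length_weight_pipeline([20.0, 21.0], (1, 1), table)
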
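import numpy as np
import pytest

from dpmlpa.outcomes import (
    OutcomePriorSpec,
    Partition,
    analyze_outcome,
    bayes_factor_anova,
    effect_size_r2,
    hard_assign,
    iter_partitions,
    log_partition_evidence,
    posterior_profile_means,
    posthoc_partition_search,
)
from quadrature import log_evidence_quadrature, posterior_mean_quadrature

BELL = {1: 1, 2: 2, 3: 5, 4: 15, 5: 52, 6: 203, 7: 877, 8: 4140}


class TestPartitions:
    @pytest.mark.parametrize("T", list(BELL))
    def test_counts_equal_bell_numbers(self, T):
        assert sum(1 for _ in iter_partitions(T)) == BELL[T]

    def test_three_profile_partitions(self):
        parts = {str(p) for p in iter_partitions(3)}
        assert parts == {
            "{1,2,3}",
            "{1,2},{3}",
            "{1,3},{2}",
            "{1},{2,3}",
            "{1},{2},{3}",
        }

    def test_single_profile_trivial_partition(self):
        parts = list(iter_partitions(1))
        assert len(parts) == 1 and parts[0].block_of == (1,)

    def test_rejects_non_rgs_labels(self):
        with pytest.raises(ValueError):
            Partition(block_of=(2, 1), n_blocks=2)


class TestHardAssign:
    def test_one_hot_rows(self):
        resp = np.eye(3)[[2, 0, 1]]
        assert hard_assign(resp).tolist() == [3, 1, 2]

    def test_tie_goes_to_lowest_label(self):
        assert hard_assign(np.array([[0.5, 0.5]])).tolist() == [1]

    def test_interior_maximum(self):
        assert hard_assign(np.array([[0.2, 0.5, 0.3]])).tolist() == [2]


class TestQuadratureAgreement:
    """Closed-form evidences match brute-force integration on tiny data."""

    CASES = [
        # (y, labels, T, prior)
        (np.array([0.0]), [1], 1, OutcomePriorSpec()),
        (np.array([1.2, -0.3, 0.5, 2.0]), [1, 1, 2, 2], 2, OutcomePriorSpec()),
        (
            np.array([0.4, -1.1, 0.9, 0.0, 1.7, -0.6]),
            [1, 2, 3, 1, 2, 3],
            3,
            OutcomePriorSpec(),
        ),
        (
            np.array([2.0, 2.2, -0.1, 0.3, 1.1, -2.0, 0.7, 0.9, -1.4, 0.2, 0.5, 1.0]),
            [1, 1, 1, 2, 2, 2, 3, 3, 3, 1, 2, 3],
            3,
            OutcomePriorSpec(precision_shape=2.0, precision_rate=1.5,
                             mean_variance_multiplier=0.5),
        ),
    ]

    @pytest.mark.parametrize("y, labels, T, prior", CASES)
    def test_partition_evidences(self, y, labels, T, prior):
        for part in iter_partitions(T):
            closed = log_partition_evidence(y, np.array(labels), part, prior)
            quad = log_evidence_quadrature(
                y, labels, part.block_of,
                a0=prior.precision_shape, b0=prior.precision_rate,
                c=prior.mean_variance_multiplier,
            )
            assert closed == pytest.approx(quad, rel=1e-6)

    def test_bayes_factor_matches_quadrature(self):
        y = np.array([1.2, -0.3, 0.5, 2.0, -1.0, 0.4])
        labels = np.array([1, 1, 2, 2, 3, 3])
        log10_bf, bf = bayes_factor_anova(y, labels, 3)
        q1 = log_evidence_quadrature(y, labels, (1, 2, 3))
        q0 = log_evidence_quadrature(y, labels, (1, 1, 1))
        assert log10_bf == pytest.approx((q1 - q0) / np.log(10), rel=1e-6)
        assert bf == pytest.approx(10**log10_bf, rel=1e-9)

    def test_prior_predictive_at_single_point(self):
        """n=1, y=0, one block: evidence is the prior predictive density at 0."""
        closed = log_partition_evidence(np.array([0.0]), np.array([1]),
                                        Partition.from_labels([1]))
        quad = log_evidence_quadrature([0.0], [1], (1,))
        assert closed == pytest.approx(quad, rel=1e-6)


class TestPosteriorProfileMeans:
    def test_empty_profile_keeps_prior_location(self):
        y = np.array([1.0, -1.0, 0.5])
        out = posterior_profile_means(y, np.array([1, 1, 1]), T=2)
        assert out[1]["location"] == pytest.approx(0.0)
        assert out[1]["n"] == 0

    def test_symmetric_data_centers_at_zero(self):
        out = posterior_profile_means(np.array([1.0, -1.0]), np.array([1, 1]), T=1)
        assert out[0]["location"] == pytest.approx(0.0, abs=1e-12)

    def test_conjugate_shrinkage(self):
        # ybar = 2 with 2 observations and unit prior pseudo-weight: 4/3
        out = posterior_profile_means(np.array([2.0, 2.0]), np.array([1, 1]), T=1)
        assert out[0]["location"] == pytest.approx(4.0 / 3.0)

    def test_location_matches_quadrature_posterior_mean(self):
        y = [0.8, 1.6, -0.2]
        out = posterior_profile_means(np.array(y), np.array([1, 1, 1]), T=1)
        assert out[0]["location"] == pytest.approx(
            posterior_mean_quadrature(y), rel=1e-6
        )

    def test_credible_interval_brackets_location(self):
        out = posterior_profile_means(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]), T=1)
        assert out[0]["ci_low"] < out[0]["location"] < out[0]["ci_high"]


class TestAnovaAndPosthoc:
    def test_null_data_favors_h0_in_majority(self):
        rng = np.random.default_rng(10)
        negative = 0
        reps = 40
        for _ in range(reps):
            y = rng.standard_normal(40)
            labels = np.repeat([1, 2], 20)
            log10_bf, _ = bayes_factor_anova(y, labels, 2)
            negative += log10_bf < 0
        assert negative >= 0.75 * reps

    def test_strong_signal_gives_large_bf(self):
        rng = np.random.default_rng(1)
        y = np.concatenate([rng.standard_normal(50), 3.0 + rng.standard_normal(50)])
        labels = np.repeat([1, 2], 50)
        log10_bf, _ = bayes_factor_anova(y, labels, 2)
        assert log10_bf > 2.0

    def test_single_profile_anova_rejected(self):
        with pytest.raises(ValueError):
            bayes_factor_anova(np.array([1.0, 2.0]), np.array([1, 1]), 1)

    def test_posthoc_recovers_planted_grouping(self):
        rng = np.random.default_rng(2)
        y = np.concatenate([
            rng.standard_normal(60),
            rng.standard_normal(60),
            5.0 + rng.standard_normal(60),
        ])
        labels = np.repeat([1, 2, 3], 60)
        best, scored = posthoc_partition_search(y, labels, 3)
        assert str(best) == "{1,2},{3}"
        assert len(scored) == 5

    def test_anova_reproducible_from_posthoc_evidences(self):
        y = np.array([0.3, -0.8, 1.2, 0.4, -0.2, 0.9])
        labels = np.array([1, 2, 3, 1, 2, 3])
        _, scored = posthoc_partition_search(y, labels, 3)
        ev = {str(p): e for p, e in scored}
        log10_bf, _ = bayes_factor_anova(y, labels, 3)
        assert log10_bf == pytest.approx(
            (ev["{1},{2},{3}"] - ev["{1,2,3}"]) / np.log(10)
        )

    def test_bell_cap_enforced(self):
        with pytest.raises(ValueError, match="cap"):
            posthoc_partition_search(np.zeros(20), np.ones(20, int), 20, bell_cap=100)


class TestEffectSize:
    def test_hand_computed_value(self):
        y = np.array([0.0, 2.0, 4.0, 6.0])
        labels = np.array([1, 1, 2, 2])
        assert effect_size_r2(y, labels, [1.0, 5.0]) == pytest.approx(0.8)

    def test_grand_mean_prediction_gives_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert effect_size_r2(y, np.ones(4, int), [2.5]) == pytest.approx(0.0)

    def test_perfect_prediction_gives_one(self):
        y = np.array([1.0, 2.0])
        assert effect_size_r2(y, np.array([1, 2]), [1.0, 2.0]) == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        y = rng.standard_normal(30)
        labels = rng.integers(1, 4, size=30)
        means = np.array([rng.standard_normal() for _ in range(3)])
        base = effect_size_r2(y, labels, means)
        assert effect_size_r2(2.5 * y - 1.0, labels, 2.5 * means - 1.0) == pytest.approx(base)

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError):
            effect_size_r2(np.ones(5), np.ones(5, int), [1.0])


class TestAnalyzeOutcome:
    def test_planted_difference_detected_with_correct_sign(self):
        rng = np.random.default_rng(8)
        n_per = 80
        resp = np.zeros((3 * n_per, 3))
        resp[np.arange(3 * n_per), np.repeat([0, 1, 2], n_per)] = 1.0
        y = np.concatenate([
            -0.5 + rng.standard_normal(n_per),
            rng.standard_normal(n_per),
            0.5 + rng.standard_normal(n_per),
        ])
        res = analyze_outcome(y, resp)
        assert res.verdict == "supports_H1"
        assert res.log10_bf10 > 0.5
        locs = [p["location"] for p in res.profile_posteriors]
        assert locs[0] < locs[1] < locs[2]
        assert 0 < res.r2 < 1
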
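"""Mitotic-age scores, division-rate estimators and turnover converters."""

import numpy as np
import pandas as pd
import pytest

from mitoclock import (
    estimate_tnsc,
    first_order_beta,
    group_auc,
    hypo_age_adjust,
    hypo_rescale,
    hypo_score,
    intrinsic_rate,
    lifetime_rate,
    pcgt_age_score,
    score_samples,
    skin_lifetime_ir,
    trajectory_approx,
    turnover_to_ir,
)


class TestEstimateTnsc:
    def test_exact_inverse_of_first_order_model(self, param_table):
        """The score inverts the linear gain model exactly."""
        # keep all probes below the saturation cap (t < 2/delta_max)
        for tnsc in (0.0, 137.5, 1400.0, 1900.0):
            betas = pd.Series(
                first_order_beta(
                    param_table["delta"].to_numpy(),
                    param_table["beta0"].to_numpy(),
                    tnsc,
                ),
                index=param_table.index,
            )
            assert estimate_tnsc(betas, param_table) == pytest.approx(
                tnsc, abs=1e-9
            )

    def test_ground_state_scores_zero(self, param_table):
        betas = pd.Series(
            param_table["beta0"].to_numpy(), index=param_table.index
        )
        assert estimate_tnsc(betas, param_table) == pytest.approx(0.0, abs=1e-9)

    def test_reduces_to_scaled_mean_beta(self):
        """With beta0=0 and equal deltas, TNSC = (2/delta)*mean(beta):
        the averaging clock is the kinetic clock's special case."""
        rng = np.random.default_rng(3)
        probes = [f"cg{i}" for i in range(40)]
        delta = 5e-5
        params = pd.DataFrame(
            {"delta": delta, "beta0": 0.0}, index=pd.Index(probes)
        )
        betas = pd.Series(rng.uniform(0, 0.4, 40), index=probes)
        expected = (2.0 / delta) * pcgt_age_score(betas, probes)
        assert estimate_tnsc(betas, params) == pytest.approx(expected, rel=1e-12)

    def test_low_coverage_errors_with_probe_names(self, param_table):
        betas = pd.Series(0.1, index=param_table.index[:10])
        with pytest.raises(ValueError, match="80%"):
            estimate_tnsc(betas, param_table)

    def test_negative_contributions_not_clipped(self, param_table):
        betas = pd.Series(0.0, index=param_table.index)  # below all beta0
        assert estimate_tnsc(betas, param_table) < 0


class TestRates:
    def test_lifetime_rate(self):
        assert lifetime_rate(350.0, 10.0) == 35.0
        assert lifetime_rate(0.0, 50.0) == 0.0
        with pytest.raises(ValueError):
            lifetime_rate(100.0, 0.0)

    def test_intrinsic_rate_median_default(self):
        est = intrinsic_rate([300, 350, 400], [10, 10, 10])
        assert est.ir == 35.0
        assert est.estimator == "median"

    def test_median_robust_to_outlier(self):
        est = intrinsic_rate([300, 350, 1000], [10, 10, 10])
        assert est.ir == 35.0

    def test_mean_option(self):
        est = intrinsic_rate([300, 350, 400], [10, 10, 10], estimator="mean")
        assert est.ir == 35.0

    def test_empty_or_bad_ages_rejected(self):
        with pytest.raises(ValueError):
            intrinsic_rate([], [])
        with pytest.raises(ValueError):
            intrinsic_rate([100.0], [0.0])


class TestAveragingClocks:
    def test_mean_of_constant(self):
        probes = ["a", "b", "c"]
        betas = pd.Series(0.2, index=probes)
        assert pcgt_age_score(betas, probes) == pytest.approx(0.2)

    def test_mean_of_mixed(self):
        probes = ["a", "b"]
        betas = pd.Series([0.0, 1.0], index=probes)
        assert pcgt_age_score(betas, probes) == pytest.approx(0.5)

    def test_hypo_score_drops_with_mitotic_age(self):
        """Loss dynamics: 1 - beta follows the gain trajectory, so older
        samples have lower scores."""
        probes = [f"s{i}" for i in range(20)]
        young = pd.Series(
            1.0 - trajectory_approx(5e-4, 0.05, 20 * 35.0), index=probes
        )
        old = pd.Series(
            1.0 - trajectory_approx(5e-4, 0.05, 80 * 35.0), index=probes
        )
        assert hypo_score(old, probes) < hypo_score(young, probes)

    def test_disjoint_probes_error(self):
        betas = pd.Series([0.5], index=["other"])
        with pytest.raises(ValueError):
            hypo_score(betas, ["s1", "s2"])


class TestHypoAdjustment:
    def test_hand_computed_adjustment(self):
        adjusted, med = hypo_age_adjust([0.9, 0.8], [50.0, 100.0])
        assert adjusted == pytest.approx([0.002, 0.002])
        assert med == pytest.approx(0.002)

    def test_fully_methylated_adjusts_to_zero(self):
        adjusted, _ = hypo_age_adjust([1.0], [73.0])
        assert adjusted[0] == 0.0

    def test_adjusted_tracks_true_rate_in_loss_simulation(self):
        """Higher division rate -> more loss per year -> larger adjusted value."""
        ages = np.linspace(20, 90, 50)
        for slow, fast in [(5.0, 35.0), (10.0, 60.0)]:
            score_slow = 1.0 - trajectory_approx(5e-4, 0.05, ages * slow)
            score_fast = 1.0 - trajectory_approx(5e-4, 0.05, ages * fast)
            _, med_slow = hypo_age_adjust(score_slow, ages)
            _, med_fast = hypo_age_adjust(score_fast, ages)
            assert med_fast > med_slow

    def test_nonpositive_age_rejected(self):
        with pytest.raises(ValueError):
            hypo_age_adjust([0.9], [-1.0])


class TestHypoRescale:
    def test_hand_computed_example(self):
        out = hypo_rescale([0.6, 0.8], [0.005, 0.009])
        assert out == pytest.approx([0.2, 0.4])

    def test_range_and_max_identities(self):
        rng = np.random.default_rng(11)
        hypo = rng.uniform(0.4, 0.95, 30)
        adj = (1 - hypo) / rng.uniform(20, 90, 30)
        out = hypo_rescale(hypo, adj)
        assert np.ptp(out) == pytest.approx(np.ptp(hypo), rel=1e-12)
        assert np.max(out) == pytest.approx(np.max(1 - hypo), rel=1e-12)

    def test_constant_adjusted_rejected(self):
        with pytest.raises(ValueError):
            hypo_rescale([0.6, 0.8], [0.005, 0.005])
        with pytest.raises(ValueError):
            hypo_rescale([0.6], [0.005])


class TestTurnoverConverters:
    def test_blood_turnover(self):
        assert turnover_to_ir(10.0) == pytest.approx(36.5)

    def test_stomach_turnover(self):
        assert turnover_to_ir(5.5) == pytest.approx(66.4, abs=0.05)

    def test_annual_turnover(self):
        assert turnover_to_ir(365.0) == 1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            turnover_to_ir(0.0)

    def test_teenager_skin(self):
        assert skin_lifetime_ir(15.0) == pytest.approx(365.0 / 21.0)

    def test_turnover_time_anchors(self):
        from mitoclock.clocks import _skin_rd

        assert _skin_rd(50.0) == 45.0
        assert _skin_rd(80.0) == 90.0

    def test_age_fifty_piecewise(self):
        assert skin_lifetime_ir(50.0) == pytest.approx(
            (20 * 365 / 21 + 30 * 365 / 35) / 50
        )
        assert 13.2 <= skin_lifetime_ir(50.0) <= 13.3

    def test_rate_declines_after_fifty(self):
        assert skin_lifetime_ir(80.0) < skin_lifetime_ir(50.0)

    def test_cohort_average_mode(self):
        ages = np.array([30.0, 50.0, 70.0])
        expected = np.mean([skin_lifetime_ir(a) for a in ages])
        assert skin_lifetime_ir(ages, cohort_average=True) == pytest.approx(
            expected
        )


class TestGroupAuc:
    def test_perfect_separation(self):
        auc, p = group_auc([1, 2, 3, 4], [0, 0, 1, 1])
        assert auc == 1.0
        assert p < 0.25

    def test_identical_distributions(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=400)
        labels = np.repeat([0, 1], 200)
        auc, _ = group_auc(x, labels)
        assert auc == pytest.approx(0.5, abs=0.08)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            group_auc([1, 2, 3], [1, 1, 1])


class TestScoreSamples:
    def test_full_scores_table(self, param_table):
        rng = np.random.default_rng(21)
        samples = [f"s{i}" for i in range(6)]
        tnscs = rng.uniform(200, 1800, 6)
        matrix = pd.DataFrame(
            {
                s: first_order_beta(
                    param_table["delta"].to_numpy(),
                    param_table["beta0"].to_numpy(),
                    t,
                )
                for s, t in zip(samples, tnscs)
            },
            index=param_table.index,
        )
        ages = pd.Series(rng.uniform(20, 90, 6), index=samples)
        hypo_probes = list(param_table.index)
        table = score_samples(
            matrix,
            ages,
            kinetic_params=param_table,
            pcgt_probes=list(param_table.index),
            hypo_probes=hypo_probes,
        )
        assert list(table.index) == samples
        assert table["tnsc"].to_numpy() == pytest.approx(tnscs, abs=1e-6)
        assert table["rate"].to_numpy() == pytest.approx(
            tnscs / ages.to_numpy(), abs=1e-6
        )
        assert set(table.columns) >= {
            "tnsc",
            "rate",
            "pcgt_age",
            "hypo_score",
            "hypo_age_adj",
            "hypo_rescaled",
        }

    def test_extrinsic_factor_derived_from_cohort_rate(self, param_table):
        samples = ["s1", "s2"]
        matrix = pd.DataFrame(
            {
                s: first_order_beta(
                    param_table["delta"].to_numpy(),
                    param_table["beta0"].to_numpy(),
                    t,
                )
                for s, t in zip(samples, (700.0, 1400.0))
            },
            index=param_table.index,
        )
        ages = pd.Series([20.0, 20.0], index=samples)
        table = score_samples(
            matrix, ages, kinetic_params=param_table, cohort_ir=35.0
        )
        # R = 35 and 70 -> ER = 0 and 1
        assert table["extrinsic_factor"].to_numpy() == pytest.approx(
            [0.0, 1.0], abs=1e-6
        )
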
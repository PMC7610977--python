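import numpy as np
import pandas as pd
import pytest

from myoprop.stats import (
    PairingError,
    bonferroni_threshold,
    exclude_non_learners,
    fit_exponential,
    learning_curves,
    paired_block_tests,
    resampled_vfpf_tests,
)


def make_dataset(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "subject",
            "trial_index",
            "block",
            "phase",
            "condition",
            "target_index",
            "mismatch",
        ],
    )


def uniform_subject_rows(subject, mismatch, n_trials=240):
    """One subject with constant mismatch; Experiment-2-like layout."""
    rows = []
    conditions = ["VF+PF"] * 3 + ["PF", "VF", "noFB"]
    for k in range(1, n_trials + 1):
        block = (k - 1) // 24 + 1
        condition = "VF" if k <= 120 else conditions[k % 6]
        rows.append(
            dict(
                subject=subject,
                trial_index=k,
                block=block,
                phase="familiarization" if k <= 120 else "test",
                condition=condition,
                target_index=k % 4,
                mismatch=mismatch,
            )
        )
    return rows


def paired_design(
    rng,
    n_subjects=19,
    n_blocks=5,
    first_block=6,
    shift=0.0,
    sd=0.1,
    conditions=("PF", "noFB"),
    base=0.5,
):
    """Balanced two-condition test-phase dataset with one trial per
    (subject, target, block, condition)."""
    rows = []
    k = 0
    for b in range(first_block, first_block + n_blocks):
        for s in range(n_subjects):
            for t in range(4):
                common = rng.normal(base, 0.1)
                for cond, delta in zip(conditions, (shift, 0.0)):
                    k += 1
                    rows.append(
                        dict(
                            subject=s,
                            trial_index=k,
                            block=b,
                            phase="test",
                            condition=cond,
                            target_index=t,
                            mismatch=common + delta + rng.normal(0.0, sd),
                        )
                    )
    return make_dataset(rows)


class TestExclusion:
    @pytest.mark.parametrize(
        "mismatch, excluded",
        [(0.9, True), (0.5, False), (0.8, False)],  # strictly greater than 0.8
    )
    def test_threshold_is_strict(self, mismatch, excluded):
        df = make_dataset(uniform_subject_rows(0, mismatch))
        retained, exclusion = exclude_non_learners(df)
        assert exclusion.flags[0] == excluded
        assert retained.empty == excluded

    def test_only_visual_conditions_and_trials_121_240_count(self):
        rows = uniform_subject_rows(0, 0.2)
        df = make_dataset(rows)
        # huge mismatch outside the window and in non-visual conditions
        outside = ~(
            df["trial_index"].between(121, 240)
            & df["condition"].isin(["VF+PF", "VF"])
        )
        df.loc[outside, "mismatch"] = 5.0
        _, exclusion = exclude_non_learners(df)
        assert not exclusion.flags[0]
        assert exclusion.criterion[0] == pytest.approx(0.2)

    def test_idempotent(self):
        df = make_dataset(
            uniform_subject_rows(0, 0.9) + uniform_subject_rows(1, 0.3)
        )
        retained, first = exclude_non_learners(df)
        again, second = exclude_non_learners(retained)
        assert first.excluded_subjects == [0]
        assert second.excluded_subjects == []
        assert len(again) == len(retained)

    def test_subject_without_window_trials_rejected(self):
        df = make_dataset(uniform_subject_rows(0, 0.5))
        with pytest.raises(ValueError):
            exclude_non_learners(df[df["trial_index"] <= 100])


class TestLearningCurves:
    def test_constant_subject(self):
        df = make_dataset(uniform_subject_rows(0, 0.4))
        curves = learning_curves(df)
        assert np.allclose(curves["mean"], 0.4)
        assert np.allclose(curves["sem"], 0.0)

    def test_two_subjects_pool(self):
        df = make_dataset(
            uniform_subject_rows(0, 0.2) + uniform_subject_rows(1, 0.6)
        )
        curves = learning_curves(df)
        assert np.allclose(curves["mean"], 0.4)

    def test_exp1_block_structure(self, exp1_cohort):
        curves = learning_curves(exp1_cohort)
        vfpf_blocks = curves.loc[curves["condition"] == "VF+PF", "block"]
        assert vfpf_blocks.min() == 1 and vfpf_blocks.max() == 20
        for cond in ("PF", "VF", "noFB"):
            blocks = curves.loc[curves["condition"] == cond, "block"]
            assert blocks.min() == 6 and blocks.max() == 20


class TestFitExponential:
    def test_parameter_recovery(self):
        """a=0.3, b=0.5, tau=4 blocks, noise sd 0.01: recovered within 10%."""
        rng = np.random.default_rng(0)
        blocks = np.arange(1, 16)
        for _ in range(10):
            y = 0.3 + 0.5 * np.exp(-(blocks - 1) / 4.0) + rng.normal(0, 0.01, 15)
            fit = fit_exponential(pd.DataFrame({"block": blocks, "mean": y}))
            assert fit.success and fit.p_value < 0.05
            assert fit.params["a"] == pytest.approx(0.3, abs=0.03)
            assert fit.params["b"] == pytest.approx(0.5, rel=0.1)
            assert fit.params["tau"] == pytest.approx(4.0, rel=0.1)

    def test_constant_data_not_significant(self):
        rng = np.random.default_rng(1)
        blocks = np.arange(1, 16)
        y = 0.4 + rng.normal(0, 0.01, 15)
        fit = fit_exponential(pd.DataFrame({"block": blocks, "mean": y}))
        assert fit.p_value > 0.05
        # the fitted curve carries no real decay: it is flat over the range
        assert np.ptp(fit.predict(blocks)) < 0.05

    def test_double_exponential_improves_on_two_time_scales(self):
        blocks = np.arange(1, 21)
        y = 0.2 + 0.6 * np.exp(-(blocks - 1) / 1.0) + 0.3 * np.exp(-(blocks - 1) / 12.0)
        df = pd.DataFrame({"block": blocks, "mean": y})
        single = fit_exponential(df, form="single")
        double = fit_exponential(df, form="double")
        assert double.r2 > single.r2
        assert double.params["tau1"] < double.params["tau2"]

    def test_too_few_blocks_rejected(self):
        df = pd.DataFrame({"block": [1, 2, 3], "mean": [1.0, 0.5, 0.3]})
        with pytest.raises(ValueError):
            fit_exponential(df)

    def test_prediction_matches_fitted_curve(self):
        blocks = np.arange(6, 21)
        y = 0.3 + 0.5 * np.exp(-(blocks - 6) / 4.0)
        fit = fit_exponential(pd.DataFrame({"block": blocks, "mean": y}))
        np.testing.assert_allclose(fit.predict(blocks), y, atol=1e-6)


class TestBonferroni:
    def test_exp1_family_threshold_prints_0_0033(self):
        threshold = bonferroni_threshold(15)
        assert f"{threshold:.2g}" == "0.0033"

    def test_invalid_family(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)


class TestPairedBlockTests:
    def test_identical_conditions_give_null_result(self, rng):
        df = paired_design(rng, shift=0.0, sd=0.0)
        results = paired_block_tests(df, "PF", "noFB")
        for r in results:
            assert r.t == 0.0 and r.p == 1.0 and not r.significant

    def test_threshold_follows_block_family(self, rng):
        df = paired_design(rng, n_blocks=15)
        results = paired_block_tests(df, "PF", "noFB")
        assert len(results) == 15
        assert results[0].threshold == pytest.approx(0.05 / 15)

    def test_strong_shift_significant_everywhere(self, rng):
        """Shift 0.3, sd 0.1, 76 pairs per block: power ~ 1."""
        df = paired_design(rng, shift=0.3, sd=0.1)
        results = paired_block_tests(df, "PF", "noFB")
        assert all(r.significant for r in results)
        assert all(r.n_pairs == 76 for r in results)
        assert all(r.mean_difference > 0.2 for r in results)

    def test_unpaired_trial_is_an_error_naming_the_key(self, rng):
        df = paired_design(rng)
        df = df.drop(df[(df["condition"] == "PF")].index[:1])
        with pytest.raises(PairingError, match="subject 0"):
            paired_block_tests(df, "PF", "noFB")

    def test_nonnormal_differences_warn_but_report(self, rng):
        df = paired_design(rng, shift=0.0, sd=0.05)
        # inject heavy-tailed differences in one block
        sel = (df["block"] == 6) & (df["condition"] == "PF")
        outliers = np.zeros(sel.sum())
        outliers[::7] = 3.0
        df.loc[sel, "mismatch"] += outliers
        with pytest.warns(UserWarning, match="Shapiro"):
            results = paired_block_tests(df, "PF", "noFB")
        assert len(results) == 5


class TestResampledVfpfTests:
    def vfpf_design(self, rng, n_subjects=10, n_blocks=5, effect=0.0, spread=0.1):
        rows = []
        k = 0
        for b in range(6, 6 + n_blocks):
            for s in range(n_subjects):
                for t in range(4):
                    base = rng.normal(0.5, 0.1)
                    for _ in range(3):
                        k += 1
                        rows.append(
                            dict(subject=s, trial_index=k, block=b, phase="test",
                                 condition="VF+PF", target_index=t,
                                 mismatch=base + effect + rng.normal(0, spread))
                        )
                    k += 1
                    rows.append(
                        dict(subject=s, trial_index=k, block=b, phase="test",
                             condition="VF", target_index=t,
                             mismatch=base + rng.normal(0, spread))
                    )
        return make_dataset(rows)

    def test_degenerate_identical_triples_collapse(self, rng):
        df = self.vfpf_design(rng, spread=0.0)
        res = resampled_vfpf_tests(df, "VF", "mismatch", n_resamples=50, seed=0)
        assert np.allclose(res.p_values, res.p_values[0])

    def test_seeded_run_reproducible(self, rng):
        df = self.vfpf_design(rng)
        a = resampled_vfpf_tests(df, "VF", "mismatch", n_resamples=100, seed=5)
        b = resampled_vfpf_tests(df, "VF", "mismatch", n_resamples=100, seed=5)
        np.testing.assert_array_equal(a.p_values, b.p_values)

    def test_real_effect_detected(self, rng):
        df = self.vfpf_design(rng, effect=0.2)
        res = resampled_vfpf_tests(df, "VF", "mismatch", n_resamples=100, seed=0)
        assert res.n_pairs == 200
        assert res.median_p < 1e-6
        assert res.fraction_below(0.01) == 1.0

    def test_wrong_multiplicity_rejected(self, rng):
        df = self.vfpf_design(rng)
        df = df.drop(df[df["condition"] == "VF+PF"].index[:1])
        with pytest.raises(PairingError):
            resampled_vfpf_tests(df, "VF", "mismatch", n_resamples=10, seed=0)
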
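"""Coefficient summaries, mean-difference tests, outlier and stubborn detection."""

import numpy as np
import pandas as pd
import pytest

from innodiff.sessions import Behavior, default_settings, initialize_session, records_to_frame, simulate_setting
from innodiff.stats import (
    detect_outliers,
    detect_stubborn,
    linear_decay_fit,
    mean_difference_test,
    summarize_coefficients,
)


def _fits(values_by_setting):
    rows = []
    for setting, vals in values_by_setting.items():
        for i, v in enumerate(vals):
            rows.append({"session": f"S{i}", "setting": setting, "c": v})
    return pd.DataFrame(rows)


class TestSummary:
    def test_mean_and_sample_sd(self):
        s = summarize_coefficients(_fits({"II": [0.5, 0.7]}))
        assert s.mean["II"] == pytest.approx(0.6)
        assert s.sd["II"] == pytest.approx(np.sqrt(0.02), abs=1e-12)

    def test_identical_values_have_zero_sd(self):
        s = summarize_coefficients(_fits({"III": [0.4, 0.4, 0.4]}))
        assert s.sd["III"] == 0.0

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            summarize_coefficients(_fits({"II": [0.5]}))

    def test_model_string_orders_circles(self):
        s = summarize_coefficients(_fits({"II": [0.6, 0.7], "III": [0.3, 0.45]}))
        assert s.model_string().index("L2") < s.model_string().index("L3")


class TestMeanDifference:
    def test_identical_samples_give_p_one(self):
        assert mean_difference_test([1.0, 1.0, 1.0], [1.0, 1.0]) == 1.0

    def test_separated_samples_give_tiny_p(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 1000), rng.normal(1, 1, 1000)
        assert mean_difference_test(a, b) < 1e-6

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            mean_difference_test([1.0], [1.0, 2.0])

    def test_welch_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 12), rng.normal(0.4, 1, 12)
        p_w = mean_difference_test(a, b)
        p_perm = mean_difference_test(a, b, method="permutation", n_perm=20_000, seed=1)
        assert p_w == pytest.approx(p_perm, abs=0.03)

    def test_null_type_one_error_is_calibrated(self):
        """Fraction of p < 0.05 under the null ≈ 0.05 (study sample size)."""
        rng = np.random.default_rng(7)
        n_rep, n = 2000, 21
        a = rng.normal(size=(n_rep, n))
        b = rng.normal(size=(n_rep, n))
        from scipy.stats import ttest_ind

        p = ttest_ind(a, b, axis=1, equal_var=False).pvalue
        assert np.mean(p < 0.05) == pytest.approx(0.05, abs=0.02)


class TestOutliers:
    # n=5 caps |z| at √4 = 2.0, so the z-score test needs the sixth value
    VALUES = {"a": 1.0, "b": 1.1, "c": 0.9, "d": 1.0, "e": 10.0}
    VALUES6 = {"a": 1.0, "b": 1.1, "c": 0.9, "d": 1.0, "f": 0.95, "e": 10.0}

    @pytest.mark.parametrize("method", ["tukey", "mean_regression"])
    def test_gross_outlier_flagged(self, method):
        assert detect_outliers(self.VALUES, method).flagged == ["e"]

    @pytest.mark.parametrize("method", ["zscore", "tukey", "mean_regression"])
    def test_gross_outlier_flagged_by_all_methods(self, method):
        assert detect_outliers(self.VALUES6, method).flagged == ["e"]

    @pytest.mark.parametrize("method", ["zscore", "tukey", "mean_regression"])
    def test_tight_sample_unflagged(self, method):
        values = {k: v for k, v in zip("abcde", [1.0, 1.02, 0.98, 1.01, 0.99])}
        assert detect_outliers(values, method).flagged == []

    def test_mr_score_zero_when_value_equals_others_mean(self):
        values = {"a": 1.0, "b": 3.0, "c": 2.0, "d": 2.0}  # d == mean(a,b,c)
        rep = detect_outliers(values, "mean_regression")
        assert rep.scores["d"] == pytest.approx(0.0)

    @pytest.mark.parametrize("method", ["zscore", "tukey"])
    def test_location_scale_equivariance(self, method):
        base = dict(zip("abcdef", [1.0, 1.2, 0.8, 1.1, 0.9, 4.0]))
        shifted = {k: 3.0 * v - 7.0 for k, v in base.items()}
        assert detect_outliers(base, method).flagged == detect_outliers(shifted, method).flagged

    def test_order_invariance(self):
        rev = dict(reversed(self.VALUES6.items()))
        assert set(detect_outliers(rev, "zscore").flagged) == {"e"}

    def test_constant_values_warn(self):
        with pytest.warns(UserWarning):
            rep = detect_outliers(dict.fromkeys("abcd", 2.0), "zscore")
        assert rep.flagged == []

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            detect_outliers({"a": 1.0, "b": 2.0}, "zscore")


class TestStubborn:
    def _session_records(self, net31, dist31, stubborn_nodes, seed=5):
        init = initialize_session(net31, 4, seed)
        for s in stubborn_nodes:
            assert init[list(net31.nodes).index(s)] == 0
        res = simulate_setting(
            net31, default_settings()[1], init, seed + 100,
            behavior=Behavior(theta=-5.0),
            roles={s: "stubborn" for s in stubborn_nodes}, dist=dist31,
        )
        return records_to_frame(res.records)

    def test_planted_stubborn_recovered_exactly(self, net31, dist31):
        init = initialize_session(net31, 4, 5)
        planted = [int(net31.nodes[i]) for i in np.flatnonzero(init == 0)[:2]]
        df = self._session_records(net31, dist31, planted)
        assert detect_stubborn(df) == sorted(planted)

    def test_full_consensus_flags_no_one(self, net31, dist31):
        df = self._session_records(net31, dist31, [])
        assert detect_stubborn(df) == []

    def test_no_consensus_means_no_defectors(self):
        # 50/50 split in the final rounds: no group consensus to defect from
        rows = [
            {"session_id": "S", "setting": "II", "round": r, "node": n, "role": "human",
             "chosen_color": n % 2, "displayed_direct": "", "displayed_distant": "", "active": 1}
            for r in (1, 2, 3) for n in range(10)
        ]
        assert detect_stubborn(pd.DataFrame(rows)) == []

    def test_bot_seats_not_flagged_by_default(self, net31, dist31):
        init = initialize_session(net31, 4, 5)
        bot = int(net31.nodes[np.flatnonzero(init == 0)[0]])
        res = simulate_setting(
            net31, default_settings()[1], init, 105,
            behavior=Behavior(theta=-5.0), roles={bot: "stubborn"}, dist=dist31,
        )
        df = records_to_frame(res.records)
        df.loc[df["node"] == bot, "role"] = "bot"  # relabel the defecting seat
        assert bot not in detect_stubborn(df)
        assert bot in detect_stubborn(df, include_bots=True)


class TestLinearDecay:
    def test_exact_linear_means_recover_the_linear_law(self):
        s = summarize_coefficients(_fits({"II": [2 / 3, 2 / 3], "III": [1 / 3, 1 / 3]}))
        slope, intercept = linear_decay_fit(s)
        assert slope == pytest.approx(-1 / 3)
        assert intercept == pytest.approx(4 / 3)

    def test_constant_means_give_flat_line(self):
        s = summarize_coefficients(_fits({"II": [1.0, 1.0], "III": [1.0, 1.0], "IV": [1.0, 1.0]}))
        slope, _ = linear_decay_fit(s)
        assert slope == pytest.approx(0.0)

    def test_study_style_means(self):
        s = summarize_coefficients(_fits({"II": [0.651, 0.651], "III": [0.373, 0.373]}))
        slope, _ = linear_decay_fit(s)
        assert slope == pytest.approx(-0.3135, abs=1e-4)
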
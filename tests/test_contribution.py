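"""Relative-contribution statistics against hand-computed oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from visitrisk.contribution import (
    ContributionConfig,
    adjust,
    analyze_contributions,
    build_fc_table,
    ci_low_from_symmetry,
    compute_fc,
    confidence_interval,
    fc_for_sample,
    p_value,
    relative_contribution,
    round_sig,
    significance_filter,
    variance_ln_rc,
)
from visitrisk.encoding import EncodedSample
from visitrisk.models import ModelConfig, SequenceClassifier


def sample(visits, label=0, pid="P0"):
    return EncodedSample(pid, "2015-06-01", label, visits)


@pytest.fixture(scope="module")
def random_model():
    cfg = ModelConfig(embed_dim=6, hidden_size=5, num_layers=2, input_size=12,
                      dropout=0.0, seed=3)
    return SequenceClassifier(cfg)


class TestComputeFc:
    def test_double_occurrence_equals_sum_of_single_removal_deltas(self, random_model):
        s = sample([(9, [1, 2]), (4, [2, 5]), (1, [3])])
        fc = compute_fc(random_model, s, feature=2, fc_scale="logit")

        def lg(x):
            p = random_model.predict([x])[0]
            return math.log(p / (1 - p))

        base = lg(s)
        v1 = sample([(9, [1]), (4, [2, 5]), (1, [3])])
        v2 = sample([(9, [1, 2]), (4, [5]), (1, [3])])
        assert fc == pytest.approx((base - lg(v1)) + (base - lg(v2)), abs=1e-9)

    def test_removal_that_empties_a_visit_drops_it(self, random_model):
        s = sample([(9, [7]), (4, [1, 2])])
        fc = compute_fc(random_model, s, feature=7, fc_scale="probability")
        shorter = sample([(4, [1, 2])])
        base = random_model.predict([s])[0]
        assert fc == pytest.approx(base - random_model.predict([shorter])[0], abs=1e-12)

    def test_feature_with_zeroed_embedding_contributes_nothing(self, random_model):
        random_model.params["E"][8] = 0.0
        s = sample([(9, [8, 2]), (4, [3])])
        assert compute_fc(random_model, s, feature=8) == pytest.approx(0.0, abs=1e-12)

    def test_absent_feature_raises(self, random_model):
        with pytest.raises(ValueError, match="does not occur"):
            compute_fc(random_model, sample([(3, [1])]), feature=9)

    def test_batched_path_agrees_with_single_feature_path(self, random_model):
        s = sample([(9, [1, 2, 3]), (4, [2])])
        batched = fc_for_sample(random_model, s, {1, 2, 3}, "logit")
        for feat, fc in batched.items():
            assert fc == pytest.approx(compute_fc(random_model, s, feat, "logit"), abs=1e-9)


class TestRelativeContribution:
    def test_simple_ratio(self):
        assert relative_contribution(np.array([2.0, 2.0]), np.array([1.0, 1.0])) == 2.0

    def test_identical_distributions_give_one(self):
        fc = np.array([0.5, 1.5, 1.0])
        assert relative_contribution(fc, fc) == 1.0

    def test_negative_means_of_matching_sign_are_valid(self):
        rc = relative_contribution(np.array([-1.0, -1.0]), np.array([-2.0, -2.0]))
        assert rc == 0.5

    def test_opposite_sign_means_raise(self):
        with pytest.raises(ValueError, match="matching sign"):
            relative_contribution(np.array([1.0, 1.0]), np.array([-1.0, -1.0]))

    def test_matches_formula_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = rng.gamma(2.0, 1.0, size=rng.integers(2, 20))
            b = rng.gamma(2.0, 1.0, size=rng.integers(2, 20))
            assert relative_contribution(a, b) == pytest.approx(
                (a.sum() / len(a)) / (b.sum() / len(b)), rel=1e-12)


class TestVarianceLnRc:
    def test_hand_arithmetic_example(self):
        # events {1,3}: mean 2, sd sqrt2 -> (sd/mean)^2/m = 0.5/2 = 0.25
        var = variance_ln_rc(np.array([1.0, 3.0]), np.array([2.0, 2.0]))
        assert var == pytest.approx(0.25, abs=1e-12)

    def test_constant_groups_give_zero(self):
        assert variance_ln_rc(np.array([2.0, 2.0]), np.array([3.0, 3.0])) == 0.0

    def test_replication_strictly_shrinks_variance(self):
        a = np.array([1.0, 2.0, 4.0])
        b = np.array([1.0, 3.0])
        prev = variance_ln_rc(a, b)
        for k in (2, 4, 8):
            cur = variance_ln_rc(np.tile(a, k), np.tile(b, k))
            assert cur < prev
            prev = cur

    def test_single_member_group_raises(self):
        with pytest.raises(ValueError):
            variance_ln_rc(np.array([1.0]), np.array([1.0, 2.0]))


class TestConfidenceInterval:
    def test_zero_variance_collapses_to_point(self):
        assert confidence_interval(1.7, 0.0) == (1.7, 1.7)

    def test_printed_row_reconstruction(self):
        assert round_sig(ci_low_from_symmetry(1.96, 2.31), 3) == 1.66
        assert round_sig(ci_low_from_symmetry(3.84, 5.77), 3) == 2.56

    @given(st.floats(0.05, 20.0), st.floats(0.0, 2.0))
    @settings(deadline=None, max_examples=200)
    def test_log_symmetry_low_times_high_equals_rc_squared(self, rc, var):
        lo, hi = confidence_interval(rc, var)
        assert lo * hi == pytest.approx(rc * rc, rel=1e-9)
        assert lo <= rc * (1 + 1e-12) and rc <= hi * (1 + 1e-12)


class TestPValue:
    def test_rc_one_gives_p_one(self):
        assert p_value(1.0, 0.5) == pytest.approx(1.0)

    def test_z_of_1_96_gives_p_near_0_05(self):
        var = 0.3
        rc = math.exp(1.96 * math.sqrt(var))
        assert p_value(rc, var) == pytest.approx(0.05, abs=1e-3)

    def test_degenerate_zero_variance(self):
        assert p_value(1.0, 0.0) == 1.0
        assert p_value(2.0, 0.0) == 0.0

    def test_matches_quadrature_oracle(self):
        rng = np.random.default_rng(11)
        pdf = lambda x: math.exp(-x * x / 2) / math.sqrt(2 * math.pi)
        for _ in range(100):
            rc = float(rng.uniform(0.2, 5.0))
            var = float(rng.uniform(0.01, 1.0))
            z = abs(math.log(rc)) / math.sqrt(var)
            tail, _err = quad(pdf, z, np.inf)
            assert p_value(rc, var) == pytest.approx(2 * tail, rel=1e-8, abs=1e-12)


class TestAdjust:
    def test_single_p(self):
        bonf, q = adjust([0.01])
        assert bonf.tolist() == [0.01]
        assert q.tolist() == [0.01]

    def test_hand_bh_step_up(self):
        bonf, q = adjust([0.01, 0.02, 0.03])
        assert np.allclose(bonf, [0.03, 0.06, 0.09])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_all_ones_stay_one(self):
        bonf, q = adjust([1.0, 1.0])
        assert bonf.tolist() == [1.0, 1.0]
        assert q.tolist() == [1.0, 1.0]

    def test_empty_input(self):
        bonf, q = adjust([])
        assert len(bonf) == 0 and len(q) == 0

    def test_bh_matches_step_up_oracle_on_random_p(self):
        rng = np.random.default_rng(5)
        p = rng.random(40)
        _, q = adjust(p)
        # independent BH step-up: q_(i) = min_{j>=i} N p_(j) / j
        order = np.argsort(p)
        n = len(p)
        ranked = p[order]
        oracle = np.minimum.accumulate((n * ranked / np.arange(1, n + 1))[::-1])[::-1]
        oracle = np.minimum(oracle, 1.0)
        assert np.allclose(q[order], oracle)


class TestSixPatientOracle:
    """Full statistic chain against a spreadsheet-style hand computation."""

    EVENT_FC = [2.0, 3.0, 4.0]
    NOEVENT_FC = [1.0, 1.5, 2.0]

    def test_pipeline_matches_hand_computation_to_1e12(self):
        fc1 = np.array(self.EVENT_FC)
        fc0 = np.array(self.NOEVENT_FC)
        rc = relative_contribution(fc1, fc0)
        var = variance_ln_rc(fc1, fc0)
        lo, hi = confidence_interval(rc, var)
        p = p_value(rc, var)

        # hand arithmetic, written out independently of the implementation
        m1 = (2.0 + 3.0 + 4.0) / 3.0
        m0 = (1.0 + 1.5 + 2.0) / 3.0
        hand_rc = m1 / m0
        sd1 = math.sqrt(((2 - m1) ** 2 + (3 - m1) ** 2 + (4 - m1) ** 2) / 2)
        sd0 = math.sqrt(((1 - m0) ** 2 + (1.5 - m0) ** 2 + (2 - m0) ** 2) / 2)
        hand_var = (sd1 / m1) ** 2 / 3 + (sd0 / m0) ** 2 / 3
        hand_lo = math.exp(math.log(hand_rc) - 1.96 * math.sqrt(hand_var))
        hand_hi = math.exp(math.log(hand_rc) + 1.96 * math.sqrt(hand_var))
        hand_z = math.log(hand_rc) / math.sqrt(hand_var)
        hand_p = math.erfc(abs(hand_z) / math.sqrt(2))

        assert rc == pytest.approx(hand_rc, abs=1e-12)
        assert var == pytest.approx(hand_var, abs=1e-12)
        assert lo == pytest.approx(hand_lo, abs=1e-12)
        assert hi == pytest.approx(hand_hi, abs=1e-12)
        assert p == pytest.approx(hand_p, abs=1e-12)


class TestScaleEquivariance:
    @given(st.floats(1e-3, 1e3))
    @settings(deadline=None, max_examples=50)
    def test_statistics_invariant_to_positive_scaling(self, c):
        fc1 = np.array([1.0, 2.5, 3.0, 4.0])
        fc0 = np.array([0.5, 1.0, 2.0])
        rc0 = relative_contribution(fc1, fc0)
        var0 = variance_ln_rc(fc1, fc0)
        rc1 = relative_contribution(c * fc1, c * fc0)
        var1 = variance_ln_rc(c * fc1, c * fc0)
        assert rc1 == pytest.approx(rc0, rel=1e-9)
        assert var1 == pytest.approx(var0, rel=1e-9)
        assert p_value(rc1, var1) == pytest.approx(p_value(rc0, var0), rel=1e-6)


def fc_frame(rows):
    return pd.DataFrame(rows, columns=["feature", "patient_id", "event", "fc"])


class TestAnalyze:
    def _table(self, m=12, n=12, shift=1.0, feature=1, start=0):
        rng = np.random.default_rng(13)
        rows = []
        for i in range(m):
            rows.append((feature, f"C{start+i}", 1, shift * (1 + 0.1 * rng.random())))
        for i in range(n):
            rows.append((feature, f"N{start+i}", 0, 1 + 0.1 * rng.random()))
        return rows

    def test_insufficient_carrier_support_is_excluded_with_reason(self):
        rows = self._table(m=5, n=20)
        results, excl = analyze_contributions(fc_frame(rows), ContributionConfig())
        assert len(results) == 0
        assert excl.iloc[0]["reason"] == "insufficient-support"

    def test_opposite_sign_means_excluded_as_sign_invalid(self):
        rows = [(1, f"C{i}", 1, 1.0) for i in range(12)]
        rows += [(1, f"N{i}", 0, -1.0) for i in range(12)]
        results, excl = analyze_contributions(fc_frame(rows), ContributionConfig())
        assert excl.iloc[0]["reason"] == "sign-invalid"

    def test_bonferroni_n_is_number_of_tested_features(self):
        rows = self._table(feature=1, shift=2.0) + self._table(feature=2, shift=0.5, start=50) \
            + self._table(feature=3, shift=1.0, start=100)
        results, _ = analyze_contributions(fc_frame(rows), ContributionConfig())
        assert len(results) == 3
        assert np.allclose(results["p_bonferroni"],
                           np.minimum(results["p_raw"] * 3, 1.0))

    def test_zero_rows_count_toward_m_n_but_not_support(self):
        rows = self._table(m=12, n=12)
        rows += [(1, f"Z{i}", 0, 0.0) for i in range(8)]  # non-carrier controls
        results, _ = analyze_contributions(fc_frame(rows), ContributionConfig())
        assert results.iloc[0]["n"] == 20

    def test_empty_table_gives_empty_outputs(self):
        results, excl = analyze_contributions(fc_frame([]), ContributionConfig())
        assert len(results) == 0 and len(excl) == 0


class TestSignificanceFilter:
    def _results(self, rows):
        return pd.DataFrame(rows, columns=["feature", "rc", "ci95_low", "ci95_high",
                                           "p_bonferroni"])

    def test_printed_risk_row_kept(self):
        df = self._results([("Glucose", 1.45, 1.38, 1.51, 7.35e-51)])
        out = significance_filter(df)
        assert len(out) == 1 and out.iloc[0]["rc"] > 1

    def test_printed_protective_row_kept(self):
        df = self._results([("IonizedCalcium", 0.498, 0.415, 0.598, 7.47e-10)])
        out = significance_filter(df)
        assert len(out) == 1 and out.iloc[0]["rc"] < 1

    def test_interval_containing_one_dropped_regardless_of_p(self):
        df = self._results([("X", 1.0, 0.9, 1.1, 1e-300)])
        assert len(significance_filter(df)) == 0

    def test_large_p_dropped(self):
        df = self._results([("X", 2.0, 1.5, 2.7, 0.2)])
        assert len(significance_filter(df)) == 0


class TestBuildFcTable:
    def test_all_mode_zero_fills_non_carriers(self, random_model):
        samples = [
            sample([(3, [1, 2])], 1, "A"),
            sample([(3, [2])], 0, "B"),
        ]
        fc = build_fc_table(random_model, samples, {1, 2},
                            ContributionConfig(group_mode="all"))
        rows_feat1 = fc[fc.feature == 1]
        assert set(rows_feat1.patient_id) == {"A", "B"}
        assert rows_feat1.set_index("patient_id").loc["B", "fc"] == 0.0

    def test_carrier_mode_emits_only_carriers(self, random_model):
        samples = [
            sample([(3, [1, 2])], 1, "A"),
            sample([(3, [2])], 0, "B"),
        ]
        fc = build_fc_table(random_model, samples, {1, 2},
                            ContributionConfig(group_mode="carriers"))
        assert set(fc[fc.feature == 1].patient_id) == {"A"}

    def test_case_patient_uses_sample_closest_to_event(self, random_model):
        early = sample([(3, [1])], 1, "A")
        late = sample([(3, [1, 2])], 1, "A")
        late.index_date = "2015-09-01"
        fc = build_fc_table(random_model, [early, late], {2},
                            ContributionConfig(group_mode="carriers"))
        # feature 2 occurs only in the later (closest-to-event) sample
        assert len(fc[fc.feature == 2]) == 1
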
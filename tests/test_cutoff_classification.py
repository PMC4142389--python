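import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from coexshift.cutoff_classification import (
    ClassCountTable,
    chi2_proportions,
    classify_pairs,
    count_classes,
    ks_asymptotic_pvalue,
    ks_max_deviation,
    survival_value,
)


def make_pair_table(c_normal, c_disease):
    n = len(c_normal)
    return pd.DataFrame({
        "gene_i": [f"A{i:03d}" for i in range(n)],
        "gene_j": [f"B{i:03d}" for i in range(n)],
        "c_normal": c_normal,
        "c_disease": c_disease,
    })


class TestSurvivalValue:
    def test_tie_included_via_geq(self):
        assert survival_value(np.array([0.2, 0.4, 0.6]), 0.4) == pytest.approx(2 / 3)

    def test_boundaries(self):
        s = np.array([0.3, 0.5, 0.9])
        assert survival_value(s, 0.0) == 1.0
        assert survival_value(s, 0.3) == 1.0
        assert survival_value(s, 0.91) == 0.0

    def test_matches_counting_loop(self):
        rng = np.random.default_rng(1)
        sample = rng.uniform(size=50)
        for c in rng.uniform(size=20):
            expected = sum(1 for v in sample if v >= c) / 50
            assert survival_value(sample, c) == pytest.approx(expected)

    def test_non_increasing_in_c(self):
        rng = np.random.default_rng(2)
        sample = rng.uniform(size=30)
        cs = np.sort(rng.uniform(size=15))
        vals = [survival_value(sample, c) for c in cs]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestKSMaxDeviation:
    def test_hand_worked_separation(self):
        res = ks_max_deviation(np.array([0.1, 0.2]), np.array([0.8, 0.9]))
        assert res.D == pytest.approx(1.0)
        assert res.C == pytest.approx(0.8)  # smallest grid value attaining D

    def test_identical_samples_zero_deviation(self):
        x = np.array([0.1, 0.5, 0.5, 0.9])
        res = ks_max_deviation(x, x.copy())
        assert res.D == 0.0
        assert res.p_value == 1.0

    def test_d_at_stored_c_and_c_in_grid(self):
        rng = np.random.default_rng(3)
        a, b = rng.beta(2, 5, 80), rng.beta(5, 2, 70)
        res = ks_max_deviation(a, b)
        assert res.C in res.grid
        dev = abs(survival_value(a, res.C) - survival_value(b, res.C))
        assert dev == pytest.approx(res.D, abs=1e-14)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_equals_reference_ks_statistic(self, seed):
        """The survival-grid maximum equals the classical two-sample KS D."""
        rng = np.random.default_rng(seed)
        n, m = rng.integers(5, 500, size=2)
        a = rng.beta(2, 3, n)
        b = rng.beta(3, 2, m)
        res = ks_max_deviation(a, b)
        assert res.D == pytest.approx(stats.ks_2samp(a, b).statistic, abs=1e-12)

    def test_smallest_tie_reported(self):
        # two grid points attain |F_d - F_n| = 0.5
        res = ks_max_deviation(np.array([0.1, 0.4]), np.array([0.3, 0.6]))
        grid_devs = [(c, abs(survival_value(np.array([0.1, 0.4]), c)
                             - survival_value(np.array([0.3, 0.6]), c)))
                     for c in res.grid]
        winners = [c for c, d in grid_devs if d == pytest.approx(res.D)]
        assert res.C == min(winners)


class TestKSAsymptoticP:
    def test_zero_deviation_gives_one(self):
        assert ks_asymptotic_pvalue(0.0, 50, 60) == 1.0

    def test_full_separation_is_tiny(self):
        assert ks_asymptotic_pvalue(1.0, 100, 100) < 1e-40

    def test_matches_hand_summed_series(self):
        D, n, m = 0.2, 100, 100
        lam = D * math.sqrt(n * m / (n + m))
        expected = 2 * sum((-1) ** (k - 1) * math.exp(-2 * k * k * lam * lam)
                           for k in range(1, 101))
        assert ks_asymptotic_pvalue(D, n, m) == pytest.approx(expected, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ks_asymptotic_pvalue(1.5, 10, 10)
        with pytest.raises(ValueError):
            ks_asymptotic_pvalue(0.5, 0, 10)


class TestClassifyPairs:
    def test_lost_connection_pair_is_normal_specific_strong(self):
        # a pair at |r| = 0.720 in normal vs 0.013 in disease, cutoff 0.440
        t = make_pair_table([0.720], [0.013])
        cls = classify_pairs(t, 0.440)
        row = cls.iloc[0]
        assert row["class_normal"] == "strong" and row["class_disease"] == "weak"
        assert row["normal_specific_strong"] and row["disease_specific_weak"]
        assert not row["disease_specific_strong"] and not row["normal_specific_weak"]

    def test_all_below_cutoff_no_strong(self):
        t = make_pair_table([0.1, 0.2, 0.3], [0.05, 0.1, 0.2])
        cls = classify_pairs(t, 0.5)
        assert (cls["class_normal"] == "weak").all()
        assert (cls["class_disease"] == "weak").all()

    def test_tie_goes_to_strong(self):
        cls = classify_pairs(make_pair_table([0.5], [0.49999]), 0.5)
        assert cls.iloc[0]["class_normal"] == "strong"
        assert cls.iloc[0]["class_disease"] == "weak"

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_flags_match_four_branch_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 60))
        t = make_pair_table(rng.uniform(size=n), rng.uniform(size=n))
        C = float(rng.uniform())
        cls = classify_pairs(t, C)
        for _, row in cls.iterrows():
            sn, sd = row["c_normal"] >= C, row["c_disease"] >= C
            assert row["normal_specific_strong"] == (sn and not sd)
            assert row["disease_specific_strong"] == (sd and not sn)
            assert row["normal_specific_weak"] == row["disease_specific_strong"]
            assert row["disease_specific_weak"] == row["normal_specific_strong"]

    def test_raising_cutoff_never_raises_strong_counts(self):
        rng = np.random.default_rng(8)
        t = make_pair_table(rng.uniform(size=100), rng.uniform(size=100))
        prev_n = prev_d = 10**9
        for C in np.linspace(0, 1, 11):
            counts = count_classes(classify_pairs(t, C))
            assert counts.strong_normal <= prev_n
            assert counts.strong_disease <= prev_d
            prev_n, prev_d = counts.strong_normal, counts.strong_disease


class TestCountClasses:
    def test_all_normal_strong(self):
        t = make_pair_table([0.9, 0.8, 0.95], [0.1, 0.2, 0.15])
        counts = count_classes(classify_pairs(t, 0.5))
        assert counts.to_dict() == {"strong_normal": 3, "weak_normal": 0,
                                    "strong_disease": 0, "weak_disease": 3}

    def test_nothing_reaches_cutoff(self):
        t = make_pair_table([0.1] * 10, [0.2] * 10)
        counts = count_classes(classify_pairs(t, 0.99))
        assert counts.to_dict() == {"strong_normal": 0, "weak_normal": 10,
                                    "strong_disease": 0, "weak_disease": 10}

    def test_matches_tally_loop(self):
        rng = np.random.default_rng(12)
        t = make_pair_table(rng.uniform(size=100), rng.uniform(size=100))
        cls = classify_pairs(t, 0.4)
        counts = count_classes(cls)
        assert counts.strong_normal == sum(v >= 0.4 for v in t["c_normal"])
        assert counts.strong_disease == sum(v >= 0.4 for v in t["c_disease"])
        assert counts.total_pairs == 100


class TestChi2Proportions:
    def test_homogeneous_table_is_null(self):
        chi2, p = chi2_proportions(ClassCountTable(5, 5, 5, 5))
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_closed_form_oracle(self, seed):
        """Pearson statistic equals sum (O-E)^2/E computed cell by cell."""
        rng = np.random.default_rng(seed)
        total = int(rng.integers(20, 2000))
        sn = int(rng.integers(1, total))
        sd = int(rng.integers(1, total))
        t = ClassCountTable(sn, total - sn, sd, total - sd)
        chi2, p = chi2_proportions(t)
        obs = t.as_2x2()
        row = obs.sum(axis=1, keepdims=True)
        col = obs.sum(axis=0, keepdims=True)
        expected_stat = float((((obs - row * col / obs.sum()) ** 2)
                               / (row * col / obs.sum())).sum())
        assert chi2 == pytest.approx(expected_stat, abs=1e-10)
        assert p == pytest.approx(float(stats.chi2.sf(expected_stat, df=1)), rel=1e-10)

    def test_row_swap_invariance(self):
        a = chi2_proportions(ClassCountTable(7436, 16000, 6083, 17353))
        b = chi2_proportions(ClassCountTable(6083, 17353, 7436, 16000))
        assert a == pytest.approx(b)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi2_proportions(ClassCountTable(0, 10, 0, 10))
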
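"""Statistics: exclusivity labels, summary arithmetic, the normality-gated
omnibus test, and rank correlations — all checked against hand/brute-force
oracles."""

import numpy as np
import pandas as pd
import pytest

from pilotcalls.cluster import CallType, Repertoire
from pilotcalls.stats import (StatsConfig, frequency_correlations, gated_group_test,
                              label_exclusivity, summarize_types)


def kruskal_brute(groups):
    """Independent oracle: the rank formula with tie correction,
    H = (12 / (N(N+1))) * sum n_i (Rbar_i - Rbar)^2, corrected by
    1 - sum(t^3 - t)/(N^3 - N)."""
    from scipy.stats import rankdata
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = rankdata(pooled)
    rbar = (n + 1) / 2
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += len(g) * (r.mean() - rbar) ** 2
        start += len(g)
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
    return h / tie


def _repertoire(counts_by_type):
    types = [CallType(lbl, [f"{lbl}_{i}" for i in range(sum(c.values()))], c)
             for lbl, c in counts_by_type.items()]
    n = sum(t.occurrence for t in types)
    return Repertoire(types, n, n)


class TestLabelExclusivity:
    def test_sole_dataset_label(self):
        labels, _ = label_exclusivity(_repertoire({"T1": {"Pavia": 12}}))
        assert labels["T1"] == "Pavia"

    def test_multi_dataset_is_mixed(self):
        labels, _ = label_exclusivity(_repertoire({"T1": {"Pavia": 3, "Sphyrna": 2}}))
        assert labels["T1"] == "mixed"

    def test_sparse_dataset_excluded_from_testing(self):
        rep = _repertoire({"T1": {"A": 5}, "T2": {"A": 4}, "T3": {"B": 3}})
        _, eligible = label_exclusivity(rep, min_group_n=2)
        assert eligible == ["A"]  # B has only one exclusive type


class TestSummarizeTypes:
    def test_two_type_hand_computation(self):
        table = pd.DataFrame({"f_mean_hz": [1000.0, 3000.0], "dur_s": [0.5, 1.0]})
        g = summarize_types(table)["global"]["frequency_hz"]
        assert g["minimum"] == 1000 and g["maximum"] == 3000 and g["mean"] == 2000
        assert g["sd"] == pytest.approx(1414.21, abs=0.01)

    def test_single_type_sd_absent(self):
        table = pd.DataFrame({"f_mean_hz": [1000.0], "dur_s": [0.5]})
        assert summarize_types(table)["global"]["frequency_hz"]["sd"] is None

    def test_empty_repertoire_empty_summary(self):
        table = pd.DataFrame({"f_mean_hz": [], "dur_s": []})
        assert summarize_types(table)["global"]["frequency_hz"] == {}


class TestGatedGroupTest:
    def test_separated_ranks_hand_formula(self):
        """H = 12.5 for three fully rank-separated groups of five."""
        groups = {"a": [1, 2, 3, 4, 5], "b": [10, 20, 30, 40, 50],
                  "c": [100, 200, 300, 400, 500]}
        res = gated_group_test(groups)
        if res.test_name == "Kruskal-Wallis":
            assert res.statistic == pytest.approx(12.5, abs=1e-9)
        arrays = [np.asarray(v, float) for v in groups.values()]
        assert kruskal_brute(arrays) == pytest.approx(12.5, abs=1e-12)

    def test_kruskal_matches_brute_force_on_random_samples(self, rng):
        from scipy.stats import kruskal
        for _ in range(100):
            sizes = rng.integers(4, 12, size=rng.integers(2, 5))
            groups = [np.round(rng.normal(0, 1, s), 1) for s in sizes]  # rounding makes ties
            h_scipy = kruskal(*groups).statistic
            assert kruskal_brute(groups) == pytest.approx(h_scipy, abs=1e-9)

    def test_normal_data_takes_anova_branch(self, rng):
        groups = {g: rng.normal(0, 1, 40) for g in "abc"}
        res = gated_group_test(groups)
        assert res.decision_path == "normal -> ANOVA"
        assert res.test_name == "ANOVA"

    def test_heavy_tailed_data_takes_kruskal_branch(self, rng):
        groups = {g: rng.standard_cauchy(40) for g in "abc"}
        res = gated_group_test(groups)
        assert res.decision_path == "non-normal -> Kruskal-Wallis"

    def test_branch_consistent_with_shapiro(self, rng):
        for _ in range(20):
            groups = {g: rng.exponential(1, 20) if rng.random() < 0.5 else rng.normal(0, 1, 20)
                      for g in "ab"}
            res = gated_group_test(groups)
            normal = res.shapiro_p > 0.05
            assert res.decision_path == ("normal -> ANOVA" if normal
                                         else "non-normal -> Kruskal-Wallis")

    def test_identical_groups_no_posthoc(self):
        res = gated_group_test({"a": [1.0, 2, 3, 4, 5], "b": [1.0, 2, 3, 4, 5]})
        assert res.p_value > 0.9
        assert res.posthoc is None

    def test_posthoc_bonferroni_at_least_raw(self, rng):
        groups = {"a": rng.normal(0, 1, 30), "b": rng.normal(3, 1, 30),
                  "c": rng.normal(6, 1, 30)}
        res = gated_group_test(groups)
        assert res.posthoc is not None
        assert (res.posthoc["p_bonferroni"] >= res.posthoc["p_raw"] - 1e-15).all()
        assert (res.posthoc["p_bonferroni"] <= 1.0).all()
        expected = np.minimum(1.0, res.posthoc["p_raw"] * len(res.posthoc))
        assert np.allclose(res.posthoc["p_bonferroni"], expected)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            gated_group_test({"a": [1.0, 2, 3]})

    def test_null_type_i_error_calibrated(self, rng):
        """Empirical size of the gated test at alpha=0.05 under a
        three-group Gaussian null (simulation oracle)."""
        n_reject = 0
        n_rep = 1000
        for _ in range(n_rep):
            groups = {g: rng.normal(0, 1, 30) for g in "abc"}
            if gated_group_test(groups).p_value <= 0.05:
                n_reject += 1
        assert 0.03 <= n_reject / n_rep <= 0.07


class TestFrequencyCorrelations:
    @staticmethod
    def _table(fmin, fmean, fmax):
        return pd.DataFrame({"f_min_hz": fmin, "f_mean_hz": fmean, "f_max_hz": fmax})

    def test_monotone_pairs_rho_one(self):
        t = self._table([1, 2, 3, 4], [10, 20, 30, 40], [100, 200, 300, 400])
        out = frequency_correlations(t)
        assert all(v[0] == pytest.approx(1.0) for v in out.values())

    def test_reversed_ranks_rho_minus_one(self):
        t = self._table([1, 2, 3, 4], [40, 30, 20, 10], [4, 3, 2, 1])
        assert frequency_correlations(t)[("min", "mean")][0] == pytest.approx(-1.0)

    def test_hand_computed_rho(self):
        """rho = 1 - 6*sum(d^2)/(n(n^2-1)) = 0.6 for y = [3,1,2,5,4]."""
        t = self._table([1, 2, 3, 4, 5], [3, 1, 2, 5, 4], [1, 2, 3, 4, 5])
        assert frequency_correlations(t)[("min", "mean")][0] == pytest.approx(0.6)

    def test_constant_vector_reported_absent(self):
        t = self._table([1.0] * 4, [1, 2, 3, 4], [1, 2, 3, 4])
        assert frequency_correlations(t)[("min", "max")] == (None, None)

    def test_too_few_types_rejected(self):
        with pytest.raises(ValueError, match="3 call types"):
            frequency_correlations(self._table([1, 2], [1, 2], [1, 2]))
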
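"""Regulation metrics, pairwise diff-reg estimator, FDR and permutation."""
from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mirdiffreg import quantify
from mirdiffreg.design import PoolDesign
from mirdiffreg.simulate import SpikeIn, SyntheticConfig, generate_counts
from mirdiffreg.stats import (
    METRIC_LOG2,
    baseline_compare,
    bh_fdr,
    diff_reg_permutation,
    diff_reg_table,
    fold_change_signed,
    log2_ratio,
    pairwise_estimates,
    snl_reg_subtraction,
    snl_reg_test,
    volcano_frame,
)

positive = st.floats(min_value=0.01, max_value=1e6, allow_nan=False)


class TestPointMetrics:
    def test_no_change_is_zero_and_unit_fold(self):
        assert snl_reg_subtraction(7.0, 7.0) == 0.0
        assert fold_change_signed(10.0, 10.0) == 1.0

    def test_subtraction_hand_value(self):
        assert snl_reg_subtraction(30.0, 10.0) == pytest.approx(1.0)

    def test_fold_change_two_fold(self):
        assert fold_change_signed(20.0, 10.0) == pytest.approx(2.0)

    def test_both_zero_undefined(self):
        assert math.isnan(snl_reg_subtraction(0.0, 0.0))
        assert math.isnan(fold_change_signed(0.0, 5.0))

    @given(snl=positive, sham=positive)
    def test_subtraction_bounded_and_antisymmetric(self, snl, sham):
        v = snl_reg_subtraction(snl, sham)
        assert -2.0 < v < 2.0
        assert v == pytest.approx(-snl_reg_subtraction(sham, snl))

    @given(snl=positive, sham=positive)
    def test_sign_agreement_across_metrics(self, snl, sham):
        sub = snl_reg_subtraction(snl, sham)
        fold = fold_change_signed(snl, sham)
        l2 = log2_ratio(snl, sham, floor=1e-12)
        assert np.sign(sub) == np.sign(l2)
        # fold uses +1 for "no change"; compare via fold-1 vs -(1/fold)+1 sign
        if sub > 0:
            assert fold > 1 or fold == pytest.approx(1.0)
        elif sub < 0:
            assert fold < -1 or fold == pytest.approx(-1.0)


class TestBhFdr:
    def test_single_p_unchanged(self):
        q, limit = bh_fdr([0.03])
        assert q[0] == pytest.approx(0.03)
        assert limit == pytest.approx(0.03)

    def test_hand_computed_examples(self):
        q, limit = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
        assert limit == pytest.approx(0.04)
        q2, _ = bh_fdr([0.005, 0.9])
        assert np.allclose(q2, [0.01, 0.9])

    def test_fdr_limit_zero_when_nothing_passes(self):
        _, limit = bh_fdr([0.5, 0.8])
        assert limit == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.5])


class TestPairwiseEstimates:
    def test_hand_enumerated_grid(self):
        est = pairwise_estimates([10, 20], [10, 10])
        assert sorted(est) == pytest.approx([0.0, 0.0, 2 / 3, 2 / 3])
        assert est.mean() == pytest.approx(1 / 3)
        # direct group-mean formula differs under within-group variance
        assert snl_reg_subtraction(15.0, 10.0) == pytest.approx(0.4)

    def test_zero_pairs_dropped(self):
        est = pairwise_estimates([0, 10], [0, 10])
        # the (0,0) pair is invalid; 3 remain
        assert len(est) == 3

    @given(
        snl=positive, sham=positive,
        k=st.integers(min_value=2, max_value=4),
    )
    def test_reduces_to_direct_formula_without_variance(self, snl, sham, k):
        est = pairwise_estimates([snl] * k, [sham] * k)
        assert est.mean() == pytest.approx(snl_reg_subtraction(snl, sham))


def exact_permutation_oracle(a, b):
    """Independent enumeration of all splits of the pooled values."""
    pooled = list(a) + list(b)
    n1 = len(a)
    observed = abs(np.mean(a) - np.mean(b))
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(np.mean(ga) - np.mean(gb)) >= observed - 1e-12:
            hits += 1
    return hits / total


class TestPermutation:
    def test_identical_sets_p_one(self):
        assert diff_reg_permutation([1.0, 1.0], [1.0, 1.0], method="exact") == 1.0

    def test_extreme_separation_exact_example(self):
        # all 20 splits of {0,0,0 | 1,1,1}: only the two extremes reach |1|
        assert diff_reg_permutation([0, 0, 0], [1, 1, 1], method="exact") == pytest.approx(2 / 20)

    def test_matches_oracle_on_3_plus_3(self, rng):
        for _ in range(10):
            a, b = rng.normal(size=3), rng.normal(size=3)
            assert diff_reg_permutation(a, b, method="exact") == pytest.approx(
                exact_permutation_oracle(a, b)
            )

    def test_sampled_mode_is_seed_deterministic(self, rng):
        a, b = rng.normal(size=9), rng.normal(size=9)
        p1 = diff_reg_permutation(a, b, n_runs=2000, seed=5, method="sampled")
        p2 = diff_reg_permutation(a, b, n_runs=2000, seed=5, method="sampled")
        assert p1 == p2


class TestSnlRegTest:
    def test_no_difference_gives_zero_estimate_p_one(self, design, group_mean_matrix):
        m = group_mean_matrix({"e1": {g: 50.0 for g in ["HA_sham", "HA_SNL", "LA_sham", "LA_SNL"]}})
        t = snl_reg_test(m, design, "HA")
        assert t.loc["e1", "snl_reg_subtraction"] == 0.0
        assert t.loc["e1", "p_one_tailed"] == 1.0

    def test_spiked_elements_rank_top(self):
        spikes = tuple(SpikeIn(element=f"el{i:03d}", line="HA", fold=2.0) for i in (1, 2, 3))
        cfg = SyntheticConfig(n_elements=60, cv=0.05, seed=11, spike_ins=spikes,
                              abundance_sdlog=0.3)
        counts, truth = generate_counts(cfg)
        rpm = quantify.to_rpm(counts)
        t = snl_reg_test(rpm, cfg.design, "HA")
        # spiked elements are the strongest *up*-regulated signals; RPM
        # normalization also induces a small compensatory down-shift on the
        # remaining elements, so rank within the up-regulated direction
        up = t[t["snl_reg_subtraction"] > 0].sort_values("p_one_tailed")
        assert set(up.head(3).index) == set(truth.diff_reg_elements)
        assert (t.loc[truth.diff_reg_elements, "q_fdr"] <= 0.05).all()

    def test_zero_variance_unequal_means_is_certain(self, design, group_mean_matrix):
        m = group_mean_matrix(
            {"e1": {"HA_sham": 20.0, "HA_SNL": 10.0, "LA_sham": 5.0, "LA_SNL": 5.0}}
        )
        t = snl_reg_test(m, design, "HA")
        # down-regulation with no replicate noise: one-tailed p in the
        # observed (negative) direction is 0, not 1
        assert t.loc["e1", "p_one_tailed"] == 0.0

    def test_requires_two_pools_per_condition(self, design, group_mean_matrix):
        m = group_mean_matrix({"e1": {g: 5.0 for g in ["HA_sham", "HA_SNL", "LA_sham", "LA_SNL"]}})
        with pytest.raises(ValueError):
            snl_reg_test(m.drop(columns=["HA_SNL1", "HA_SNL2"]), design, "HA")


class TestDiffReg:
    def test_zero_variance_reduces_to_direct_difference(self, design, group_mean_matrix):
        m = group_mean_matrix(
            {"mir30d": {"HA_sham": 9187.0, "HA_SNL": 8140.0,
                        "LA_sham": 11047.0, "LA_SNL": 11168.0}}
        )
        d = diff_reg_table(m, design)
        expected = snl_reg_subtraction(8140, 9187) - snl_reg_subtraction(11168, 11047)
        assert d.loc["mir30d", "diff"] == pytest.approx(expected)

    def test_line_swap_flips_sign(self, design, group_mean_matrix):
        m = group_mean_matrix(
            {"e1": {"HA_sham": 10.0, "HA_SNL": 30.0, "LA_sham": 20.0, "LA_SNL": 18.0}}
        )
        d1 = diff_reg_table(m, design)
        d2 = diff_reg_table(m, PoolDesign(lines=("LA", "HA")))
        assert d1.loc["e1", "diff"] == pytest.approx(-d2.loc["e1", "diff"])

    def test_estimate_count_is_k_times_k(self, design, rng):
        m = pd.DataFrame(
            rng.uniform(10, 100, (3, 12)), columns=design.pools,
            index=["a", "b", "c"],
        )
        d = diff_reg_table(m, design)
        assert (d["n_pairs_HA"] == 9).all()
        assert (d["n_pairs_LA"] == 9).all()

    def test_log2_metric_supported(self, design, group_mean_matrix):
        m = group_mean_matrix(
            {"e1": {"HA_sham": 10.0, "HA_SNL": 40.0, "LA_sham": 10.0, "LA_SNL": 10.0}}
        )
        d = diff_reg_table(m, design, metric=METRIC_LOG2)
        assert d.loc["e1", "diff"] == pytest.approx(2.0)

    def test_permutation_column_present_and_valid(self, design, rng):
        m = pd.DataFrame(rng.uniform(10, 100, (2, 12)), columns=design.pools, index=["a", "b"])
        d = diff_reg_table(m, design, permutation_runs=500, seed=3)
        assert ((d["perm_p"] > 0) & (d["perm_p"] <= 1)).all()

    def test_volcano_pairs_finite(self, design, rng):
        m = pd.DataFrame(rng.uniform(5, 200, (30, 12)), columns=design.pools)
        v = volcano_frame(diff_reg_table(m, design))
        assert np.isfinite(v.to_numpy()).all()


class TestBaselineCompare:
    def test_identical_sham_groups(self, design, group_mean_matrix):
        m = group_mean_matrix({"e1": {g: 25.0 for g in ["HA_sham", "HA_SNL", "LA_sham", "LA_SNL"]}})
        b = baseline_compare(m, design)
        assert b.loc["e1", "ratio"] == pytest.approx(1.0)
        assert b.loc["e1", "p_two_tailed"] == 1.0

    def test_baseline_fold_recovery(self):
        # one element expressed 9.5-fold higher in HA at baseline
        cfg = SyntheticConfig(n_elements=50, cv=0.05, seed=2, abundance_sdlog=0.5)
        counts, _ = generate_counts(cfg)
        rpm = quantify.to_rpm(counts)
        boosted = rpm.copy()
        boosted.loc["el001", ["HA_sham1", "HA_sham2", "HA_sham3"]] *= 9.5
        b = baseline_compare(boosted, cfg.design)
        assert b.loc["el001", "ratio"] == pytest.approx(9.5, rel=0.15)
        assert b["p_two_tailed"].idxmin() == "el001"

    def test_null_mostly_insignificant(self):
        cfg = SyntheticConfig(n_elements=300, cv=0.2, seed=8)
        counts, _ = generate_counts(cfg)
        b = baseline_compare(quantify.to_rpm(counts), cfg.design)
        assert (b["q_fdr"] > 0.05).mean() >= 0.95
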
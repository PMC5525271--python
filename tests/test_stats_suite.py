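"""Tests of the comparative statistics: K-S, Fisher, t-tests, clustering."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from photosrna.stats_suite import (
    ClusterResult,
    cluster_profiles,
    fisher_2x2,
    fold_change_compare,
    ks_two_sample,
    load_reference_clusters,
    ratio_analysis,
    ratio_records_table,
)


def ks_D(a, b):
    """Independent D oracle: max ECDF gap on the pooled support."""
    pooled = sorted(set(a) | set(b))
    return max(
        abs(sum(x <= v for x in a) / len(a) - sum(x <= v for x in b) / len(b))
        for v in pooled
    )


def ks_exact_p_enumeration(a, b):
    """Exact p by enumeration over all label assignments of the pooled
    sample: P(D >= D_obs) under exchangeability."""
    pooled = list(a) + list(b)
    n1 = len(a)
    d_obs = ks_D(a, b)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        aa = [pooled[i] for i in idx]
        bb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if ks_D(aa, bb) >= d_obs - 1e-12:
            hits += 1
    return hits / total


class TestKS:
    def test_identical_samples(self):
        res = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert res.D == 0.0
        assert res.p_value == 1.0

    def test_disjoint_supports(self):
        assert ks_two_sample([1, 2, 3], [4, 5, 6]).D == 1.0

    def test_small_sample_exact_p_matches_enumeration(self):
        a, b = [1.0, 3.0], [2.0, 4.0]
        res = ks_two_sample(a, b)
        assert res.D == pytest.approx(ks_D(a, b))
        assert res.p_value == pytest.approx(ks_exact_p_enumeration(a, b))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    def test_monotone_transform_invariance(self, rng):
        a = rng.normal(size=20)
        b = rng.normal(1, 1, size=15)
        assert ks_two_sample(a, b).D == pytest.approx(
            ks_two_sample(np.exp(a), np.exp(b)).D
        )


def fisher_enumeration(table):
    """Oracle: sum hypergeometric point probabilities <= the observed one
    over all tables with the observed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def point(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = point(a)
    return sum(
        point(x)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
        if point(x) <= p_obs * (1 + 1e-12)
    )


class TestFisher:
    def test_no_association(self):
        assert fisher_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table",
        [[[1, 9], [9, 1]], [[3, 7], [8, 2]], [[0, 10], [5, 5]], [[2, 2], [2, 14]]],
    )
    def test_matches_enumeration_oracle(self, table):
        assert fisher_2x2(table) == pytest.approx(fisher_enumeration(table), rel=1e-9)

    def test_monotone_depletion_family(self):
        # fixed first row [30, 150]; pulling x below its expectation under
        # the margins monotonically strengthens the association
        pvals = [fisher_2x2([[30, 150], [x, 155 - x]]) for x in (26, 20, 14, 8)]
        assert all(a > b for a, b in zip(pvals, pvals[1:]))

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            fisher_2x2([[-1, 2], [3, 4]])
        with pytest.raises(ValueError):
            fisher_2x2([[0, 0], [3, 4]])


class TestFoldChangeCompare:
    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(42)
        rejections = 0
        n_sims = 500
        for _ in range(n_sims):
            ratios = {f"f{i}": float(2.0 ** rng.normal(0, 0.5)) for i in range(40)}
            grouping = {f"f{i}": ("plus" if i < 20 else "minus") for i in range(40)}
            if fold_change_compare(ratios, grouping) < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sims <= 0.07

    def test_power_at_stated_effect(self):
        rng = np.random.default_rng(7)
        ratios = {}
        grouping = {}
        for i in range(50):
            ratios[f"p{i}"] = float(2.0 ** rng.normal(-1.0, 0.5))
            grouping[f"p{i}"] = "plus"
            ratios[f"m{i}"] = float(2.0 ** rng.normal(0.0, 0.5))
            grouping[f"m{i}"] = "minus"
        assert fold_change_compare(ratios, grouping) < 0.01

    def test_single_feature_group_rejected(self):
        with pytest.raises(ValueError):
            fold_change_compare({"a": 1.0, "b": 2.0}, {"a": "plus", "b": "minus"})


class _FakeCall:
    def __init__(self, sid, tid, valid=True):
        class A:
            pass

        self.alignment = A()
        self.alignment.srna_id = sid
        self.alignment.transcript_id = tid
        self.valid = valid


class TestRatioAnalysis:
    def test_low_rpkm_target_excluded(self):
        srna = pd.Series({"s1": 10.0, "s2": 10.0})
        rpkm = pd.Series({"t1": 5.0, "t2": 0.005})
        with pytest.warns(UserWarning):  # losing t2 empties the minus stratum
            records, tests = ratio_analysis(
                srna, rpkm, [_FakeCall("s1", "t1")],
                pairs=[("s1", "t1"), ("s2", "t2")], condition="dark",
            )
        assert [r.target_id for r in records] == ["t1"]

    def test_empty_stratum_warns_and_omits_tests(self):
        srna = pd.Series({"s1": 10.0})
        rpkm = pd.Series({"t1": 5.0})
        with pytest.warns(UserWarning):
            records, tests = ratio_analysis(
                srna, rpkm, [], pairs=[("s1", "t1")], condition="light"
            )
        assert tests == {}

    def test_planted_ratio_shift_detected(self, rng):
        srna, rpkm, calls, pairs = _ratio_cohort(rng, fold=10.0)
        records, tests = ratio_analysis(srna, rpkm, calls, pairs=pairs)
        assert tests["ratio"].p_value < 0.01
        assert tests["target_abundance"].p_value > 0.1
        table = ratio_records_table(records)
        assert set(table["degradome_status"]) == {"plus", "minus"}


def _ratio_cohort(rng, fold=10.0, n_per_group=30):
    """Synthetic determinant-analysis cohort: 'plus' pairs carry ``fold``-x
    the sRNA abundance; target abundance shares one distribution."""
    srna, rpkm, calls, pairs = {}, {}, [], []
    for i in range(2 * n_per_group):
        plus = i < n_per_group
        sid, tid = f"s{i}", f"t{i}"
        srna[sid] = float(rng.lognormal(np.log(10.0) + (np.log(fold) if plus else 0), 0.6))
        rpkm[tid] = float(rng.lognormal(np.log(5.0), 0.6))
        pairs.append((sid, tid))
        if plus:
            calls.append(_FakeCall(sid, tid))
    return pd.Series(srna), pd.Series(rpkm), calls, pairs


class TestClustering:
    def test_two_blobs_perfect_recovery(self, rng):
        X = np.vstack(
            [rng.normal(0, 0.1, size=(20, 6)), rng.normal(5, 0.1, size=(20, 6))]
        )
        df = pd.DataFrame(X, index=[f"f{i}" for i in range(40)])
        result = cluster_profiles(df, k=2, n_restarts=10, seed=0)
        truth = [0] * 20 + [1] * 20
        labels = [result.labels[f"f{i}"] for i in range(40)]
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_identical_features_zero_inertia(self):
        df = pd.DataFrame(np.ones((5, 6)), index=list("abcde"))
        result = cluster_profiles(df, k=3, n_restarts=5, seed=0)
        assert result.inertia == pytest.approx(0.0)
        assert len(set(result.labels.values())) >= 1

    def test_k_exceeding_features_rejected(self):
        df = pd.DataFrame(np.ones((2, 3)))
        with pytest.raises(ValueError):
            cluster_profiles(df, k=5)

    def test_deterministic_given_seed(self):
        df = load_reference_clusters().drop(columns="cluster")
        a = cluster_profiles(df, k=3, n_restarts=20, seed=1)
        b = cluster_profiles(df, k=3, n_restarts=20, seed=1)
        assert a.labels == b.labels
        assert a.inertia == b.inertia


def test_reference_cluster_table_shape():
    df = load_reference_clusters()
    assert df.shape == (66, 7)
    assert (df["W0"] == 0).all()
    assert df.loc["miR163", "cluster"] == "I"
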
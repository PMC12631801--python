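"""Statistical screen: MWU enumeration oracle, BKY two-stage, PCA, clustering."""

import math

import numpy as np
import pandas as pd
import pytest

from orgsig.core import ValidationError
from orgsig.screen import (
    bky_adjust,
    bky_reject,
    hier_cluster,
    log2_fc,
    log2_fc_frame,
    mwu_screen,
    pca_parallel,
    significance_tier,
    spearman_matrix,
)

from conftest import mwu_exact_two_sided


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _table(a, b, name="m"):
    return pd.DataFrame(
        {"group": ["A"] * len(a) + ["B"] * len(b), name: list(a) + list(b)}
    )


def test_mwu_well_separated_small_groups_attain_exact_floor():
    res = mwu_screen(_table([1, 2, 3], [10, 11, 12]), "A", "B")
    row = res.iloc[0]
    assert row["U"] == 0.0
    assert row["p"] == pytest.approx(0.1)  # smallest attainable two-sided p at n=3,3
    assert row["mean_rank_diff"] == pytest.approx(2.0 - 5.0)


@pytest.mark.parametrize("seed", range(8))
def test_mwu_matches_enumeration_oracle_for_small_groups(seed):
    rng = np.random.default_rng(seed)
    n, m = rng.integers(2, 6), rng.integers(2, 6)
    vals = rng.permutation(100)[: n + m].astype(float)  # tie-free
    a, b = vals[:n], vals[n:]
    res = mwu_screen(_table(a, b), "A", "B")
    assert res.iloc[0]["p"] == pytest.approx(mwu_exact_two_sided(a, b), rel=1e-9)


def test_identical_groups_with_ties_are_not_significant():
    vals = [1.0, 1.0, 2.0, 2.0, 3.0, 3.0]
    res = mwu_screen(_table(vals, vals), "A", "B")
    assert res.iloc[0]["p"] > 0.9
    assert not res.iloc[0]["significant"]


def test_metrics_with_insufficient_data_are_excluded():
    df = _table([1, 2, 3], [4, 5, 6])
    df["sparse"] = [1.0, np.nan, np.nan, 2.0, 3.0, 4.0]  # one A data point
    res = mwu_screen(df, "A", "B")
    assert "sparse" not in set(res["metric"])
    assert "m" in set(res["metric"])


def test_empty_group_raises():
    df = _table([1, 2], [3, 4])
    with pytest.raises(ValidationError, match="empty group"):
        mwu_screen(df, "A", "C")


# ---------------------------------------------------------------------------
# BKY two-stage FDR


def test_bky_hand_executed_example():
    # stage 1 at q' = 0.1/1.1 = 0.0909: rejects p=(0.001, 0.002) -> r1 = 2;
    # stage 2 at level q'*4/2 = 0.1818 rejects the same two
    reject = bky_reject(np.array([0.001, 0.002, 0.9, 0.95]), q=0.1)
    assert reject.tolist() == [True, True, False, False]


def test_bky_all_ones_rejects_nothing_and_all_tiny_rejects_everything():
    assert bky_reject(np.ones(10), 0.1).sum() == 0
    assert bky_reject(np.full(200, 1e-9), 0.1).all()


def test_bky_with_no_stage_one_rejections_equals_bh_at_reduced_level():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(11)
    p = rng.uniform(0.3, 1.0, 50)  # nothing rejectable in stage 1
    ours = bky_reject(p, 0.1)
    bh = multipletests(p, alpha=0.1 / 1.1, method="fdr_bh")[0]
    assert (ours == bh).all()


@pytest.mark.parametrize("seed", range(5))
def test_bky_agrees_with_statsmodels_two_stage(seed):
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(seed)
    p = np.concatenate([rng.uniform(0, 0.01, 10), rng.uniform(0, 1, 90)])
    ours = bky_reject(p, 0.1)
    ref = multipletests(p, alpha=0.1, method="fdr_tsbky")[0]
    assert (ours == ref).all()


def test_bky_qvalues_are_smallest_rejecting_level():
    p = np.array([0.001, 0.02, 0.5])
    reject, qvals = bky_adjust(p, q=0.1)
    for pi, qi in zip(p, qvals):
        if qi < 1:
            eps = 1e-6
            assert bky_reject(p, min(qi + eps, 1 - eps))[list(p).index(pi)]
            if qi > 2e-6:
                assert not bky_reject(p, qi - eps)[list(p).index(pi)]
    assert reject.tolist() == [True, True, False]


def test_significance_tiers():
    assert significance_tier(0.0005) == "****"
    assert significance_tier(0.005) == "***"
    assert significance_tier(0.03) == "**"
    assert significance_tier(0.09) == "*"
    assert significance_tier(0.2) == "ns"


# ---------------------------------------------------------------------------
# fold change


def test_log2_fold_change_basic_and_degenerate():
    assert log2_fc([8, 8], [2, 2]) == pytest.approx(2.0)
    assert log2_fc([5, 5], [5, 5]) == 0.0
    assert math.isnan(log2_fc([1, 2], [0, 0]))  # zero control mean -> missing
    t = pd.DataFrame({"x": [8.0, 8.0], "y": [0.0, 0.0]})
    c = pd.DataFrame({"x": [2.0, 2.0], "y": [1.0, 1.0]})
    fc = log2_fc_frame(t, c)
    assert fc["x"] == pytest.approx(2.0)
    assert math.isnan(fc["y"])


# ---------------------------------------------------------------------------
# PCA with parallel analysis


def _planted_table(n_per_group=12, n_feat=20, shift=6.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_per_group, n_feat))
    b = rng.standard_normal((n_per_group, n_feat))
    b[:, : n_feat // 2] += shift
    df = pd.DataFrame(np.vstack([a, b]), columns=[f"f{i}" for i in range(n_feat)])
    df["group"] = ["A"] * n_per_group + ["B"] * n_per_group
    return df


def test_planted_mean_shift_is_captured_by_retained_pc1():
    df = _planted_table()
    cols = [c for c in df.columns if c != "group"]
    res = pca_parallel(df, n_sim=200, seed=1, metric_cols=cols)
    assert res.n_retained >= 1
    pc1 = res.scores[:, 0]
    a_scores, b_scores = pc1[df["group"] == "A"], pc1[df["group"] == "B"]
    assert max(a_scores.min(), b_scores.min()) > min(a_scores.max(), b_scores.max()) or (
        a_scores.max() < b_scores.min() or b_scores.max() < a_scores.min()
    )


def test_constant_column_is_dropped_without_changing_result():
    df = _planted_table(seed=3)
    cols = [c for c in df.columns if c != "group"]
    base = pca_parallel(df, n_sim=100, seed=7, metric_cols=cols)
    df2 = df.copy()
    df2["const"] = 5.0
    with_const = pca_parallel(df2, n_sim=100, seed=7, metric_cols=cols + ["const"])
    assert "const" in with_const.dropped_columns
    np.testing.assert_allclose(base.scores, with_const.scores)


def test_pca_requires_three_rows():
    df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
    with pytest.raises(ValidationError):
        pca_parallel(df, n_sim=10, seed=0)


def test_pca_scores_reproducible_for_fixed_seed():
    df = _planted_table(seed=5)
    cols = [c for c in df.columns if c != "group"]
    r1 = pca_parallel(df, n_sim=50, seed=9, metric_cols=cols)
    r2 = pca_parallel(df, n_sim=50, seed=9, metric_cols=cols)
    np.testing.assert_array_equal(r1.scores, r2.scores)
    np.testing.assert_array_equal(r1.null_thresholds, r2.null_thresholds)


# ---------------------------------------------------------------------------
# hierarchical clustering


def test_ward_heights_match_r_hclust_oracle():
    # frozen oracle: R 4.3.3 hclust(dist(x), method="ward.D") on this matrix
    x = np.array([[0.0, 0.1], [0.2, 0.0], [3.0, 3.1], [3.2, 2.9], [10.0, 0.0], [10.1, 0.2]])
    df = pd.DataFrame(x, columns=["u", "v"])
    # bypass standardization to compare raw geometry with the R run
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import pdist

    z = hierarchy.linkage(np.sqrt(pdist(x)), method="ward")
    z[:, 2] = z[:, 2] ** 2
    np.testing.assert_allclose(
        np.sort(z[:, 2]),
        [0.2236067977, 0.2236067977, 0.2828427125, 8.1690492129, 20.2691521894],
        rtol=1e-8,
    )
    assert hierarchy.leaves_list(z).tolist() == [4, 5, 0, 1, 2, 3]


def test_two_planted_groups_split_at_the_top_merge():
    df = _planted_table(n_per_group=8, shift=8.0, seed=2)
    cols = [c for c in df.columns if c != "group"]
    z, order = hier_cluster(df, metric_cols=cols)
    # the final merge joins two clusters of exactly 8 cells each
    from scipy.cluster.hierarchy import fcluster

    two = fcluster(z, t=2, criterion="maxclust")
    groups = df["group"].to_numpy()
    assert len(set(two[groups == "A"])) == 1
    assert len(set(two[groups == "B"])) == 1
    assert set(two) == {1, 2}


def test_duplicate_rows_merge_at_height_zero():
    x = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [1.0, 3.0]])
    df = pd.DataFrame(x, columns=["a", "b"])
    z, _ = hier_cluster(df)
    assert z[0, 2] == pytest.approx(0.0, abs=1e-12)
    assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}


# ---------------------------------------------------------------------------
# correlation


def test_spearman_matrix_trivial_correlations():
    x = pd.DataFrame({"x": np.arange(10.0)})
    y = pd.DataFrame({"same": np.arange(10.0), "neg": -np.arange(10.0)})
    r, p = spearman_matrix(x, y)
    assert r.loc["x", "same"] == pytest.approx(1.0)
    assert r.loc["x", "neg"] == pytest.approx(-1.0)
    assert p.loc["x", "same"] < 1e-6

    with pytest.raises(ValidationError):
        spearman_matrix(x, y.iloc[:5])
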
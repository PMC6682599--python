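"""PCA, clustering, permutation ANOVA, BH-FDR, decile filter, enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb
from sklearn.metrics import adjusted_rand_score

from enamelmap.errors import ValidationError
from enamelmap.spatialstats import (
    GroupAssignment,
    assign_direction,
    bh_adjust,
    complete_matrix,
    differential_abundance,
    hcluster_locations,
    over_representation,
    pca_locations,
    percentile_filter,
    permutation_anova,
)
from enamelmap.tables_io import SampleBlock


def make_grid(stages, tooth="M3"):
    return [SampleBlock(f"L{i}", tooth, i, 0, 2.0, s) for i, s in enumerate(stages)]


# ---------------------------------------------------------------------------
# PCA


def test_pca_identical_locations_degenerate():
    df = pd.DataFrame({"L1": [1.0, 2.0], "L2": [1.0, 2.0], "L3": [1.0, 2.0]},
                      index=["P1", "P2"])
    scores, frac = pca_locations(df)
    assert np.allclose(scores.to_numpy(), 0.0)
    assert np.allclose(frac, 0.0)


def test_pca_two_locations_symmetric_scores():
    df = pd.DataFrame({"L1": [0.0, 0.0], "L2": [3.0, 4.0]}, index=["P1", "P2"])
    scores, frac = pca_locations(df)
    d = 5.0  # Euclidean distance between the two locations
    got = sorted(scores["PC1"])
    assert got == pytest.approx([-d / 2, d / 2])
    assert frac[0] == pytest.approx(1.0)


def test_pca_fewer_than_two_locations_rejected():
    with pytest.raises(ValidationError, match="2 locations"):
        pca_locations(pd.DataFrame({"L1": [1.0]}, index=["P1"]))


def test_pca_matches_eigendecomposition_oracle():
    """Scores agree with a dense covariance eigendecomposition to 1e-8."""
    rng = np.random.default_rng(9)
    df = pd.DataFrame(rng.normal(size=(5, 8)),
                      index=[f"P{i}" for i in range(5)],
                      columns=[f"L{j}" for j in range(8)])
    scores, frac = pca_locations(df)

    X = df.to_numpy().T
    C = X - X.mean(axis=0)
    evals, evecs = np.linalg.eigh(C.T @ C / (X.shape[0] - 1))
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    for i in range(scores.shape[1]):
        v = evecs[:, i]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        assert np.allclose(scores.iloc[:, i], C @ v, atol=1e-8)
    assert np.allclose(frac, evals[: scores.shape[1]] / evals.sum(), atol=1e-8)


# ---------------------------------------------------------------------------
# clustering


def test_hcluster_extreme_k():
    stages = ["secretory"] * 3 + ["dentin"] * 2
    grid = make_grid(stages)
    df = pd.DataFrame(np.eye(5), columns=[b.location_id for b in grid])
    all_own = hcluster_locations(df, grid, k=5)
    assert len(set(all_own.labels.values())) == 5
    one = hcluster_locations(df, grid, k=1)
    assert set(one.labels.values()) == {1}
    with pytest.raises(ValidationError, match="k="):
        hcluster_locations(df, grid, k=6)


def test_hcluster_recovers_planted_blobs():
    rng = np.random.default_rng(0)
    a = rng.normal(0.0, 0.1, size=(4, 6))
    b = rng.normal(10.0, 0.1, size=(4, 6))
    df = pd.DataFrame(np.hstack([a, b]), columns=[f"L{i}" for i in range(12)])
    grid = make_grid(["secretory"] * 6 + ["dentin"] * 6)
    got = hcluster_locations(df, grid, k=2)
    labels = [got.labels[f"L{i}"] for i in range(12)]
    planted = [0] * 6 + [1] * 6
    assert adjusted_rand_score(planted, labels) == 1.0
    assert got.group_of("L0") == "Secretion" and got.group_of("L11") == "NonEnamel"


def test_hcluster_majority_tie_broken_toward_earlier_stage():
    grid = make_grid(["secretory", "late_maturation"])
    df = pd.DataFrame([[0.0, 0.1]], columns=["L0", "L1"])
    got = hcluster_locations(df, grid, k=1)
    assert got.group_names[1] == "Secretion"


# ---------------------------------------------------------------------------
# permutation ANOVA


def anova_p_oracle(values, groups):
    """Exhaustive oracle: F over every permutation of the value vector."""
    def f_stat(vals):
        vals = np.asarray(vals, dtype=float)
        k = len(set(groups))
        n = len(vals)
        grand = vals.mean()
        ssb = ssw = 0.0
        for g in set(groups):
            sub = vals[np.asarray(groups) == g]
            ssb += len(sub) * (sub.mean() - grand) ** 2
            ssw += ((sub - sub.mean()) ** 2).sum()
        if ssw == 0:
            return math.inf if ssb > 0 else 0.0
        return (ssb / (k - 1)) / (ssw / (n - k))

    obs = f_stat(values)
    perms = list(itertools.permutations(values))
    hits = sum(f_stat(p) >= obs - 1e-9 * (abs(obs) + 1) for p in perms)
    return hits / len(perms)


def test_all_equal_values_give_p_one():
    _, p = permutation_anova([3.0] * 8, ["a"] * 4 + ["b"] * 4, 99, seed=0)
    assert p == 1.0


def test_exhaustive_matches_full_enumeration_oracle():
    rng = np.random.default_rng(21)
    groups = ["a", "a", "b", "b"]
    for _ in range(20):
        values = rng.normal(size=4).tolist()
        stat, p = permutation_anova(values, groups, n_permutations=4999, seed=1)
        assert p == pytest.approx(anova_p_oracle(values, groups), abs=1e-12)


def test_exhaustive_three_groups():
    rng = np.random.default_rng(2)
    groups = ["a", "a", "b", "b", "c", "c"]
    values = rng.normal(size=6).tolist()
    _, p = permutation_anova(values, groups, n_permutations=4999, seed=1)
    assert p == pytest.approx(anova_p_oracle(values, groups), abs=1e-12)


def test_monte_carlo_close_to_exhaustive():
    rng = np.random.default_rng(4)
    groups = ["a"] * 5 + ["b"] * 5
    values = rng.normal(size=10)
    values[:5] += 1.0
    # 252 distinct arrangements: exhaustive at B=300, Monte-Carlo at B=199
    _, p_ex = permutation_anova(values, groups, n_permutations=300, seed=0)
    B = 199
    _, p_mc = permutation_anova(values, groups, n_permutations=B, seed=11)
    assert abs(p_mc - p_ex) <= 2 * math.sqrt(p_ex * (1 - p_ex) / B) + 1 / B


def test_group_smaller_than_two_rejected():
    with pytest.raises(ValidationError, match="fewer than 2"):
        permutation_anova([1.0, 2.0, 3.0], ["a", "a", "b"], 99, seed=0)


def test_degenerate_within_variance_is_significant():
    values = [1.0, 1.0, 5.0, 5.0]
    stat, p = permutation_anova(values, ["a", "a", "b", "b"], 4999, seed=0)
    assert math.isinf(stat)
    # only the 2 arrangements splitting the tie reach F = inf
    assert p == pytest.approx(2 / 6)


def test_null_p_values_super_uniform():
    """Rejection never exceeds its nominal level beyond Monte-Carlo error."""
    rng = np.random.default_rng(12)
    groups = ["a"] * 6 + ["b"] * 5 + ["c"] * 5 + ["d"] * 5
    n = 300
    ps = []
    for i in range(n):
        vals = rng.normal(size=21)
        _, p = permutation_anova(vals, groups, n_permutations=499,
                                 seed=int(rng.integers(2**31)))
        ps.append(p)
    ps = np.asarray(ps)
    for alpha in (0.01, 0.05, 0.1, 0.25):
        se = math.sqrt(alpha * (1 - alpha) / n)
        assert (ps <= alpha).mean() <= alpha + 3 * se


# ---------------------------------------------------------------------------
# BH adjustment


def bh_oracle(p):
    """Direct step-up definition: q_(i) = min_{j >= i} p_(j) * n / j, capped."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = running
    return np.minimum(q, 1.0)


def test_bh_single_p_unchanged():
    q, rej = bh_adjust([0.03])
    assert q[0] == pytest.approx(0.03) and rej[0]


def test_bh_all_equal():
    q, _ = bh_adjust([0.2, 0.2, 0.2])
    assert np.allclose(q, 0.2)


def test_bh_matches_brute_force_definition():
    rng = np.random.default_rng(8)
    for _ in range(200):
        p = rng.uniform(1e-6, 1.0, size=int(rng.integers(1, 11)))
        q, rej = bh_adjust(p, alpha=0.05)
        assert np.allclose(q, bh_oracle(p), atol=1e-12)
        assert (rej == (q <= 0.05)).all()


def test_bh_rejects_out_of_range():
    with pytest.raises(ValidationError, match="p-values"):
        bh_adjust([0.0, 0.5])
    with pytest.raises(ValidationError, match="p-values"):
        bh_adjust([1.5])


# ---------------------------------------------------------------------------
# direction and decile filter


def test_direction_secretion_high():
    values = np.array([10.0, 11.0, 1.0, 1.5, 0.5, 1.0])
    groups = np.array(["Secretion", "Secretion", "DEJ", "DEJ",
                       "Maturation", "Maturation"])
    got = assign_direction(values, groups)
    assert got == {"Secretion": "higher", "DEJ": "lower", "Maturation": "lower"}


def test_direction_all_equal_neutral():
    got = assign_direction([2.0] * 6, ["a", "a", "b", "b", "c", "c"])
    assert set(got.values()) == {"neutral"}


def test_percentile_filter_distinct_removes_nearest_rank_count():
    means = pd.Series({f"P{i}": float(i) for i in range(10)})
    kept = percentile_filter(means, percentile=10)
    assert len(kept) == 9 and "P0" not in kept.index


def test_percentile_filter_all_equal_removes_none():
    means = pd.Series({f"P{i}": 5.0 for i in range(10)})
    assert len(percentile_filter(means, percentile=10)) == 10


def test_percentile_filter_empty():
    assert len(percentile_filter(pd.Series(dtype=float), percentile=10)) == 0


def test_percentile_filter_scales_with_n():
    means = pd.Series({f"P{i}": float(i) for i in range(21)})
    kept = percentile_filter(means, percentile=10)
    assert len(kept) == 18  # ceil(0.1 * 21) = 3 removed


# ---------------------------------------------------------------------------
# over-representation


def hypergeom_tail_oracle(k, M, K, N):
    return sum(comb(K, i, exact=True) * comb(M - K, N - i, exact=True)
               for i in range(k, min(K, N) + 1)) / comb(M, N, exact=True)


def test_term_covering_background_has_fold_one():
    background = {f"g{i}" for i in range(20)}
    ann = pd.DataFrame({"protein": sorted(background),
                        "term": ["everything"] * 20})
    df, _ = over_representation({"g1", "g2", "g3"}, ann, background)
    assert df.loc[0, "fold_enrichment"] == pytest.approx(1.0)
    assert df.loc[0, "p_value"] == pytest.approx(1.0)


def test_hypergeometric_p_matches_tail_oracle():
    background = {f"g{i}" for i in range(1000)}
    term_genes = {f"g{i}" for i in range(50)}
    gene_set = {f"g{i}" for i in range(10)} | {f"g{i}" for i in range(500, 510)}
    ann = pd.DataFrame({"protein": sorted(term_genes), "term": ["T"] * 50})
    df, _ = over_representation(gene_set, ann, background)
    assert df.loc[0, "hits"] == 10
    expected = hypergeom_tail_oracle(10, 1000, 50, 20)
    assert df.loc[0, "p_value"] == pytest.approx(expected, rel=1e-10)


def test_empty_gene_set_gives_empty_result():
    ann = pd.DataFrame({"protein": ["g1"], "term": ["T"]})
    df, _ = over_representation(set(), ann, {"g1", "g2"})
    assert df.empty


def test_genes_absent_from_background_audited():
    ann = pd.DataFrame({"protein": ["g1", "g2"], "term": ["T", "T"]})
    df, audit = over_representation({"g1", "g2", "alien"}, ann, {"g1", "g2", "g3"})
    assert audit["genes_absent_from_background"] == ["alien"]


# ---------------------------------------------------------------------------
# differential abundance wrapper


def diff_fixture():
    stages = (["secretory"] * 5 + ["early_maturation"] * 5 + ["DEJ"] * 5
              + ["erupted"] * 6)
    grid = make_grid(stages)
    locs = [b.location_id for b in grid]
    rng = np.random.default_rng(6)
    base = rng.normal(50.0, 1.0, size=(6, 21))
    base[0, :5] += 40.0  # planted Secretion-high protein
    df = pd.DataFrame(base, index=[f"P{i}" for i in range(6)], columns=locs)
    labels = {loc: {"secretory": 1, "early_maturation": 2, "DEJ": 3,
                    "erupted": 4}[b.stage] for loc, b in zip(locs, grid)}
    names = {1: "Secretion", 2: "Maturation", 3: "DEJ", 4: "Cuspal"}
    assignment = GroupAssignment(labels, names, np.empty((0, 4)), locs)
    return df, assignment


def test_differential_abundance_flags_planted_protein():
    df, assignment = diff_fixture()
    res = differential_abundance(df, assignment, n_permutations=999, seed=0)
    top = res.iloc[0]
    assert top["protein"] == "P0" and top["significant"]
    assert top["direction_Secretion"] == "higher"
    assert top["direction_DEJ"] == "lower"
    nulls = res[res["protein"] != "P0"]
    assert (~nulls["significant"]).all()


def test_differential_abundance_deterministic_given_seed():
    df, assignment = diff_fixture()
    a = differential_abundance(df, assignment, n_permutations=499, seed=3)
    b = differential_abundance(df, assignment, n_permutations=499, seed=3)
    pd.testing.assert_frame_equal(a, b)


def test_complete_matrix_policies():
    df = pd.DataFrame({"L1": [1.0, np.nan], "L2": [2.0, 3.0]}, index=["P1", "P2"])
    zeroed, audit = complete_matrix(df, "zero")
    assert zeroed.at["P2", "L1"] == 0.0 and audit["imputed_zero_cells"] == 1
    dropped, audit2 = complete_matrix(df, "drop")
    assert list(dropped.index) == ["P1"] and audit2["dropped_incomplete_rows"] == 1
    with pytest.raises(ValidationError, match="policy"):
        complete_matrix(df, "interpolate")
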
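import io as stdio

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from dualcore import community_stats as cs
from dualcore.datatypes import AbundanceTable, TaxonomyTable, TAXONOMY_RANKS

from ._oracles import stepup_bh


def _table(counts, asvs=None, samples=None, **kw):
    counts = np.asarray(counts, dtype=float)
    asvs = asvs or [f"a{i}" for i in range(counts.shape[0])]
    samples = samples or [f"s{j}" for j in range(counts.shape[1])]
    return AbundanceTable(pd.DataFrame(counts, index=asvs, columns=samples), **kw)


# --- relative abundance -----------------------------------------------------


def test_relative_abundance_examples():
    rel = cs.relative_abundance(_table([[2], [2]]))
    np.testing.assert_allclose(rel.data.to_numpy().ravel(), [0.5, 0.5])
    rel = cs.relative_abundance(_table([[0], [5]]))
    np.testing.assert_allclose(rel.data.to_numpy().ravel(), [0.0, 1.0])


def test_relative_abundance_idempotent():
    rel = cs.relative_abundance(_table([[1], [3]]))
    again = cs.relative_abundance(rel)
    assert again is rel


def test_relative_abundance_all_zero_sample_errors():
    with pytest.raises(ValueError, match="s1"):
        cs.relative_abundance(_table([[1, 0], [1, 0]]))


# --- Bray-Curtis ------------------------------------------------------------


def test_bray_curtis_identical_columns_zero():
    dm = cs.bray_curtis(_table([[1, 1], [2, 2]]))
    assert dm.data[0, 1] == 0.0


def test_bray_curtis_disjoint_supports_one():
    dm = cs.bray_curtis(_table([[1, 0], [0, 1]]))
    assert dm.data[0, 1] == pytest.approx(1.0)


def test_bray_curtis_range_symmetry_random():
    rng = np.random.default_rng(0)
    dm = cs.bray_curtis(_table(rng.integers(0, 10, size=(12, 8)) + rng.integers(0, 2, size=(12, 8))))
    assert (dm.data >= 0).all() and (dm.data <= 1).all()
    np.testing.assert_allclose(dm.data, dm.data.T, atol=1e-15)
    assert np.all(np.diag(dm.data) == 0)


# --- unweighted UniFrac -----------------------------------------------------


def _tree(newick):
    return TreeNode.read(stdio.StringIO(newick))


def test_unifrac_identical_presence_zero():
    tree = _tree("((A:1,B:1):1,C:1);")
    table = _table([[1, 2], [1, 1], [0, 0]], asvs=["A", "B", "C"])
    dm = cs.unweighted_unifrac(table, tree)
    assert dm.data[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_unifrac_disjoint_sides_one():
    tree = _tree("((A:1,B:1):1,(C:1,D:1):1);")
    table = _table([[1, 0], [1, 0], [0, 1], [0, 1]], asvs=["A", "B", "C", "D"])
    dm = cs.unweighted_unifrac(table, tree)
    assert dm.data[0, 1] == pytest.approx(1.0)


def test_unifrac_hand_derived_sister_tip():
    # tree branches: A:1, B:1, (AB):1, C:1. Samples {A} vs {A,B}:
    # unique = B's branch (1); union = A + B + AB stem (3) -> d = 1/3
    tree = _tree("((A:1,B:1):1,C:1);")
    table = _table([[1, 1], [0, 1], [0, 0]], asvs=["A", "B", "C"])
    dm = cs.unweighted_unifrac(table, tree)
    assert dm.data[0, 1] == pytest.approx(1 / 3, abs=1e-12)


def test_unifrac_missing_tip_errors():
    tree = _tree("(A:1,B:1);")
    table = _table([[1], [1]], asvs=["A", "Z"])
    with pytest.raises(ValueError, match="Z"):
        cs.unweighted_unifrac(table, tree)


def test_unifrac_upper_bound_random(default_scenario):
    _, (table, _, _, _, tree, _) = default_scenario
    sub = AbundanceTable(table.data.iloc[:, :6])
    dm = cs.unweighted_unifrac(sub, tree)
    assert (dm.data <= 1.0 + 1e-12).all()


# --- PCoA -------------------------------------------------------------------


def test_pcoa_equilateral_two_equal_eigenvalues():
    d = 0.8
    dm = cs.DistanceMatrix(["a", "b", "c"], d * (1 - np.eye(3)), "test")
    res = cs.pcoa(dm)
    # closed form: B = d^2/2 * centering matrix -> eigenvalues {d^2/2, d^2/2}
    np.testing.assert_allclose(res.eigenvalues, [d**2 / 2, d**2 / 2], rtol=1e-9)


def test_pcoa_reproduces_euclidean_distances():
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(7, 3))
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    dm = cs.DistanceMatrix([f"s{i}" for i in range(7)], d, "euclidean")
    res = cs.pcoa(dm)
    coords = res.coordinates.to_numpy()
    d2 = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    np.testing.assert_allclose(d2, d, atol=1e-9)


def test_pcoa_duplicated_point_drops_zero_direction():
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    dm = cs.DistanceMatrix(["a", "b", "b2", "c"], d, "euclidean")
    res = cs.pcoa(dm)
    assert res.coordinates.shape[1] == 2  # zero eigenvalue dropped
    assert (res.eigenvalues > 0).all()
    assert res.proportion_explained.sum() == pytest.approx(1.0)


def test_pcoa_too_few_samples():
    dm = cs.DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float), "t")
    with pytest.raises(ValueError):
        cs.pcoa(dm)


# --- ANOSIM -----------------------------------------------------------------


def _dm_two_groups(within, between, n_per=3):
    n = 2 * n_per
    d = np.full((n, n), between, dtype=float)
    for block in (slice(0, n_per), slice(n_per, n)):
        d[block, block] = within
    np.fill_diagonal(d, 0.0)
    ids = [f"s{i}" for i in range(n)]
    groups = {ids[i]: ("g1" if i < n_per else "g2") for i in range(n)}
    return cs.DistanceMatrix(ids, d, "test"), groups


def test_anosim_perfect_separation_r_one():
    dm, groups = _dm_two_groups(within=0.2, between=0.9)
    res = cs.anosim(dm, groups, n_permutations=99, seed=0)
    assert res.R == pytest.approx(1.0)
    assert res.p >= 1 / 100


def test_anosim_all_equal_ranks_r_zero():
    dm, groups = _dm_two_groups(within=0.5, between=0.5)
    res = cs.anosim(dm, groups, n_permutations=99, seed=0)
    assert res.R == pytest.approx(0.0, abs=1e-12)


def test_anosim_group_of_one_errors():
    dm, _ = _dm_two_groups(0.2, 0.9)
    groups = {f"s{i}": ("g1" if i == 0 else "g2") for i in range(6)}
    with pytest.raises(ValueError):
        cs.anosim(dm, groups)


def test_anosim_null_mean_r_near_zero():
    # structureless data, random labels: E[R] ~ 0 (200 replicates)
    rng = np.random.default_rng(2)
    vals = []
    for _ in range(200):
        n = 12
        x = rng.normal(size=(n, 4))
        d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
        ids = [f"s{i}" for i in range(n)]
        labels = rng.permutation([0] * 6 + [1] * 6)
        groups = {ids[i]: str(labels[i]) for i in range(n)}
        dm = cs.DistanceMatrix(ids, d, "t")
        vals.append(cs.anosim(dm, groups, n_permutations=10, seed=1).R)
    assert abs(np.mean(vals)) < 0.05


def test_anosim_matches_skbio_r_statistic():
    import skbio.stats.distance as sksd

    rng = np.random.default_rng(3)
    n = 10
    x = rng.normal(size=(n, 3))
    d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
    ids = [f"s{i}" for i in range(n)]
    labels = ["g1"] * 5 + ["g2"] * 5
    ours = cs.anosim(cs.DistanceMatrix(ids, d, "t"),
                     dict(zip(ids, labels)), n_permutations=99, seed=0)
    theirs = sksd.anosim(sksd.DistanceMatrix(d, ids), grouping=list(labels),
                         permutations=99)
    assert ours.R == pytest.approx(theirs["test statistic"], abs=1e-12)


# --- PERMANOVA --------------------------------------------------------------


def test_permanova_zero_within_r2_one():
    dm, groups = _dm_two_groups(within=0.0, between=0.9)
    res = cs.permanova(dm, groups, n_permutations=99, seed=0)
    assert res.R2 == pytest.approx(1.0)
    assert res.F == np.inf


def test_permanova_single_group_errors():
    dm, _ = _dm_two_groups(0.1, 0.5)
    groups = {f"s{i}": "g" for i in range(6)}
    with pytest.raises(ValueError):
        cs.permanova(dm, groups)


def test_permanova_matches_skbio():
    import skbio.stats.distance as sksd

    rng = np.random.default_rng(4)
    n = 12
    x = rng.normal(size=(n, 3))
    d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
    ids = [f"s{i}" for i in range(n)]
    labels = ["g1"] * 6 + ["g2"] * 6
    ours = cs.permanova(cs.DistanceMatrix(ids, d, "t"),
                        dict(zip(ids, labels)), n_permutations=99, seed=0)
    theirs = sksd.permanova(sksd.DistanceMatrix(d, ids), grouping=list(labels),
                            permutations=99)
    assert ours.F == pytest.approx(theirs["test statistic"], abs=1e-10)


def test_permanova_type_one_error_calibrated():
    rng = np.random.default_rng(5)
    rejections = 0
    n_reps = 400
    for _ in range(n_reps):
        n = 12
        x = rng.normal(size=(n, 3))
        d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
        ids = [f"s{i}" for i in range(n)]
        labels = rng.permutation([0] * 6 + [1] * 6)
        groups = {ids[i]: str(labels[i]) for i in range(n)}
        res = cs.permanova(cs.DistanceMatrix(ids, d, "t"), groups,
                           n_permutations=99, seed=int(rng.integers(1 << 31)))
        rejections += res.p <= 0.05
    assert rejections / n_reps == pytest.approx(0.05, abs=0.02)


# --- aggregation & differential abundance -----------------------------------


def _taxonomy(mapping):
    rows = {a: ["Bacteria", p, "c", "o", "f", "g"] for a, p in mapping.items()}
    return TaxonomyTable(pd.DataFrame.from_dict(rows, orient="index",
                                                columns=list(TAXONOMY_RANKS)))


def test_aggregate_rank_sums_and_conserves():
    table = _table([[0.1], [0.2], [0.7]], asvs=["a", "b", "c"])
    tax = _taxonomy({"a": "P1", "b": "P1", "c": "unassigned"})
    agg = cs.aggregate_rank(table, tax, "phylum")
    assert agg.data.loc["P1", "s0"] == pytest.approx(0.3)
    assert agg.data.loc["unassigned", "s0"] == pytest.approx(0.7)
    assert agg.data.sum().to_numpy() == pytest.approx(table.data.sum().to_numpy())


def test_aggregate_rank_missing_taxonomy_errors():
    table = _table([[1.0]], asvs=["a"])
    tax = _taxonomy({"b": "P1"})
    with pytest.raises(ValueError, match="a"):
        cs.aggregate_rank(table, tax, "phylum")


def _features(rows, samples):
    return pd.DataFrame(rows, index=[f"f{i}" for i in range(len(rows))],
                        columns=[f"s{j}" for j in range(samples)], dtype=float)


def test_welch_identical_groups():
    fa = _features([[0.5, 0.5, 0.5]], 3)
    results = cs.welch_bh(fa, fa.copy())
    assert results[0].welch_t == 0.0
    assert results[0].p_raw == 1.0
    assert not results[0].significant


def test_bh_worked_example():
    q = cs.bh_adjust([0.01, 0.02, 0.03, 0.04])
    np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)
    np.testing.assert_allclose(q, stepup_bh([0.01, 0.02, 0.03, 0.04]), atol=1e-15)


def test_bh_matches_stepup_oracle_random():
    rng = np.random.default_rng(6)
    for _ in range(20):
        p = rng.uniform(size=rng.integers(1, 30))
        np.testing.assert_allclose(cs.bh_adjust(p), stepup_bh(p), atol=1e-12)


def test_bh_order_invariant_and_monotone():
    rng = np.random.default_rng(7)
    p = rng.uniform(size=15)
    q = cs.bh_adjust(p)
    perm = rng.permutation(15)
    np.testing.assert_allclose(cs.bh_adjust(p[perm]), q[perm], atol=1e-12)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


def test_welch_ten_sd_shift_highly_significant():
    rng = np.random.default_rng(8)
    base = rng.normal(0, 1.0, size=10)
    fa = _features([base], 10)
    fb = _features([base + 10 * base.std(ddof=1)], 10)
    results = cs.welch_bh(fa, fb)
    assert results[0].q_bh < 0.001


def test_welch_small_group_skipped(caplog):
    fa = _features([[0.5]], 1)
    fb = _features([[0.4]], 1)
    with caplog.at_level("INFO", logger="dualcore.community_stats"):
        results = cs.welch_bh(fa, fb)
    assert results == []
    assert "skipped" in caplog.text
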
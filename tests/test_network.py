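"""Adjacency, TOM, module detection, eigengenes, membership, edge export."""

import numpy as np
import pandas as pd
import pytest

import dielnet as dn
from conftest import make_expression


def _adjacency_from_profiles(profiles, beta=16.0):
    em = make_expression(profiles, zts=[1, 5, 9, 13], scale="log2")
    return dn.signed_adjacency(em, beta=beta)


# ---------------------------------------------------------------------------
# signed adjacency
# ---------------------------------------------------------------------------

def test_adjacency_closed_forms():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    profiles = np.vstack([x, x + 10.0, -x, [1.0, -1.0, 1.0, -1.0]])
    # g3 vs a vector orthogonal to it after centering
    profiles = np.vstack([profiles, [1.0, 1.0, -1.0, -1.0]])
    adj = _adjacency_from_profiles(profiles)
    a = adj.values
    assert a[0, 1] == pytest.approx(1.0, abs=1e-12)  # cor = 1
    assert a[0, 2] == pytest.approx(0.0, abs=1e-12)  # cor = -1
    assert a[3, 4] == pytest.approx(2.0**-16, rel=1e-9)  # cor = 0


def test_adjacency_symmetric_unit_diagonal(ww_pipeline):
    adj = dn.signed_adjacency(ww_pipeline["log"])
    assert np.allclose(adj.values, adj.values.T, atol=1e-12)
    assert np.allclose(np.diag(adj.values), 1.0)
    assert adj.values.min() >= 0 and adj.values.max() <= 1


def test_increasing_beta_weakly_shrinks_edges():
    rng = np.random.default_rng(3)
    em = make_expression(rng.normal(size=(10, 4)), zts=[1, 5, 9, 13], scale="log2")
    a8 = dn.signed_adjacency(em, beta=8).values
    a16 = dn.signed_adjacency(em, beta=16).values
    off = ~np.eye(10, dtype=bool)
    assert (a16[off] <= a8[off] + 1e-15).all()


def test_zero_variance_gene_dropped_with_warning():
    profiles = np.vstack([np.arange(4.0), 2.0 * np.arange(4.0), np.ones(4)])
    em = make_expression(profiles, zts=[1, 5, 9, 13], scale="log2")
    with pytest.warns(UserWarning, match="zero-variance"):
        adj = dn.signed_adjacency(em)
    assert list(adj.gene_ids) == ["g0", "g1"]


# ---------------------------------------------------------------------------
# topological overlap
# ---------------------------------------------------------------------------

def naive_tom(a):
    """O(n^3) triple-loop oracle for the signed TOM formula."""
    n = a.shape[0]
    t = np.eye(n)
    k = a.sum(axis=0) - np.diag(a)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            t[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return t


def test_tom_hand_example_all_half():
    a = np.full((3, 3), 0.5)
    np.fill_diagonal(a, 1.0)
    tom = dn.topological_overlap(dn.AdjacencyMatrix(pd.Index(list("abc")), a))
    assert tom.values[0, 1] == pytest.approx(0.5, abs=1e-12)


def test_tom_zero_adjacency_gives_zero():
    a = np.eye(4)
    tom = dn.topological_overlap(dn.AdjacencyMatrix(pd.Index(list("abcd")), a))
    off = ~np.eye(4, dtype=bool)
    assert np.allclose(tom.values[off], 0.0)


def test_tom_matches_naive_oracle():
    rng = np.random.default_rng(8)
    for _ in range(50):
        a = rng.uniform(0, 1, size=(8, 8))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = dn.topological_overlap(
            dn.AdjacencyMatrix(pd.Index([f"g{i}" for i in range(8)]), a)
        )
        assert np.abs(tom.values - naive_tom(a)).max() < 1e-12


def test_tom_invariant_to_gene_permutation(ww_pipeline):
    adj = dn.signed_adjacency(ww_pipeline["log"])
    perm = np.random.default_rng(0).permutation(len(adj.gene_ids))
    adj_p = dn.AdjacencyMatrix(
        adj.gene_ids[perm], adj.values[np.ix_(perm, perm)], adj.beta
    )
    t1 = dn.topological_overlap(adj).values
    t2 = dn.topological_overlap(adj_p).values
    assert np.abs(t1[np.ix_(perm, perm)] - t2).max() < 1e-12


# ---------------------------------------------------------------------------
# module detection
# ---------------------------------------------------------------------------

def _block_tom(sizes, within, between=0.01, seed=None):
    n = sum(sizes)
    a = np.full((n, n), between)
    start = 0
    for size, w in zip(sizes, within):
        a[start : start + size, start : start + size] = w
        start += size
    np.fill_diagonal(a, 1.0)
    return dn.TOMatrix(pd.Index([f"g{i:04d}" for i in range(n)]), a)


def test_two_planted_blocks_recovered_exactly():
    tom = _block_tom([50, 50], [0.8, 0.8])
    mods, _ = dn.detect_modules(tom, min_size=30)
    assert mods.module_sizes.to_dict() == {1: 50, 2: 50}
    assert (mods.labels != 0).all()
    # labels are contiguous with the planted blocks
    assert mods.labels.iloc[:50].nunique() == 1
    assert mods.labels.iloc[50:].nunique() == 1


def test_uniform_random_tom_yields_no_modules():
    rng = np.random.default_rng(4)
    m = rng.uniform(0, 0.05, size=(120, 120))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    tom = dn.TOMatrix(pd.Index([f"g{i}" for i in range(120)]), m)
    mods, _ = dn.detect_modules(tom, min_size=10)
    assert mods.module_ids == []


def test_undersized_planted_module_is_rejected():
    tom = _block_tom([25, 40], [0.8, 0.01])
    mods, _ = dn.detect_modules(tom, min_size=30)
    assert mods.module_ids == []


# ---------------------------------------------------------------------------
# eigengenes
# ---------------------------------------------------------------------------

def test_identical_genes_give_shared_zscore_eigengene():
    x = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
    em = make_expression(np.vstack([x, x, x]), zts=[1, 5, 9, 13, 17, 21], scale="log2")
    mods = dn.ModuleAssignment(pd.Series([1, 1, 1], index=em.gene_ids))
    eig = dn.module_eigengenes(em, mods)
    z = (x - x.mean()) / x.std()
    expected = z / np.linalg.norm(z)
    np.testing.assert_allclose(eig.me.loc[1].to_numpy(), expected, atol=1e-12)
    assert eig.variance_explained[1] == pytest.approx(1.0, abs=1e-12)


def test_eigengene_recovers_common_cosine():
    rng = np.random.default_rng(5)
    t = np.array(sorted(list(range(1, 46, 4)) * 2), dtype=float)
    cosine = np.cos(2 * np.pi * (t - 5) / 24)
    profiles = np.vstack([cosine + rng.normal(0, 1 / 3, size=len(t)) for _ in range(5)])
    em = make_expression(profiles, zts=t, scale="log2")
    mods = dn.ModuleAssignment(pd.Series(1, index=em.gene_ids))
    eig = dn.module_eigengenes(em, mods)
    me = eig.me.loc[1].to_numpy()
    r = np.corrcoef(me, np.cos(2 * np.pi * (em.samples["zt"] - 5) / 24))[0, 1]
    assert r >= 0.95


def test_eigengene_orientation_invariant_to_sample_order(ww_pipeline):
    em = ww_pipeline["log"]
    mods = ww_pipeline["modules"]
    eig1 = ww_pipeline["eigengenes"]
    shuffled = dn.ExpressionMatrix(
        em.values[list(reversed(em.sample_ids))], em.samples, em.scale
    )
    eig2 = dn.module_eigengenes(shuffled, mods)
    for m in eig1.module_ids:
        np.testing.assert_allclose(
            eig1.me.loc[m, eig2.me.columns], eig2.me.loc[m], atol=1e-9
        )


def test_single_gene_module_warns():
    em = make_expression(np.random.default_rng(0).normal(size=(2, 4)), zts=[1, 5, 9, 13], scale="log2")
    mods = dn.ModuleAssignment(pd.Series([1, 2], index=em.gene_ids))
    with pytest.warns(UserWarning, match="single gene"):
        dn.module_eigengenes(em, mods)


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def _cosine_module_em(phases, genes_per=5, noise=0.02, seed=0):
    rng = np.random.default_rng(seed)
    t = np.array(sorted(list(range(1, 46, 4)) * 2), dtype=float)
    rows, labels = [], []
    for mi, ph in enumerate(phases, start=1):
        for _ in range(genes_per):
            rows.append(
                np.cos(2 * np.pi * (t - ph) / 24) + rng.normal(0, noise, len(t))
            )
            labels.append(mi)
    em = make_expression(np.array(rows), zts=t, scale="log2")
    return em, dn.ModuleAssignment(pd.Series(labels, index=em.gene_ids))


def test_identical_eigengenes_merge():
    em, mods = _cosine_module_em([5.0, 5.0])
    merged = dn.merge_close_modules(em, mods, merge_cut=0.25)
    assert len(merged.module_ids) == 1


def test_distant_eigengenes_do_not_merge():
    # phases 4 h apart: ME correlation ~0.5, dissimilarity ~0.5 > 0.25
    em, mods = _cosine_module_em([1.0, 5.0])
    merged = dn.merge_close_modules(em, mods, merge_cut=0.25)
    assert len(merged.module_ids) == 2


def test_chained_merging_collapses_cluster_of_three():
    # pairwise ME correlations ~{0.97, 0.97, 0.9}: all within the cut chain
    em, mods = _cosine_module_em([4.0, 5.0, 6.0])
    merged = dn.merge_close_modules(em, mods, merge_cut=0.25)
    assert len(merged.module_ids) == 1


def test_merge_cut_bounds():
    em, mods = _cosine_module_em([1.0, 13.0])
    with pytest.raises(ValueError):
        dn.merge_close_modules(em, mods, merge_cut=1.5)


# ---------------------------------------------------------------------------
# module membership
# ---------------------------------------------------------------------------

def test_mm_identities_and_t_formula():
    rng = np.random.default_rng(6)
    t = np.arange(12, dtype=float)
    base = np.cos(2 * np.pi * t / 12)
    em = make_expression(
        np.vstack([base, base * 2 + 1]), zts=list(range(1, 46, 4)), scale="log2"
    )
    mods = dn.ModuleAssignment(pd.Series([1, 1], index=em.gene_ids))
    eig = dn.module_eigengenes(em, mods)
    mm, p = dn.module_membership(em, eig)
    assert mm.at["g0", 1] == pytest.approx(1.0, abs=1e-9)
    assert p.at["g0", 1] == pytest.approx(0.0, abs=1e-9)


def test_mm_orthogonal_gene_zero():
    x = np.array([1.0, -1.0, 1.0, -1.0] * 3)
    y = np.array([1.0, 1.0, -1.0, -1.0] * 3)
    em = make_expression(np.vstack([x, y]), zts=list(range(1, 46, 4)), scale="log2")
    mods = dn.ModuleAssignment(pd.Series([1, 2], index=em.gene_ids))
    eig = dn.module_eigengenes(em, mods)
    mm, p = dn.module_membership(em, eig)
    assert mm.at["g1", 1] == pytest.approx(0.0, abs=1e-9)
    assert p.at["g1", 1] == pytest.approx(1.0, abs=1e-9)


def test_mm_p_closed_form_r07_n12():
    """r = 0.7 at n = 12 gives t ~= 3.10 and two-sided p ~= 0.011."""
    from scipy import stats as ss

    r, n = 0.7, 12
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
    p = 2 * ss.t.sf(t, df=n - 2)
    assert t == pytest.approx(3.0996, abs=1e-3)
    assert p == pytest.approx(0.0113, abs=5e-4)
    # the implementation reproduces the same formula on constructed data
    rng = np.random.default_rng(12)
    me = rng.normal(size=12)
    me = (me - me.mean()) / np.linalg.norm(me - me.mean())
    resid = rng.normal(size=12)
    resid -= resid.mean() + me * (resid @ me)  # orthogonalize
    gene = r * me / np.std(me) + np.sqrt(1 - r**2) * resid / np.std(resid)
    em = make_expression(gene[None, :], zts=list(range(1, 46, 4)), scale="log2")
    eig = dn.EigengeneSet(
        pd.DataFrame([me], index=[1], columns=em.sample_ids),
        pd.Series({1: 1.0}),
        em.samples,
    )
    mm, pv = dn.module_membership(em, eig)
    assert mm.at["g0", 1] == pytest.approx(0.7, abs=1e-9)
    assert pv.at["g0", 1] == pytest.approx(p, abs=1e-9)


# ---------------------------------------------------------------------------
# edge export
# ---------------------------------------------------------------------------

def test_edge_export_thresholds(tmp_path):
    a = np.full((3, 3), 0.5)
    np.fill_diagonal(a, 1.0)
    tom = dn.topological_overlap(dn.AdjacencyMatrix(pd.Index(list("abc")), a))
    mods = dn.ModuleAssignment(pd.Series([1, 1, 1], index=tom.gene_ids))
    e_mid = dn.export_network_edges(tom, mods, tmp_path / "e.tsv", threshold=0.1)
    assert len(e_mid) == 3
    e_all = dn.export_network_edges(tom, mods, tmp_path / "e.tsv", threshold=0.0)
    assert len(e_all) == 3  # n(n-1)/2
    e_none = dn.export_network_edges(tom, mods, tmp_path / "e.tsv", threshold=1.0)
    assert len(e_none) == 0
    with pytest.raises(ValueError):
        dn.export_network_edges(tom, mods, tmp_path / "e.tsv", threshold=1.5)


def test_module_recovery_on_default_synthetic(ww_pipeline):
    """Planted module structure is recovered from the WW network (ARI)."""
    from sklearn.metrics import adjusted_rand_score

    truth = ww_pipeline["truth"]
    detected = ww_pipeline["modules"].labels.reindex(truth.genes.index).fillna(0)
    ari = adjusted_rand_score(truth.labels_for_condition("WW"), detected)
    assert ari >= 0.8
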
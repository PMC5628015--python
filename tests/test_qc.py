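"""Probe-count normalization, modified-Z masking, replicate logic, enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

import dielnet as dn


def _table(counts, housekeeping=("hk1", "hk2", "hk3"), sets=None, pairs=None):
    samples = pd.DataFrame(
        {
            "condition": "WW",
            "zt": 1.0,
            "replicate": 1,
            "set": sets if sets is not None else 0,
            "is_reference": False,
        },
        index=counts.columns,
    )
    return dn.ProbeCountTable(counts, samples, list(housekeeping), list(pairs or []))


def _random_counts(n_probes=10, n_samples=8, seed=0):
    rng = np.random.default_rng(seed)
    idx = [f"p{i}" for i in range(n_probes - 3)] + ["hk1", "hk2", "hk3"]
    cols = [f"s{i}" for i in range(n_samples)]
    return pd.DataFrame(
        rng.poisson(500, size=(n_probes, n_samples)).astype(float), index=idx, columns=cols
    )


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def test_identical_samples_are_left_unchanged():
    counts = pd.DataFrame(
        np.tile([[100.0], [200.0], [50.0], [80.0]], (1, 5)),
        index=["hk1", "hk2", "hk3", "p1"],
        columns=[f"s{i}" for i in range(5)],
    )
    table = _table(counts)
    out = dn.normalize_probe_counts(table)
    pd.testing.assert_frame_equal(out.counts, counts)


def test_doubled_sample_is_rescaled_to_match():
    counts = _random_counts()
    counts["s0"] = counts["s1"] * 2.0  # same content, doubled depth
    out = dn.normalize_probe_counts(_table(counts))
    np.testing.assert_allclose(out.counts["s0"], out.counts["s1"], rtol=1e-9)


def test_housekeeping_geomeans_equal_after_normalization():
    counts = _random_counts(seed=3)
    out = dn.normalize_probe_counts(_table(counts))
    gms = [
        np.exp(np.mean(np.log(out.counts.loc[["hk1", "hk2", "hk3"], c])))
        for c in out.counts.columns
    ]
    assert max(gms) - min(gms) < 1e-9


def test_content_normalization_is_idempotent():
    counts = _random_counts(seed=4)
    once = dn.normalize_probe_counts(_table(counts))
    twice = dn.normalize_probe_counts(once)
    pd.testing.assert_frame_equal(once.counts, twice.counts)


def test_zero_housekeeping_count_rejects_sample():
    counts = _random_counts(seed=5)
    counts.loc["hk2", "s3"] = 0.0
    with pytest.raises(ValueError, match="s3"):
        dn.normalize_probe_counts(_table(counts))


def test_codeset_step_removes_set_factor():
    rng = np.random.default_rng(6)
    base = rng.poisson(400, size=(6, 1)).astype(float)
    # two sets measuring the same material; set 1 read twice as deep
    cols = ["a0", "a1", "ref_a", "b0", "b1", "ref_b"]
    counts = pd.DataFrame(
        np.hstack([base, base, base, 2 * base, 2 * base, 2 * base]),
        index=["p1", "p2", "p3", "hk1", "hk2", "hk3"],
        columns=cols,
    )
    samples = pd.DataFrame(
        {
            "condition": "WW",
            "zt": 1.0,
            "replicate": 1,
            "set": [0, 0, 0, 1, 1, 1],
            "is_reference": [False, False, True, False, False, True],
        },
        index=cols,
    )
    table = dn.ProbeCountTable(counts, samples, ["hk1", "hk2", "hk3"])
    out = dn.normalize_probe_counts(table)
    np.testing.assert_allclose(out.counts["a0"], out.counts["b0"], rtol=1e-9)


# ---------------------------------------------------------------------------
# modified Z-score filtering
# ---------------------------------------------------------------------------

def test_modified_z_hand_example():
    x = np.array([10.0, 12.0, 11.0, 10.0, 11.0, 50.0])
    counts = pd.DataFrame([x] * 4, index=["p1", "hk1", "hk2", "hk3"],
                          columns=[f"s{i}" for i in range(6)])
    z, flagged = dn.modified_zscore(counts)
    # median 11, MAD 1 -> M(50) = 0.6745 * 39 ~= 26.3
    expected = 0.6745 * (50.0 - 11.0) / 1.0
    assert z.at["p1", "s5"] == pytest.approx(expected, rel=1e-12)
    table = _table(counts)
    filtered, mask = dn.modified_zscore_filter(table, cut=3.0)
    assert mask.at["p1", "s5"]
    assert np.isnan(filtered.counts.at["p1", "s5"])


def test_constant_probe_masks_nothing():
    counts = pd.DataFrame(
        np.vstack([np.full(6, 7.0), _random_counts(4, 6, seed=7).to_numpy()[:3]]),
        index=["flat", "hk1", "hk2", "hk3"],
        columns=[f"s{i}" for i in range(6)],
    )
    _, mask = dn.modified_zscore_filter(_table(counts), cut=3.0)
    assert not mask.loc["flat"].any()


def test_mad_zero_fallback_uses_mean_ad():
    x = np.array([5.0, 5.0, 5.0, 5.0, 5.0, 100.0])
    counts = pd.DataFrame([x] * 4, index=["p1", "hk1", "hk2", "hk3"],
                          columns=[f"s{i}" for i in range(6)])
    z, flagged = dn.modified_zscore(counts)
    assert "p1" in flagged
    mean_ad = np.mean(np.abs(x - 5.0))
    assert z.at["p1", "s5"] == pytest.approx(0.7979 * 95.0 / mean_ad, rel=1e-12)


def test_planted_spikes_fully_masked_with_low_false_rate(probe_table):
    table, spikes = probe_table
    norm = dn.normalize_probe_counts(table)
    filtered, mask = dn.modified_zscore_filter(norm, cut=3.0)
    spiked = spikes.to_numpy()
    masked = mask.to_numpy()
    assert masked[spiked].all()  # every planted spike caught
    false_rate = masked[~spiked].mean()
    assert false_rate <= 0.01
    # flat housekeeping probes are essentially never flagged
    assert mask.loc[table.housekeeping].to_numpy().mean() <= 0.01


# ---------------------------------------------------------------------------
# technical replicates
# ---------------------------------------------------------------------------

def test_spiked_member_is_discarded():
    counts = _random_counts(n_samples=6, seed=8)
    counts["s5"] = counts["s4"]
    counts.loc["p0", "s5"] = counts.loc["p0", "s5"] * 10  # spike in s5
    table = _table(counts, pairs=[("s4", "s5")])
    kept = dn.choose_technical_replicate(table)
    assert "s4" in kept.counts.columns and "s5" not in kept.counts.columns


def test_identical_members_tie_breaks_lexicographically():
    counts = _random_counts(n_samples=6, seed=9)
    counts["s5"] = counts["s4"]
    table = _table(counts, pairs=[("s5", "s4")])
    kept = dn.choose_technical_replicate(table)
    assert "s4" in kept.counts.columns and "s5" not in kept.counts.columns


def test_kept_member_has_smaller_max_z(probe_table):
    table, _ = probe_table
    z, _ = dn.modified_zscore(table.counts)
    max_abs = z.abs().max(axis=0)
    kept = dn.choose_technical_replicate(table)
    for a, b in table.technical_pairs:
        survivor = a if a in kept.counts.columns else b
        other = b if survivor == a else a
        assert max_abs[survivor] <= max_abs[other]


def test_unpaired_member_rejected():
    counts = _random_counts()
    table = _table(counts)
    with pytest.raises(ValueError, match="unknown sample"):
        dn.choose_technical_replicate(table, [("s0", "nope")])


# ---------------------------------------------------------------------------
# replicate summary and per-timepoint tests
# ---------------------------------------------------------------------------

def test_replicate_summary_hand_computation():
    vals = {"WW": [1.0, 2.0, 3.0, 4.0, 5.0], "D": [1.0, 2.0, 3.0, 4.0, 5.0]}
    cols, data = [], []
    for cond, v in vals.items():
        for i, x in enumerate(v):
            cols.append(f"{cond}_b{i}")
            data.append(x)
    counts = pd.DataFrame(
        [data] * 4, index=["p1", "hk1", "hk2", "hk3"], columns=cols
    )
    samples = pd.DataFrame(
        {
            "condition": [c.split("_")[0] for c in cols],
            "zt": 1.0,
            "replicate": range(len(cols)),
            "set": 0,
            "is_reference": False,
        },
        index=cols,
    )
    table = dn.ProbeCountTable(counts, samples, ["hk1", "hk2", "hk3"])
    res = dn.replicate_summary_and_tests(table, alternative="less")
    row = res[(res["probe"] == "p1")].iloc[0]
    assert row["mean_ww"] == pytest.approx(3.0)
    assert row["se_ww"] == pytest.approx(math.sqrt(2.5) / math.sqrt(5), rel=1e-12)
    assert row["p"] == pytest.approx(0.5)  # identical groups


def test_direction_flip_symmetry_probe_tests(probe_table):
    table, _ = probe_table
    norm = dn.normalize_probe_counts(table)
    less = dn.replicate_summary_and_tests(norm, alternative="less")
    greater = dn.replicate_summary_and_tests(norm, alternative="greater")
    np.testing.assert_allclose(less["p"] + greater["p"], 1.0, atol=1e-9)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def test_enrichment_closed_form():
    universe = [f"g{i}" for i in range(100)]
    term = {"T": universe[:10]}
    gene_set = universe[:5]
    res = dn.enrichment_test(gene_set, term, universe)
    expected = math.comb(10, 5) / math.comb(100, 5)
    assert res.at[0, "p"] == pytest.approx(expected, rel=1e-9)


def test_term_equal_to_universe_gives_p_one():
    universe = [f"g{i}" for i in range(20)]
    res = dn.enrichment_test(universe[:5], {"ALL": universe}, universe)
    assert res.at[0, "p"] == pytest.approx(1.0)


def test_enrichment_matches_brute_force_small_universe():
    from test_compare import brute_hypergeom_tail

    rng = np.random.default_rng(13)
    universe = [f"g{i}" for i in range(25)]
    for _ in range(10):
        term_genes = list(rng.choice(universe, size=8, replace=False))
        gene_set = list(rng.choice(universe, size=6, replace=False))
        res = dn.enrichment_test(gene_set, {"T": term_genes}, universe)
        k = int(res.at[0, "overlap"])
        assert res.at[0, "p"] == pytest.approx(
            brute_hypergeom_tail(k, 25, 8, 6), abs=1e-10
        )


def test_random_sets_give_roughly_uniform_p():
    rng = np.random.default_rng(14)
    universe = [f"g{i}" for i in range(200)]
    terms = {
        f"T{j}": list(rng.choice(universe, size=20, replace=False)) for j in range(50)
    }
    gene_set = list(rng.choice(universe, size=30, replace=False))
    res = dn.enrichment_test(gene_set, terms, universe)
    # a random draw should not be systematically enriched
    assert res["p"].median() > 0.2
    assert (res["q"] < 0.01).sum() == 0


def test_small_terms_are_skipped_and_bad_inputs_rejected():
    universe = [f"g{i}" for i in range(30)]
    res = dn.enrichment_test(universe[:5], {"tiny": universe[:3]}, universe)
    assert len(res) == 0
    with pytest.raises(ValueError):
        dn.enrichment_test([], {"T": universe[:10]}, universe)
    with pytest.raises(ValueError):
        dn.enrichment_test(["zz"], {"T": universe[:10]}, universe)
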
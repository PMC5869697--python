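"""Drug-level aggregation: frequencies, empirical nulls, deciles, consistency."""

import numpy as np
import pandas as pd
import pytest

import revcon
from revcon.nbglm import bh_fdr
from revcon.summarize import (
    cumulative_enrichment_p,
    decile_fdr,
    directional_consistency,
    enrichment_frequency,
    gene_directionality,
    null_deg_threshold,
    spearman,
)
from revcon.tumour_sig import Signature


def _results(flags):
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(len(flags))],
        "drug_id": "d", "score": -0.5, "p": 0.01,
        "n_shared_genes": 10, "negative_enriched": flags,
    })


def test_enrichment_frequency_and_oracle():
    assert enrichment_frequency(_results([True] * 3 + [False] * 7)) == pytest.approx(0.30)
    rng = np.random.default_rng(0)
    for _ in range(5):
        flags = rng.random(20) < 0.4
        assert enrichment_frequency(_results(list(flags))) == pytest.approx(
            sum(flags) / 20)
    with pytest.raises(ValueError):
        enrichment_frequency(_results([]))


def test_null_deg_threshold_single_gene():
    # one uniform p: BH fdr = p, count = 1{p < 0.5}, whose 95th pct is 1
    assert null_deg_threshold(1, seed=0) == 1


def test_null_deg_threshold_monte_carlo_stability():
    a = null_deg_threshold(500, n_mc=10_000, seed=1)
    b = null_deg_threshold(500, n_mc=20_000, seed=2)
    assert abs(a - b) <= 1


def test_null_deg_threshold_monotone_in_genes():
    vals = [null_deg_threshold(n, n_mc=4000, seed=3) for n in (10, 100, 1000)]
    assert vals[0] <= vals[1] <= vals[2]


def test_null_deg_threshold_matches_direct_bh():
    """The vectorised chance-DEG count equals per-replicate BH counting."""
    rng = np.random.default_rng(4)
    from revcon.summarize import _bh_count
    for _ in range(20):
        p = np.sort(rng.random(40))
        assert _bh_count(p[None, :], 0.5)[0] == int((bh_fdr(p) < 0.5).sum())


def test_cumulative_enrichment_p():
    assert cumulative_enrichment_p(0.9, np.linspace(0, 0.8, 99)) == pytest.approx(1 / 100)
    assert cumulative_enrichment_p(0.0, np.array([0.0, 0.1])) == 1.0
    rng = np.random.default_rng(5)
    null = rng.random(50)
    for f in rng.random(10):
        expected = (1 + sum(n >= f for n in null)) / 51
        assert cumulative_enrichment_p(f, null) == pytest.approx(expected)
    with pytest.raises(ValueError):
        cumulative_enrichment_p(0.5, np.array([]))


def _summary_frame(n, cum_p=None, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "drug_id": [f"d{i:03d}" for i in range(n)],
        "pct_deg": rng.random(n) * 100,
        "cum_p": cum_p if cum_p is not None else rng.random(n),
    })


def test_decile_fdr_constants_and_single_per_decile():
    s = decile_fdr(_summary_frame(10, cum_p=[0.01] * 10))
    assert sorted(s["decile"]) == list(range(1, 11))
    np.testing.assert_allclose(s["fdr"], 0.01)  # one drug per decile: fdr = cum_p


def test_decile_fdr_matches_bruteforce_split():
    s = decile_fdr(_summary_frame(73, seed=6))
    for dec, grp in s.groupby("decile"):
        np.testing.assert_allclose(grp["fdr"], bh_fdr(grp["cum_p"].to_numpy()))
    sizes = s.groupby("decile").size()
    assert sizes.max() - sizes.min() <= 1


def test_spearman_basic_and_ties():
    assert spearman([1, 2, 3, 4], [10, 20, 30, 40])[0] == pytest.approx(1.0)
    assert spearman([1, 2, 3, 4], [4, 3, 2, 1])[0] == pytest.approx(-1.0)
    # tie-aware oracle: Pearson correlation of average ranks
    rng = np.random.default_rng(7)
    x = rng.integers(0, 5, 30).astype(float)
    y = rng.integers(0, 5, 30).astype(float)
    rx = pd.Series(x).rank().to_numpy()
    ry = pd.Series(y).rank().to_numpy()
    oracle = np.corrcoef(rx, ry)[0, 1]
    assert spearman(x, y)[0] == pytest.approx(oracle, abs=1e-12)
    with pytest.raises(ValueError):
        spearman([1, 1, 1], [1, 2, 3])


def _dir_sig(log2fc, fdr, kind="sample", cid="s0"):
    genes = [f"g{i}" for i in range(len(log2fc))]
    return Signature(kind, cid, pd.DataFrame(
        {"log2fc": log2fc, "p": fdr, "fdr": fdr}, index=genes), 0.1)


def test_gene_directionality_trivial_cases():
    group = _dir_sig([2.0, 1.0, -1.0], [0.001, 0.001, 0.5], "group", "all")
    samples = [_dir_sig([1.0, -1.0, 0.5], [0.001, 0.001, 0.9], cid=f"s{i}")
               for i in range(4)]
    d = gene_directionality(samples, group)
    assert d.loc["g0", "inclusion_freq"] == 1.0
    assert d.loc["g0", "frac_same_direction"] == 1.0
    assert d.loc["g1", "frac_same_direction"] == 0.0  # always opposite
    assert d.loc["g2", "inclusion_freq"] == 0.0
    assert np.isnan(d.loc["g2", "frac_same_direction"])  # outside group signature
    assert not d.loc["g2", "in_group_signature"]


def test_gene_directionality_planted_opposition(het_cohort, sample_signatures):
    """Private programs opposing the group effect show up as direction flips."""
    f, phi, truth = het_cohort["filtered"], het_cohort["phi"], het_cohort["truth"]
    group = revcon.make_signatures(f, phi, "group")[0]
    d = gene_directionality(sample_signatures, group, fdr_sample=0.5)
    included = d[d["in_group_signature"] & (d["inclusion_freq"] > 0)]
    assert (included["frac_same_direction"] < 1).any()
    assert included["frac_same_direction"].mean() > 0.5  # group direction dominates


def test_directional_consistency_identical_and_random():
    rng = np.random.default_rng(8)
    n_per_bin = 2000
    p1 = np.concatenate([rng.uniform(lo if lo else 1e-6, hi, n_per_bin)
                         for _, lo, hi in
                         (("a", 0.01, 0.1), ("b", 0.001, 0.01), ("c", 0.0, 0.001))])
    n = len(p1)
    s1 = rng.normal(size=n)
    same = pd.DataFrame({"score1": s1, "p1": p1, "score2": s1})
    rep = directional_consistency(same)
    occupied = rep.table[rep.table["n_pairs"] > 0]
    assert (occupied["same_sign_fraction"] == 1.0).all()
    indep = pd.DataFrame({"score1": s1, "p1": p1, "score2": rng.normal(size=n)})
    rep2 = directional_consistency(indep)
    occ2 = rep2.table[rep2.table["n_pairs"] > 0]
    assert ((occ2["same_sign_fraction"] - 0.5).abs() < 0.05).all()


def test_directional_consistency_empty_bin_reported():
    pairs = pd.DataFrame({"score1": [0.5], "p1": [0.05], "score2": [0.4]})
    rep = directional_consistency(pairs)
    assert rep.table.loc["p_lt_0.001", "n_pairs"] == 0
    assert np.isnan(rep.table.loc["p_lt_0.001", "same_sign_fraction"])
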
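"""Weighted-KS scoring, the combination rule and gene-label permutations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import revcon
from conftest import assert_es_agreement, brute_force_es
from revcon.connectivity import (
    QuerySignature,
    _combine,
    build_query,
    connectivity_score,
    drug_ranking,
    is_negative_enriched,
    permutation_p,
    weighted_es,
)
from revcon.nbglm import bh_fdr
from revcon.tumour_sig import Signature


def _sig(log2fc, fdr, genes=None):
    genes = genes or [f"g{i}" for i in range(len(log2fc))]
    table = pd.DataFrame({"log2fc": log2fc, "p": fdr, "fdr": fdr}, index=genes)
    return Signature("sample", "s0", table, 0.1)


def _drug(t_by_gene, drug_id="d0"):
    genes = list(t_by_gene)
    table = pd.DataFrame({
        "slope": 0.0, "moderated_t": list(t_by_gene.values()),
        "p": 0.5, "fdr": 0.5,
    }, index=genes)
    return revcon.DrugSignature(drug_id, table, None, 4, 1)


def test_build_query_rule_and_subset():
    sig = _sig([2.0, -1.0, 3.0], [0.005, 0.005, 0.5])
    q = build_query(sig)
    assert dict(q.up) == {"g0": 2.0}
    assert dict(q.down) == {"g1": 1.0}
    q2 = build_query(sig, gene_subset=["g1", "g2"])
    assert len(q2.up) == 0 and dict(q2.down) == {"g1": 1.0}
    q3 = build_query(sig, fdr_cutoff=0.001)
    assert q3.empty


def test_weighted_es_forced_extremes():
    ranked = ["a", "b", "c", "d"]
    assert weighted_es(ranked, {"a": 5.0}) == pytest.approx(1.0)
    assert weighted_es(ranked, {"d": 0.3}) == pytest.approx(-1.0)
    # entire ranking in the set
    assert weighted_es(ranked, {g: 1.0 for g in ranked}) == pytest.approx(1.0)


@settings(deadline=None, max_examples=80, derandomize=True)
@given(st.data())
def test_weighted_es_matches_running_sum(data):
    n = data.draw(st.integers(2, 12))
    ranked = [f"g{i}" for i in range(n)]
    m = data.draw(st.integers(1, n - 1))
    members = data.draw(st.permutations(ranked))[:m]
    weights = data.draw(st.lists(st.floats(0.1, 10), min_size=m, max_size=m))
    gene_set = dict(zip(members, weights))
    assert_es_agreement(weighted_es(ranked, gene_set),
                        brute_force_es(ranked, gene_set))


def test_combination_rule():
    assert _combine(np.asarray(1.0), np.asarray(-1.0)) == pytest.approx(1.0)
    assert _combine(np.asarray(-1.0), np.asarray(1.0)) == pytest.approx(-1.0)
    assert _combine(np.asarray(0.5), np.asarray(0.5)) == 0.0
    assert _combine(np.asarray(0.5), np.asarray(0.0)) == pytest.approx(0.25)


def test_score_bounds_and_min_shared():
    drug = _drug({f"g{i}": float(10 - i) for i in range(10)})
    q = QuerySignature("s", up=pd.Series({"g0": 1.0, "g5": 2.0}),
                       down=pd.Series({"g9": 1.0}))
    s = connectivity_score(q, drug, min_shared=3)
    assert s is not None and -1 <= s <= 1
    assert connectivity_score(q, drug, min_shared=5) is None
    q_off = QuerySignature("s", up=pd.Series({"x1": 1.0}), down=pd.Series(dtype=float))
    assert connectivity_score(q_off, drug, min_shared=1) is None


def test_antisymmetry_under_t_negation(het_cohort, sample_signatures, het_panel):
    q = build_query(sample_signatures[0])
    drug = next(iter(het_panel["sigs"].values()))
    flipped_table = drug.table.copy()
    flipped_table["moderated_t"] = -flipped_table["moderated_t"]
    flipped = revcon.DrugSignature("flip", flipped_table, None, 1, 1)
    s1 = connectivity_score(q, drug)
    s2 = connectivity_score(q, flipped)
    assert s1 == pytest.approx(-s2, abs=1e-12)


def test_permutation_p_plus_one_rule_and_zero_score():
    drug = _drug({f"g{i}": float(100 - i) for i in range(100)})
    q = QuerySignature("s", up=pd.Series({"g0": 1.0, "g1": 1.0, "g2": 1.0}),
                       down=pd.Series({"g97": 1.0, "g98": 1.0, "g99": 1.0}))
    score = connectivity_score(q, drug, min_shared=5)
    assert score == pytest.approx(1.0, abs=0.05)
    p = permutation_p(q, drug, score, n_perm=1000, seed=0)
    assert p == pytest.approx(1 / 1001)
    assert permutation_p(q, drug, 0.0, n_perm=50, seed=0) == 1.0


def test_negative_enrichment_definition_boundaries():
    cases = [
        (-0.5, 0.049, True), (-0.5, 0.05, False), (-0.5, 0.051, False),
        (0.0, 0.001, False), (0.5, 0.001, False), (-1e-9, 0.0499, True),
        (0.5, 0.9, False), (-0.5, 1.0, False),
    ]
    for score, p, expected in cases:
        assert is_negative_enriched(score, p) is expected


def test_query_recovers_private_program():
    """A planted sample's query captures most of its expressed private program.

    Recovery is assessed among program genes with baseline mean >= 50
    counts: below that, a contrast with a single tumour observation cannot
    reach 1% FDR regardless of method (a power limit, not a defect).
    """
    cfg = revcon.CohortConfig(
        n_tumour=3, n_normal=50, n_genes=1000, dispersion=0.1,
        frac_group_de=0.0, frac_subtype_de=0.0, frac_private_de=0.05,
        effect_log2fc_sd=2.0, seed=12,
    )
    cm, truth = revcon.generate_cohort(cfg)
    phi = revcon.estimate_cohort_dispersion(cm)
    sig = revcon.make_signatures(cm, phi, "sample")[0]
    q = build_query(sig)
    sid = sig.contrast_id
    prog = truth[truth["scope"] == f"sample:{sid}"]
    mu = dict(zip(cm.genes, cm.counts.attrs["baseline_mu"]))
    expressed = {g for g in prog["gene"] if mu[g] >= 50}
    got = set(q.up.index) | set(q.down.index)
    assert len(got & expressed) >= 0.8 * len(expressed)


def test_reversal_drug_detected(het_cohort, sample_signatures, het_panel):
    """A reversal drug is negatively enriched against its target sample."""
    labels = het_panel["panel"].truth.set_index("drug")
    drug_id = labels[labels["is_reversal"]].index[0]
    target = labels.loc[drug_id, "target_scope"].split(":", 1)[1]
    sig = next(s for s in sample_signatures if s.contrast_id == target)
    res = revcon.score_pair(build_query(sig), het_panel["sigs"][drug_id],
                            n_perm=200, global_seed=0)
    assert res.score < 0 and res.p < 0.05 and res.negative_enriched


def test_drug_ranking_deterministic_ties():
    drug = _drug({"b": 1.0, "a": 1.0, "c": 2.0})
    assert list(drug_ranking(drug)) == ["c", "a", "b"]
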
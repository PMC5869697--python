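"""Fitted-generator extraction, batch simulation and the enrichment null."""

import numpy as np
import pytest

import revcon
from revcon import simnull
from revcon.io import rng_for
from revcon.nbglm import fit_nb_glm


@pytest.fixture(scope="module")
def group_fit():
    cfg = revcon.CohortConfig(
        n_tumour=100, n_normal=20, n_genes=400, dispersion=0.1,
        frac_group_de=0.1, frac_subtype_de=0.05, frac_private_de=0.0,
        effect_log2fc_sd=1.0, seed=20,
    )
    cm, truth = revcon.generate_cohort(cfg)
    counts = cm.counts.to_numpy(float)
    offsets = np.log(cm.library_sizes().to_numpy(float))
    tm = cm.tissue_mask("tumour")
    X = np.column_stack([np.ones(cm.n_samples), tm.astype(float)])
    fit = fit_nb_glm(counts, X, offsets, 0.1)
    return {"cm": cm, "truth": truth, "fit": fit, "counts": counts,
            "offsets": offsets, "tumour_mask": tm}


def test_extract_generator_round_trip(group_fit):
    """Extracted mu matches the planted tumour-condition mean at unit depth."""
    cm, truth = group_fit["cm"], group_fit["truth"]
    tm = group_fit["tumour_mask"]
    depths = cm.library_sizes().to_numpy(float)[tm]
    gen = simnull.extract_generator(group_fit["fit"], np.array([1.0, 1.0]),
                                    depths, "group", genes=cm.genes)
    mu_base = cm.counts.attrs["baseline_mu"]
    # planted tumour mean per unit library size: scale to the offset convention
    prog = truth[truth["scope"] == "group"].set_index("gene")["true_log2fc"]
    lfc = np.zeros(cm.n_genes)
    lfc[cm.genes.get_indexer(prog.index)] = prog.to_numpy()
    # subtype effects average into the group fit; compare on non-subtype genes
    sub_genes = set(truth.loc[truth["scope"].str.startswith("subtype:"), "gene"])
    keep = ~cm.genes.isin(sub_genes)
    expected = mu_base * np.exp2(lfc)
    # offsets are log library size, so mu is per library-size unit: rescale
    scale = np.median(gen.mu[keep] / expected[keep])
    rel = np.abs(gen.mu[keep] / (expected[keep] * scale) - 1)
    assert np.median(rel) < 0.05
    assert gen.size == pytest.approx(10.0)


def test_poisson_generator_flagged(group_fit):
    fit = fit_nb_glm(group_fit["counts"][:50], group_fit["fit"].design,
                     group_fit["offsets"], 0.0)
    libsizes = group_fit["cm"].library_sizes().to_numpy(float)
    # constant depth pool: the marginal is pure Poisson, not a depth mixture
    gen = simnull.extract_generator(fit, np.array([1.0, 1.0]),
                                    np.full(5, libsizes.mean()), "group")
    assert gen.poisson
    counts, _, _ = simnull.simulate_batch(gen, 400, rng_for(0))
    m = counts.mean(axis=1)
    v = counts.var(axis=1, ddof=1)
    keep = m > 5
    assert abs((v[keep] / m[keep]).mean() - 1.0) < 0.05


def test_subtype_generator_differs_on_subtype_genes(group_fit):
    """Subtype vs group generators differ exactly where subtype effects sit."""
    cm, truth = group_fit["cm"], group_fit["truth"]
    counts, offsets = group_fit["counts"], group_fit["offsets"]
    meta = cm.metadata
    st0 = (meta["subtype"] == "S0").to_numpy()
    normals = (meta["tissue"] == "normal").to_numpy()
    used = st0 | normals
    X = np.column_stack([np.ones(used.sum()), st0[used].astype(float)])
    fit0 = fit_nb_glm(counts[:, used], X, offsets[used], 0.1)
    gen0 = simnull.extract_generator(fit0, np.array([1.0, 1.0]), np.ones(5), "subtype:0")
    gen_g = simnull.extract_generator(group_fit["fit"], np.array([1.0, 1.0]),
                                      np.ones(5), "group")
    ratio = np.abs(np.log2(gen0.mu) - np.log2(gen_g.mu))
    s0_genes = cm.genes.isin(truth.loc[truth["scope"] == "subtype:0", "gene"])
    mu_base = cm.counts.attrs["baseline_mu"]
    detectable = s0_genes & (mu_base > 20)
    background = ~cm.genes.isin(truth["gene"]) & (mu_base > 20)
    assert np.median(ratio[detectable]) > 5 * np.median(ratio[background])


def test_simulate_batch_moments_and_determinism(group_fit):
    cm = group_fit["cm"]
    tm = group_fit["tumour_mask"]
    depths = cm.library_sizes().to_numpy(float)[tm]
    gen = simnull.extract_generator(group_fit["fit"], np.array([1.0, 1.0]),
                                    depths, "group", genes=cm.genes)
    c1, d1, w1 = simnull.simulate_batch(gen, 1000, rng_for(7))
    c2, d2, w2 = simnull.simulate_batch(gen, 1000, rng_for(7))
    np.testing.assert_array_equal(c1, c2)
    np.testing.assert_array_equal(d1, d2)
    m = c1.mean(axis=1)
    expected = d1.mean() * gen.mu
    keep = expected > 20
    se = np.sqrt((expected + 0.1 * expected**2) / 1000)
    frac_within = (np.abs(m - expected) < 3 * se + 0.03 * expected)[keep].mean()
    assert frac_within > 0.95


def test_mixture_draws_sources_in_proportion(group_fit):
    gen_a = simnull.FittedGenerator(mu=np.ones(10), size=10.0,
                                    depth_pool=np.ones(3), source="a")
    gen_b = simnull.FittedGenerator(mu=np.ones(10) * 2, size=10.0,
                                    depth_pool=np.ones(3), source="b")
    _, _, which = simnull.simulate_batch([gen_a, gen_b], 2000, rng_for(1),
                                         proportions=[0.25, 0.75])
    assert (which == 1).mean() == pytest.approx(0.75, abs=0.04)


def test_two_batches_interval_is_min_max(group_fit, het_panel):
    cm = group_fit["cm"]
    tm = group_fit["tumour_mask"]
    # a tiny, fast null run: 2 batches -> the interval degenerates to min/max
    depths = cm.library_sizes().to_numpy(float)[tm]
    gen = simnull.extract_generator(group_fit["fit"], np.array([1.0, 1.0]),
                                    depths, "group", genes=cm.genes)
    dsig = next(iter(het_panel["sigs"].values()))
    table = dsig.table.copy()
    rng = np.random.default_rng(0)
    table = table.iloc[:0]
    import pandas as pd
    table = pd.DataFrame({
        "slope": 0.0, "moderated_t": rng.normal(size=cm.n_genes),
        "p": 0.5, "fdr": 0.5}, index=cm.genes)
    drug = revcon.DrugSignature("null", table, None, 4, 1)
    out = simnull.null_enrichment_distribution(
        gen, {"null": drug},
        normals=group_fit["counts"][:, ~tm],
        normal_offsets=group_fit["offsets"][~tm],
        genes=cm.genes, phi=0.1, n_batches=2, batch_size=5, n_perm=39, seed=0,
    )
    vals = out["table"]["null"].to_numpy()
    lo, hi = out["per_drug"]["null"]["interval"]
    assert lo == vals.min() and hi == vals.max()


def test_fast_path_matches_public_scoring(group_fit, het_panel):
    """The batched enrichment counter reproduces score_pair flag for flag."""
    cm = group_fit["cm"]
    tm = group_fit["tumour_mask"]
    counts, offsets = group_fit["counts"], group_fit["offsets"]
    sub = np.flatnonzero(tm)[:6]
    drug_sigs = {}
    for d, sig in list(het_panel["sigs"].items())[:2]:
        aligned = sig.table.reindex(cm.genes)
        aligned["moderated_t"] = np.random.default_rng(3).normal(size=cm.n_genes)
        drug_sigs[d] = revcon.DrugSignature(d, aligned, None, 4, 1)
    counts_fast = simnull.observed_negative_counts(
        counts[:, sub], counts[:, ~tm], offsets[~tm], cm.genes, 0.1,
        drug_sigs, n_perm=99, seed=5,
    )
    # public path: per-sample signatures -> queries -> score_pair
    lfc, p = revcon.tumour_sig.one_vs_rest_block(
        counts, offsets,
        np.broadcast_to(np.flatnonzero(~tm), (6, int((~tm).sum()))), sub, 0.1)
    from revcon.tumour_sig import _signature_from_arrays
    expected = {d: 0 for d in drug_sigs}
    for j, s_idx in enumerate(sub):
        sig = _signature_from_arrays(cm.genes, lfc[:, j], p[:, j], "sample",
                                     f"sim{j}", 0.1)
        q = revcon.build_query(sig)
        if q.empty:
            continue
        for d, dsig in drug_sigs.items():
            score = revcon.connectivity_score(q, dsig)
            if score is None or score >= 0:
                continue
            pv = revcon.permutation_p(q, dsig, score, n_perm=99,
                                      rng=rng_for(5, "observed", j, d))
            if score < 0 and pv < 0.05:
                expected[d] += 1
    assert counts_fast == expected
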
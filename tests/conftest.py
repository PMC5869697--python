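import numpy as np
import pandas as pd
import pytest

import revcon


@pytest.fixture(scope="session")
def het_cohort():
    """Heterogeneous cohort with strong planted effects, filtered, with phi.

    Shared across tests: 10 tumours (group + subtype + private programs),
    30 normals for per-sample power, effect magnitude 2 log2 units.
    """
    cfg = revcon.CohortConfig(
        n_tumour=10, n_normal=30, n_genes=500, effect_log2fc_sd=2.0,
        dispersion=0.1, seed=2,
    )
    cm, truth = revcon.generate_cohort(cfg)
    filtered = revcon.filter_low_expressed(cm)
    phi = revcon.estimate_cohort_dispersion(filtered)
    return {"config": cfg, "cm": cm, "truth": truth, "filtered": filtered, "phi": phi}


@pytest.fixture(scope="session")
def sample_signatures(het_cohort):
    return revcon.make_signatures(het_cohort["filtered"], het_cohort["phi"], "sample")


@pytest.fixture(scope="session")
def het_panel(het_cohort):
    cfg = revcon.DrugPanelConfig(
        n_drugs=10, frac_reversal_drugs=0.3, frac_no_control=0.1,
        noise_sd=0.3, seed=3,
    )
    panel = revcon.generate_drug_panel(
        cfg, het_cohort["truth"], het_cohort["filtered"].genes,
        subtype_of=revcon.subtype_scope_map(het_cohort["cm"].metadata),
    )
    sigs, status = revcon.fit_drug_panel(panel)
    return {"config": cfg, "panel": panel, "sigs": sigs, "status": status}


def brute_force_bh(p):
    """Step-up definition evaluated literally: fdr_(i) = min_{j>=i} p_(j)*n/j."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    out = np.empty(n)
    for rank_pos, idx in enumerate(order):
        candidates = [p[order[j]] * n / (j + 1) for j in range(rank_pos, n)]
        out[idx] = min(1.0, min(candidates))
    return out


def brute_force_es(ranked, gene_set):
    """Literal running-sum evaluation of the weighted KS statistic."""
    total_w = sum(gene_set.values())
    n = len(ranked)
    n_hit = len(gene_set)
    running = 0.0
    best_pos, best_neg = 0.0, 0.0
    for g in ranked:
        if g in gene_set:
            running += gene_set[g] / total_w
        else:
            running -= 1.0 / (n - n_hit)
        best_pos = max(best_pos, running)
        best_neg = min(best_neg, running)
    return best_pos if best_pos >= -best_neg else best_neg


def assert_es_agreement(es, oracle, tol=1e-9):
    """Compare enrichment scores, tolerating the sign flip of an exact tie.

    When the positive and negative running-sum extrema tie in magnitude, a
    different floating-point accumulation order can legitimately flip which
    one is reported; magnitudes must always agree.
    """
    assert abs(abs(es) - abs(oracle)) < tol
    if abs(es + oracle) > tol:  # not an opposite-sign tie
        assert abs(es - oracle) < tol
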
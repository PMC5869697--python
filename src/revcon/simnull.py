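"""Simulation study: is per-sample enrichment explainable by the group model?

The fitted group (or subtype) NB model is turned into a generator: per-gene
mean mu at unit depth and size = 1/phi, plus the pool of observed tumour
depth factors.  Batches of pseudo-samples are drawn from it, pushed through
the full per-sample pipeline (signature -> query -> connectivity vs each
drug, against the real normal samples), and the per-batch counts of
negatively enriched samples give an empirical 95% interval per drug.  An
observed count far above the interval means the individual-sample analysis
captures heterogeneity the aggregated model cannot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import (
    DEFAULT_MIN_SHARED,
    DEFAULT_QUERY_FDR,
    NEG_P_CUTOFF,
    _combine,
    _es_from_positions,
    _permute_scores,
    drug_ranking,
)
from .io import rng_for
from .nbglm import NBFit
from .tumour_sig import intercept_nb_fit, one_vs_rest_block

logger = logging.getLogger("revcon")

DEFAULT_N_BATCHES = 200
DEFAULT_BATCH_SIZE = 50


@dataclass
class FittedGenerator:
    """Per-gene (mu at unit depth, size) plus an empirical depth pool."""

    mu: np.ndarray
    size: float                  # 1/phi; np.inf flags the Poisson limit
    depth_pool: np.ndarray
    source: str
    genes: pd.Index = None
    fallback_flagged: np.ndarray = field(default=None)

    @property
    def poisson(self) -> bool:
        return np.isinf(self.size)


@dataclass
class SimBatchResult:
    batch_id: int
    neg_counts: dict            # drug id -> negatively enriched sample count


def extract_generator(
    fit: NBFit,
    x_condition: np.ndarray,
    depth_pool: np.ndarray,
    source: str,
    genes: pd.Index | None = None,
    fallback_mu: np.ndarray | None = None,
) -> FittedGenerator:
    """Generator from a fitted contrast: mu = exp(x_condition' beta).

    ``x_condition`` is the covariate vector of the condition to simulate
    (e.g. (1, 1) for the tumour condition of an intercept+indicator
    design); offsets are excluded so mu is the mean at unit depth.
    Unconverged genes fall back to ``fallback_mu`` (typically the observed
    depth-corrected group mean) and are flagged.
    """
    mu = np.exp(fit.beta @ np.asarray(x_condition, dtype=float))
    flagged = ~fit.converged
    if flagged.any():
        if fallback_mu is not None:
            mu = np.where(flagged, fallback_mu, mu)
        logger.warning("%d unconverged genes fell back to observed means",
                       int(flagged.sum()))
    size = np.inf if fit.dispersion == 0 else 1.0 / fit.dispersion
    return FittedGenerator(
        mu=np.maximum(mu, 1e-8), size=size,
        depth_pool=np.asarray(depth_pool, dtype=float),
        source=source, genes=genes, fallback_flagged=flagged,
    )


def observed_group_mean(counts: np.ndarray, depths: np.ndarray) -> np.ndarray:
    """Depth-corrected per-gene mean, the fallback for unconverged fits."""
    return counts.mean(axis=1) / depths.mean()


def simulate_batch(
    generator: FittedGenerator | list,
    n_samples: int,
    rng: np.random.Generator,
    proportions: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw a batch of pseudo-tumour counts.

    ``generator`` is one FittedGenerator or a list of them (the subtype
    mixture), in which case each sample's generator is drawn from
    ``proportions``.  Depths are resampled with replacement from the pool.
    Returns (counts genes x n_samples, depths, source index per sample).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    gens = generator if isinstance(generator, list) else [generator]
    if proportions is None:
        proportions = np.ones(len(gens)) / len(gens)
    which = rng.choice(len(gens), size=n_samples, p=np.asarray(proportions, dtype=float))
    n_genes = len(gens[0].mu)
    counts = np.empty((n_genes, n_samples), dtype=np.int64)
    depths = np.empty(n_samples)
    for i in range(n_samples):
        g = gens[which[i]]
        d = g.depth_pool[rng.integers(len(g.depth_pool))]
        mean = d * g.mu
        if g.poisson:
            counts[:, i] = rng.poisson(mean)
        else:
            counts[:, i] = rng.negative_binomial(g.size, g.size / (g.size + mean))
        depths[i] = d
    return counts, depths, which


def _bh_matrix(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values along axis 0 (genes), vectorised."""
    n = p.shape[0]
    order = np.argsort(p, axis=0)
    ps = np.take_along_axis(p, order, axis=0)
    adj = ps * n / np.arange(1, n + 1)[:, None]
    adj = np.minimum(np.minimum.accumulate(adj[::-1], axis=0)[::-1], 1.0)
    out = np.empty_like(adj)
    np.put_along_axis(out, order, adj, axis=0)
    return out


def _gene_positions(rankings: dict, genes: pd.Index) -> dict:
    """Per drug: position of each universe gene in the drug's t-ranking."""
    pos = {}
    for drug, ranking in rankings.items():
        idx = genes.get_indexer(ranking)
        if (idx < 0).any() or len(ranking) != len(genes):
            raise ValueError("drug signatures must cover the tumour gene universe")
        p = np.empty(len(genes), dtype=np.int64)
        p[idx] = np.arange(len(genes))
        pos[drug] = p
    return pos


def _batch_neg_counts(
    sim_counts: np.ndarray,
    normals: np.ndarray,
    normal_offsets: np.ndarray,
    phi: float,
    gene_pos: dict,
    query_fdr: float,
    min_shared: int,
    n_perm: int,
    batch_seed_parts: tuple,
    bg_fit=None,
) -> dict:
    """Per-sample pipeline on one simulated batch -> per-drug enrichment counts.

    This is the numpy fast path of signature -> query -> connectivity:
    identical statistics to the public API, with gene ids replaced by
    integer positions so 10^4 batches stay affordable.  ``bg_fit`` is the
    (reusable) intercept fit of the normal panel.
    """
    n_sim = sim_counts.shape[1]
    combined = np.concatenate([normals, sim_counts], axis=1)
    offsets = np.concatenate([normal_offsets, np.log(sim_counts.sum(axis=0))])
    n_norm = normals.shape[1]
    bg = np.broadcast_to(np.arange(n_norm), (n_sim, n_norm))
    col = n_norm + np.arange(n_sim)
    lfc, p = one_vs_rest_block(combined, offsets, bg, col, phi, bg_fit=bg_fit)
    fdr = _bh_matrix(p)
    hit = fdr < query_fdr
    up = hit & (lfc > 0)
    down = hit & (lfc < 0)
    n_genes = lfc.shape[0]

    counts_out = {drug: 0 for drug in gene_pos}
    for i in range(n_sim):
        up_i = np.flatnonzero(up[:, i])
        dn_i = np.flatnonzero(down[:, i])
        if len(up_i) + len(dn_i) < max(min_shared, 1):
            continue
        w_up = np.abs(lfc[up_i, i])
        w_dn = np.abs(lfc[dn_i, i])
        for drug, pos in gene_pos.items():
            eu = _es_from_positions(pos[up_i], w_up, n_genes) if len(up_i) else 0.0
            ed = _es_from_positions(pos[dn_i], w_dn, n_genes) if len(dn_i) else 0.0
            score = float(_combine(np.asarray(eu), np.asarray(ed)))
            if score >= 0:
                continue  # cannot be negatively enriched; skip the permutations
            rng = rng_for(*batch_seed_parts, i, drug)
            perm = _permute_scores(rng, n_perm, n_genes, w_up, w_dn)
            pv = (1 + np.sum(np.abs(perm) >= abs(score))) / (n_perm + 1)
            if pv < NEG_P_CUTOFF:
                counts_out[drug] += 1
    return counts_out


def observed_negative_counts(
    tumour_counts: np.ndarray,
    normals: np.ndarray,
    normal_offsets: np.ndarray,
    genes: pd.Index,
    phi: float,
    drug_sigs: dict,
    n_perm: int = 200,
    query_fdr: float = DEFAULT_QUERY_FDR,
    min_shared: int = DEFAULT_MIN_SHARED,
    seed: int = 0,
) -> dict:
    """Observed per-drug negative-enrichment counts of the real tumour samples.

    Uses the same per-sample pipeline (and permutation budget) as the
    simulated batches, so observed and simulated counts are comparable.
    """
    rankings = {drug: drug_ranking(sig) for drug, sig in drug_sigs.items()}
    gene_pos = _gene_positions(rankings, genes)
    bg_fit = intercept_nb_fit(np.asarray(normals, dtype=float), normal_offsets, phi)
    return _batch_neg_counts(
        np.asarray(tumour_counts, dtype=float), normals, normal_offsets, phi,
        gene_pos, query_fdr, min_shared, n_perm,
        batch_seed_parts=(seed, "observed"), bg_fit=bg_fit,
    )


def null_enrichment_distribution(
    generator,
    drug_sigs: dict,
    normals: np.ndarray,
    normal_offsets: np.ndarray,
    genes: pd.Index,
    phi: float,
    n_batches: int = DEFAULT_N_BATCHES,
    batch_size: int = DEFAULT_BATCH_SIZE,
    observed_counts: dict | None = None,
    proportions: np.ndarray | None = None,
    n_perm: int = 200,
    query_fdr: float = DEFAULT_QUERY_FDR,
    min_shared: int = DEFAULT_MIN_SHARED,
    seed: int = 0,
    max_skip_fraction: float = 0.1,
) -> dict:
    """Simulated null distribution of per-drug negative-enrichment counts.

    Each batch re-runs the full per-sample pipeline against the real normal
    samples.  Returns per-drug empirical (2.5%, 97.5%) intervals over
    batches and, when ``observed_counts`` is given, the observed/endpoint
    fold ratios.  Per-batch seeds derive from (seed, batch_id).
    """
    if n_batches < 2:
        raise ValueError("need at least 2 batches for an interval")
    rankings = {drug: drug_ranking(sig) for drug, sig in drug_sigs.items()}
    gene_pos = _gene_positions(rankings, genes)
    bg_fit = intercept_nb_fit(np.asarray(normals, dtype=float), normal_offsets, phi)
    results: list[SimBatchResult] = []
    skipped = 0
    for b in range(n_batches):
        rng = rng_for(seed, "simnull-batch", b)
        try:
            sim_counts, _, _ = simulate_batch(
                generator, batch_size, rng, proportions=proportions
            )
            neg = _batch_neg_counts(
                sim_counts, normals, normal_offsets, phi,
                gene_pos, query_fdr, min_shared, n_perm,
                batch_seed_parts=(seed, "simnull-perm", b), bg_fit=bg_fit,
            )
            results.append(SimBatchResult(batch_id=b, neg_counts=neg))
        except Exception as exc:  # batch-level robustness: skip, log, bound
            skipped += 1
            logger.warning("batch %d failed (%s); skipped", b, exc)
            if skipped > max_skip_fraction * n_batches:
                raise RuntimeError(
                    f"{skipped} of {n_batches} simulation batches failed"
                ) from exc

    table = pd.DataFrame([r.neg_counts for r in results])
    out = {"batches": results, "table": table, "per_drug": {}}
    for drug in table.columns:
        vals = table[drug].to_numpy()
        lo = float(np.percentile(vals, 2.5, method="lower"))
        hi = float(np.percentile(vals, 97.5, method="higher"))
        entry = {
            "interval": (lo, hi),
            "n_batches": len(results),
            "batch_size": batch_size,
        }
        if observed_counts is not None and drug in observed_counts:
            obs = float(observed_counts[drug])
            entry["observed_count"] = obs
            entry["fold_ratios"] = (
                obs / lo if lo > 0 else np.inf,
                obs / hi if hi > 0 else np.inf,
            )
        out["per_drug"][drug] = entry
    return out
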
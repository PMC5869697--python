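"""Weighted Kolmogorov-Smirnov connectivity between tumour and drug signatures.

A tumour query is split into up- and down-regulated gene sets (genes under
1% FDR, weighted by |log2 fold change|).  Drug genes are ranked by
decreasing moderated t (ties broken by gene id, so the ranking is
deterministic), and each set's enrichment score is the signed extremum of
the classic weighted running sum: a hit at gene j adds w_j / sum(w), a miss
subtracts 1/(N - N_hit).  The two scores combine as

    score = (es_up - es_down) / 2   if the signs differ or one is zero,
    score = 0                       otherwise,

so score < 0 means the drug's expression changes oppose the tumour
signature (up genes pushed down and/or down genes pushed up).  Significance
comes from resampling the gene labels: random disjoint sets of the same
sizes (weights retained) on the drug's gene universe, with the two-sided
empirical p = (1 + #{|score_perm| >= |score|}) / (n_perm + 1).

Negative enrichment — the operational criterion for therapeutic potential —
is a negative score with permutation P < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import rng_for
from .tumour_sig import Signature

logger = logging.getLogger("revcon")

DEFAULT_QUERY_FDR = 0.01
DEFAULT_MIN_SHARED = 5
DEFAULT_N_PERM = 1000
NEG_P_CUTOFF = 0.05

_PERM_CHUNK = 2000


@dataclass
class QuerySignature:
    """Up/down weighted gene sets of one tumour contrast."""

    sample_id: str
    up: pd.Series      # gene -> weight (|log2fc|), log2fc > 0
    down: pd.Series    # gene -> weight, log2fc < 0

    @property
    def empty(self) -> bool:
        return len(self.up) == 0 and len(self.down) == 0


@dataclass
class ConnectivityResult:
    sample_id: str
    drug_id: str
    score: float
    p: float
    n_shared_genes: int
    negative_enriched: bool


def is_negative_enriched(score: float, p: float) -> bool:
    return bool(score < 0 and p < NEG_P_CUTOFF)


def aggregated_n_perm(n_perm: int, n_tumour_samples: int) -> int:
    """Permutation budget for group/subtype queries: n_perm per tumour sample."""
    return int(n_perm * n_tumour_samples)


def build_query(
    sig: Signature,
    fdr_cutoff: float = DEFAULT_QUERY_FDR,
    gene_subset=None,
) -> QuerySignature:
    """Threshold a tumour signature into weighted up/down sets.

    ``gene_subset`` restricts the query to a platform's measured genes (the
    landmark-gene restriction) before thresholding.  A query with both sets
    empty is UNSCORABLE against every drug.
    """
    table = sig.table
    if len(table) == 0:
        raise ValueError("empty signature")
    if gene_subset is not None:
        table = table.loc[table.index.intersection(pd.Index(gene_subset))]
    hits = table[(table["fdr"] < fdr_cutoff) & (table["log2fc"] != 0)]
    up = hits[hits["log2fc"] > 0]["log2fc"]
    down = hits[hits["log2fc"] < 0]["log2fc"].abs()
    return QuerySignature(sample_id=str(sig.contrast_id), up=up, down=down)


def drug_ranking(drug_sig) -> pd.Index:
    """Drug genes ordered by decreasing moderated t; ties by gene id."""
    t = drug_sig.moderated_t
    order = np.lexsort((t.index.to_numpy(), -t.to_numpy()))
    return t.index[order]


def _es_from_positions(pos: np.ndarray, w: np.ndarray, n_ranked: int) -> np.ndarray:
    """Signed KS extremum from hit positions, vectorised over leading axes.

    ``pos``: (..., m) 0-based positions of the set genes in the ranking,
    ``w``: weights aligned with pos (broadcastable).  The running sum's
    extrema occur at hit positions (candidates for the maximum) and just
    before hit positions (candidates for the minimum); ties between the
    positive and negative extremum resolve to the positive one.
    """
    pos = np.asarray(pos)
    w = np.broadcast_to(np.asarray(w, dtype=float), pos.shape)
    m = pos.shape[-1]
    order = np.argsort(pos, axis=-1)
    pos_s = np.take_along_axis(pos, order, axis=-1)
    w_s = np.take_along_axis(w, order, axis=-1)
    cumw = np.cumsum(w_s, axis=-1)
    total = cumw[..., -1:]
    j = np.arange(m)
    if n_ranked == m:
        return np.ones(pos.shape[:-1])
    miss = 1.0 / (n_ranked - m)
    at_hit = cumw / total - (pos_s - j) * miss
    before_hit = np.concatenate(
        [np.zeros(pos.shape[:-1] + (1,)), cumw[..., :-1]], axis=-1
    ) / total - (pos_s - j) * miss
    max_dev = at_hit.max(axis=-1)
    min_dev = np.minimum(before_hit.min(axis=-1), 0.0)
    return np.where(max_dev >= -min_dev, max_dev, min_dev)


def weighted_es(ranked_genes, gene_set: pd.Series | dict) -> float:
    """Weighted KS enrichment of one gene set against a ranked gene list."""
    gene_set = pd.Series(gene_set, dtype=float)
    if len(gene_set) == 0:
        raise ValueError("empty gene set has no enrichment score")
    if (gene_set <= 0).any():
        raise ValueError("weights must be positive")
    ranked = pd.Index(ranked_genes)
    if ranked.has_duplicates:
        raise ValueError("ranked gene list contains duplicates")
    pos = ranked.get_indexer(gene_set.index)
    if (pos < 0).any():
        raise ValueError("gene set contains genes absent from the ranking")
    return float(_es_from_positions(pos, gene_set.to_numpy(), len(ranked)))


def _combine(es_up: np.ndarray, es_down: np.ndarray) -> np.ndarray:
    """Two-set combination: (es_up - es_down)/2 when signs differ or one is 0."""
    opposed = (np.sign(es_up) != np.sign(es_down)) | (es_up == 0) | (es_down == 0)
    return np.where(opposed, (es_up - es_down) / 2.0, 0.0)


def connectivity_score(
    query: QuerySignature,
    drug_sig,
    min_shared: int = DEFAULT_MIN_SHARED,
    ranking: pd.Index | None = None,
) -> float | None:
    """Combined connectivity score, or None for an UNSCORABLE pair.

    Query genes absent from the drug platform are dropped; the pair is
    scorable only when at least ``min_shared`` query genes remain.  A set
    that is empty after the drop contributes an enrichment score of 0.
    """
    if ranking is None:
        ranking = drug_ranking(drug_sig)
    up = query.up[query.up.index.isin(ranking)]
    down = query.down[query.down.index.isin(ranking)]
    if len(up) + len(down) < min_shared:
        return None
    es_up = weighted_es(ranking, up) if len(up) else 0.0
    es_down = weighted_es(ranking, down) if len(down) else 0.0
    return float(_combine(np.asarray(es_up), np.asarray(es_down)))


def _permute_scores(
    rng: np.random.Generator,
    n_perm: int,
    n_ranked: int,
    w_up: np.ndarray,
    w_down: np.ndarray,
) -> np.ndarray:
    """Null scores from random disjoint up/down sets of the observed sizes."""
    m_up, m_down = len(w_up), len(w_down)
    m = m_up + m_down
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        chunk = min(_PERM_CHUNK, n_perm - done)
        u = rng.random((chunk, n_ranked))
        pos = np.argpartition(u, m - 1, axis=1)[:, :m]
        eu = _es_from_positions(pos[:, :m_up], w_up, n_ranked) if m_up else np.zeros(chunk)
        ed = (_es_from_positions(pos[:, m_up:], w_down, n_ranked)
              if m_down else np.zeros(chunk))
        out[done:done + chunk] = _combine(eu, ed)
        done += chunk
    return out


def permutation_p(
    query: QuerySignature,
    drug_sig,
    score: float,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    ranking: pd.Index | None = None,
) -> float:
    """Two-sided gene-label permutation p-value with the +1 convention."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if ranking is None:
        ranking = drug_ranking(drug_sig)
    w_up = query.up[query.up.index.isin(ranking)].to_numpy()
    w_down = query.down[query.down.index.isin(ranking)].to_numpy()
    perm = _permute_scores(rng, n_perm, len(ranking), w_up, w_down)
    return float((1 + np.sum(np.abs(perm) >= abs(score))) / (n_perm + 1))


def score_pair(
    query: QuerySignature,
    drug_sig,
    n_perm: int = DEFAULT_N_PERM,
    min_shared: int = DEFAULT_MIN_SHARED,
    global_seed: int = 0,
    ranking: pd.Index | None = None,
) -> ConnectivityResult | None:
    """Score + permutation p for one (sample, drug) pair; None if UNSCORABLE."""
    if ranking is None:
        ranking = drug_ranking(drug_sig)
    if query.empty:
        return None
    score = connectivity_score(query, drug_sig, min_shared=min_shared, ranking=ranking)
    if score is None:
        return None
    rng = rng_for(global_seed, query.sample_id, drug_sig.drug_id)
    p = permutation_p(query, drug_sig, score, n_perm=n_perm, rng=rng, ranking=ranking)
    n_shared = int(query.up.index.isin(ranking).sum() + query.down.index.isin(ranking).sum())
    return ConnectivityResult(
        sample_id=query.sample_id, drug_id=drug_sig.drug_id,
        score=score, p=p, n_shared_genes=n_shared,
        negative_enriched=is_negative_enriched(score, p),
    )


def connect_all(
    queries: list[QuerySignature],
    drug_sigs: dict,
    n_perm: int = DEFAULT_N_PERM,
    min_shared: int = DEFAULT_MIN_SHARED,
    global_seed: int = 0,
) -> pd.DataFrame:
    """Score every (query, drug) pair; UNSCORABLE pairs are omitted.

    Group and subtype queries should be passed with an ``n_perm`` already
    scaled by the number of tumour samples, per the permutation-budget
    convention for aggregated signatures.
    """
    rows = []
    n_unscorable = 0
    for drug_id, dsig in drug_sigs.items():
        ranking = drug_ranking(dsig)
        for q in queries:
            res = score_pair(q, dsig, n_perm=n_perm, min_shared=min_shared,
                             global_seed=global_seed, ranking=ranking)
            if res is None:
                n_unscorable += 1
            else:
                rows.append(res)
    if n_unscorable:
        logger.info("connect_all: %d UNSCORABLE pairs excluded (fewer than "
                    "%d shared query genes)", n_unscorable, min_shared)
    return pd.DataFrame(
        [(r.sample_id, r.drug_id, r.score, r.p, r.n_shared_genes, r.negative_enriched)
         for r in rows],
        columns=["sample_id", "drug_id", "score", "p", "n_shared_genes",
                 "negative_enriched"],
    )
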
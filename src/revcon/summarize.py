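"""Aggregation of connectivity results into drug-level evidence.

Per drug: the fraction of scored tumour samples that are negatively
enriched (UNSCORABLE pairs excluded from numerator and denominator); an
empirical cumulative P locating that fraction in the distribution observed
for "empty" drug signatures (those with fewer DEG than expected by chance
95% of the time under a uniform-p Monte Carlo null); and BH FDR applied
separately within each decile of signature quality (%DEG).  Also: the
quality/enrichment Spearman correlation, gene inclusion/directionality
profiles against the group signature, and replicate sign-consistency
binned by first-analysis P.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .nbglm import bh_fdr
from .tumour_sig import Signature

CONSISTENCY_BINS = (
    ("p_0.01_0.1", 0.01, 0.1),
    ("p_0.001_0.01", 0.001, 0.01),
    ("p_lt_0.001", 0.0, 0.001),
)


@dataclass
class ConsistencyReport:
    """Same-sign fraction of replicate connectivity scores per P interval."""

    table: pd.DataFrame  # index bin label; columns n_pairs, same_sign_fraction


def enrichment_frequency(results: pd.DataFrame) -> float:
    """Fraction of scored samples negatively enriched, for one drug's rows."""
    if len(results) == 0:
        raise ValueError("drug has zero scored samples")
    return float(results["negative_enriched"].mean())


def _bh_count(p_sorted: np.ndarray, cutoff: float) -> np.ndarray:
    """#genes under BH FDR < cutoff for each row of sorted p-values."""
    n = p_sorted.shape[-1]
    j = np.arange(1, n + 1)
    ok = p_sorted < cutoff * j / n
    rev = np.flip(ok, axis=-1)
    first_true = np.argmax(rev, axis=-1)
    any_true = rev.max(axis=-1)
    return np.where(any_true, n - first_true, 0)


def null_deg_threshold(
    n_genes: int,
    fdr_cutoff: float = 0.5,
    n_mc: int = 10_000,
    seed: int = 0,
) -> int:
    """95th percentile of chance DEG counts under uniform p-values.

    Drug signatures with fewer DEG than this threshold are treated as
    statistically empty and form the null set for the cumulative P.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    counts = np.empty(n_mc, dtype=int)
    chunk = max(1, min(n_mc, int(2e7) // max(n_genes, 1)))
    done = 0
    while done < n_mc:
        b = min(chunk, n_mc - done)
        p = np.sort(rng.random((b, n_genes)), axis=1)
        counts[done:done + b] = _bh_count(p, fdr_cutoff)
        done += b
    return int(np.percentile(counts, 95, method="higher"))


def cumulative_enrichment_p(neg_freq: float, null_freqs: np.ndarray) -> float:
    """Empirical P of a drug's negative-enrichment frequency vs the null drugs."""
    null_freqs = np.asarray(null_freqs, dtype=float)
    if null_freqs.size == 0:
        raise ValueError(
            "empty null-drug set: no drug signature fell below the chance-DEG "
            "threshold; lower the threshold or supply more drugs"
        )
    return float((1 + np.sum(null_freqs >= neg_freq)) / (null_freqs.size + 1))


def summarize_drugs(
    results: pd.DataFrame,
    pct_deg_by_drug: dict,
    deg_count_by_drug: dict,
    null_threshold: int,
    min_null_drugs: int = 20,
) -> pd.DataFrame:
    """Drug-level table: neg_freq, cum_p, pct_deg decile, per-decile FDR.

    Drugs with zero scored samples are dropped with a warning.  The null
    set are drugs whose DEG count is below ``null_threshold``.
    """
    import logging
    logger = logging.getLogger("revcon")

    rows = []
    for drug_id, grp in results.groupby("drug_id"):
        if len(grp) == 0:
            continue
        rows.append({
            "drug_id": drug_id,
            "n_scored_samples": int(len(grp)),
            "neg_freq": enrichment_frequency(grp),
            "pct_deg": float(pct_deg_by_drug[drug_id]),
            "deg_count": int(deg_count_by_drug[drug_id]),
        })
    dropped = set(pct_deg_by_drug) - {r["drug_id"] for r in rows}
    if dropped:
        logger.warning("dropped %d drugs with zero scored samples", len(dropped))
    summary = pd.DataFrame(rows)
    if len(summary) == 0:
        raise ValueError("no drug has scored samples")

    null_mask = summary["deg_count"] < null_threshold
    if null_mask.sum() < min_null_drugs:
        logger.warning("only %d null drugs (< %d); cumulative P is unstable",
                       int(null_mask.sum()), min_null_drugs)
    null_freqs = summary.loc[null_mask, "neg_freq"].to_numpy()
    summary["cum_p"] = [cumulative_enrichment_p(f, null_freqs)
                        for f in summary["neg_freq"]]
    summary = decile_fdr(summary)
    return summary


def decile_fdr(summary: pd.DataFrame) -> pd.DataFrame:
    """Assign pct_deg deciles (rank-based, ties by drug id) and BH within each."""
    if len(summary) < 10:
        raise ValueError("need at least 10 drugs for decile-wise FDR")
    summary = summary.sort_values(["pct_deg", "drug_id"]).reset_index(drop=True)
    n = len(summary)
    summary["decile"] = (np.arange(n) * 10) // n + 1
    fdr = np.empty(n)
    for _, idx in summary.groupby("decile").groups.items():
        fdr[np.asarray(idx)] = bh_fdr(summary.loc[idx, "cum_p"].to_numpy())
    summary["fdr"] = fdr
    return summary


def spearman(x, y) -> tuple[float, float]:
    """Tie-aware Spearman rank correlation with t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def gene_directionality(
    sample_signatures: list[Signature],
    group_signature: Signature,
    fdr_sample: float = 0.01,
    group_fdr: float = 0.01,
) -> pd.DataFrame:
    """Per-gene inclusion frequency and agreement with the group direction.

    ``inclusion_freq`` is the fraction of sample signatures containing the
    gene at ``fdr_sample``; ``frac_same_direction`` is, among those
    inclusions, the fraction whose log2fc sign matches the group signature
    (thresholded at ``group_fdr``).  Genes outside the thresholded group
    signature get ``in_group_signature = False`` and NaN agreement; genes
    never included get NaN agreement.
    """
    genes = group_signature.table.index
    group_hits = group_signature.table["fdr"] < group_fdr
    group_sign = np.sign(group_signature.table["log2fc"])

    incl = np.zeros(len(genes))
    same = np.zeros(len(genes))
    for sig in sample_signatures:
        tab = sig.table.reindex(genes)
        included = (tab["fdr"] < fdr_sample).to_numpy()
        incl += included
        same += included & (np.sign(tab["log2fc"]) == group_sign).to_numpy()
    n = len(sample_signatures)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_same = np.where(incl > 0, same / np.maximum(incl, 1), np.nan)
    frac_same = np.where(group_hits, frac_same, np.nan)
    return pd.DataFrame({
        "inclusion_freq": incl / n,
        "frac_same_direction": frac_same,
        "in_group_signature": group_hits,
    }, index=genes)


def directional_consistency(pairs: pd.DataFrame) -> ConsistencyReport:
    """Sign agreement of replicate scores, binned by the first replicate's P.

    ``pairs`` needs columns score1, p1, score2.  A zero score counts as a
    sign mismatch against a nonzero partner (and as a match against zero).
    """
    rows = []
    for label, lo, hi in CONSISTENCY_BINS:
        sel = pairs[(pairs["p1"] >= lo) & (pairs["p1"] < hi)]
        if len(sel) == 0:
            rows.append({"bin": label, "n_pairs": 0, "same_sign_fraction": np.nan})
            continue
        same = np.sign(sel["score1"]) == np.sign(sel["score2"])
        rows.append({
            "bin": label,
            "n_pairs": int(len(sel)),
            "same_sign_fraction": float(same.mean()),
        })
    return ConsistencyReport(table=pd.DataFrame(rows).set_index("bin"))
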
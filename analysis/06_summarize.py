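"""Drug-level evidence: enrichment frequencies, empirical-null P, decile FDR,
quality correlation, gene directionality, replicate consistency."""

import importlib
import json

import pandas as pd

import revcon
from revcon.io import read_signature
from revcon.plots import negfreq_vs_pctdeg

from analysis_config import (
    DEG_FDR,
    DSIGS,
    MIN_SHARED,
    N_PERM,
    QUERY_FDR,
    RESULTS,
    SEED,
    SIGS,
)

def main() -> None:
    results = pd.read_csv(RESULTS / "connectivity_results.tsv", sep="\t")
    panel_summary = json.loads((DSIGS / "panel_summary.json").read_text())
    ok = {d: e for d, e in panel_summary.items() if e["status"] == "OK"}

    n_genes = len(pd.read_csv(DSIGS / f"{next(iter(ok))}.tsv", sep="\t", index_col=0))
    thr = revcon.null_deg_threshold(n_genes, fdr_cutoff=DEG_FDR, seed=SEED)
    print(f"chance-DEG threshold (95th pct of {n_genes} uniform p-values "
          f"under BH<{DEG_FDR}): {thr} genes")

    summary = revcon.summarize_drugs(
        results,
        {d: e["pct_deg"] for d, e in ok.items()},
        {d: e["deg_count"] for d, e in ok.items()},
        null_threshold=thr,
    )
    summary.to_csv(RESULTS / "drug_summary.tsv", sep="\t", index=False)
    negfreq_vs_pctdeg(summary, RESULTS / "fig_negfreq_vs_pctdeg")

    rho, p = revcon.spearman(summary["pct_deg"], summary["neg_freq"])
    print(f"Spearman rho(%DEG, negative-enrichment frequency) = {rho:.2f} (P = {p:.2g})")

    hits = summary[(summary["cum_p"] < 0.05) & (summary["fdr"] < 0.10)]
    print(f"{len(hits)} drugs with cumulative-enrichment P < 0.05 and decile FDR < 10%:")
    for _, r in hits.sort_values("neg_freq", ascending=False).head(8).iterrows():
        print(f"  {r['drug_id']}: {100 * r['neg_freq']:.0f}% of samples, "
              f"%DEG {r['pct_deg']:.0f}, cum P {r['cum_p']:.3f}, FDR {r['fdr']:.3f}")

    sample_sigs = [read_signature(p) for p in sorted(SIGS.glob("sample_*.tsv"))]
    group_sig = read_signature(SIGS / "group_all_tumours.tsv")
    for fdr_s in (0.01, 0.5):
        d = revcon.gene_directionality(sample_sigs, group_sig, fdr_sample=fdr_s)
        included = d[d["in_group_signature"] & (d["inclusion_freq"] > 0)]
        opp = (included["frac_same_direction"] < 1).mean()
        d.to_csv(RESULTS / f"gene_directionality_fdr{int(fdr_s * 100)}.tsv", sep="\t")
        print(f"FDR<{int(fdr_s * 100)}%: {100 * opp:.0f}% of included group-signature "
              "genes appear in the opposite direction in at least one sample")

    # technical replicates: re-measure the same cohort (new count noise on the
    # same planted truth) and re-run the per-sample analysis from scratch
    import dataclasses
    from analysis_config import COHORT
    cm2, _ = revcon.generate_cohort(dataclasses.replace(COHORT, count_noise_seed=1))
    cm2 = cm2.subset_genes(group_sig.table.index)
    phi2 = revcon.estimate_cohort_dispersion(cm2)
    rep_sigs = revcon.make_signatures(cm2, phi2, "sample")
    rep_queries = [revcon.build_query(s, fdr_cutoff=QUERY_FDR) for s in rep_sigs]
    rep_queries = [q for q in rep_queries if not q.empty]
    drug_sigs = importlib.import_module("05_connectivity").load_drug_sigs()
    rep = revcon.connect_all(rep_queries, drug_sigs, n_perm=N_PERM,
                             min_shared=MIN_SHARED, global_seed=SEED + 1000)
    merged = results.merge(rep, on=["sample_id", "drug_id"], suffixes=("1", "2"))
    report = revcon.directional_consistency(merged[["score1", "p1", "score2"]])
    report.table.to_csv(RESULTS / "replicate_consistency.tsv", sep="\t")
    print("technical-replicate sign consistency by first-analysis P interval:")
    print(report.table.to_string())

    # different samples from the same patients (paired tumour samples)
    meta = pd.read_csv(RESULTS / "data" / "cohort_sample_metadata.tsv", sep="\t")
    tum = meta[meta["tissue"] == "tumour"]
    pair_rows = []
    for _, grp in tum.groupby("patient_id"):
        if len(grp) == 2:
            a, b = grp["sample_id"].tolist()
            ra = results[results["sample_id"] == a].set_index("drug_id")
            rb = results[results["sample_id"] == b].set_index("drug_id")
            for d in ra.index.intersection(rb.index):
                pair_rows.append({"score1": ra.loc[d, "score"], "p1": ra.loc[d, "p"],
                                  "score2": rb.loc[d, "score"]})
    if pair_rows:
        pat = revcon.directional_consistency(pd.DataFrame(pair_rows))
        print("same-patient different-sample sign consistency:")
        print(pat.table.to_string())

if __name__ == "__main__":
    main()
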
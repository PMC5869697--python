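"""Score every (tumour-sample signature, drug signature) pair; flag negative enrichment."""

import json

import pandas as pd

import revcon
from revcon.drug_sig import DrugSignature, STATUS_OK
from revcon.io import read_signature

from analysis_config import DSIGS, MIN_SHARED, N_PERM, QUERY_FDR, RESULTS, SEED, SIGS

def load_drug_sigs() -> dict:
    summary = json.loads((DSIGS / "panel_summary.json").read_text())
    out = {}
    for drug, entry in summary.items():
        if entry["status"] != STATUS_OK:
            continue
        table = pd.read_csv(DSIGS / f"{drug}.tsv", sep="\t", index_col=0)
        out[drug] = DrugSignature(drug_id=drug, table=table, ebayes=None,
                                  n_experiments=0, n_cell_lines=0)
    return out

def main() -> None:
    drug_sigs = load_drug_sigs()
    queries = []
    for p in sorted(SIGS.glob("sample_*.tsv")):
        q = revcon.build_query(read_signature(p), fdr_cutoff=QUERY_FDR)
        if q.empty:
            print(f"sample {q.sample_id}: UNSCORABLE (no genes under "
                  f"{QUERY_FDR:.0%} FDR)")
            continue
        queries.append(q)

    results = revcon.connect_all(queries, drug_sigs, n_perm=N_PERM,
                                 min_shared=MIN_SHARED, global_seed=SEED)
    results.to_csv(RESULTS / "connectivity_results.tsv", sep="\t", index=False)

    agg_queries = []
    for pattern in ("group_*.tsv", "subtype_*.tsv"):
        for p in sorted(SIGS.glob(pattern)):
            q = revcon.build_query(read_signature(p), fdr_cutoff=QUERY_FDR)
            if not q.empty:
                agg_queries.append(q)
    agg = revcon.connect_all(
        agg_queries, drug_sigs,
        n_perm=revcon.aggregated_n_perm(N_PERM, len(queries)),
        min_shared=MIN_SHARED, global_seed=SEED,
    )
    agg.to_csv(RESULTS / "connectivity_results_aggregated.tsv", sep="\t", index=False)

    neg = results[results["negative_enriched"]]
    print(f"{len(results)} scored (sample, drug) pairs; "
          f"{len(neg)} negatively enriched (score < 0, permutation P < 0.05)")
    top = (neg.groupby("drug_id").size().sort_values(ascending=False).head(5))
    print("most frequently negatively enriched drugs:")
    for drug, n in top.items():
        print(f"  {drug}: {n} of {results['sample_id'].nunique()} samples")

if __name__ == "__main__":
    main()
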
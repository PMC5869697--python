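"""Fit per-drug linear models with eBayes moderation; score signature quality."""

import json

import numpy as np

import revcon
from revcon.drug_sig import STATUS_OK
from revcon.io import read_drug_panel

from analysis_config import DATA, DEG_FDR, DSIGS

def main() -> None:
    panel = read_drug_panel(DATA / "panel")
    sigs, status = revcon.fit_drug_panel(panel)
    n_un = sum(1 for s in status.values() if s != STATUS_OK)
    print(f"{len(status)} drugs, {n_un} UNPROCESSABLE "
          f"({100 * n_un / len(status):.1f}%, no controls or degenerate design)")

    DSIGS.mkdir(parents=True, exist_ok=True)
    summary = {}
    for drug, st in status.items():
        entry = {"status": st}
        if st == STATUS_OK:
            sig = sigs[drug]
            sig.table.rename_axis("gene").to_csv(DSIGS / f"{drug}.tsv", sep="\t")
            entry["pct_deg"] = revcon.pct_deg(sig, DEG_FDR)
            entry["deg_count"] = int((sig.table["fdr"] < DEG_FDR).sum())
        summary[drug] = entry
    (DSIGS / "panel_summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))

    truth = panel.truth.set_index("drug")
    pd_rev = [summary[d]["pct_deg"] for d in summary
              if summary[d]["status"] == STATUS_OK and truth.loc[d, "is_reversal"]]
    pd_null = [summary[d]["pct_deg"] for d in summary
               if summary[d]["status"] == STATUS_OK and not truth.loc[d, "is_reversal"]]
    print(f"median %DEG (FDR<50%): reversal drugs {np.median(pd_rev):.1f}, "
          f"null drugs {np.median(pd_null):.1f}")

if __name__ == "__main__":
    main()
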
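"""Generate the synthetic tumour cohort and drug panel with known ground truth."""

import json

import revcon
from revcon.io import write_counts, write_drug_panel

from analysis_config import COHORT, DATA, PANEL

def main() -> None:
    cm, truth = revcon.generate_cohort(COHORT)
    DATA.mkdir(parents=True, exist_ok=True)
    write_counts(cm, DATA)
    truth.to_csv(DATA / "cohort_truth.tsv", sep="\t", index=False)

    panel = revcon.generate_drug_panel(
        PANEL, truth, cm.genes, subtype_of=revcon.subtype_scope_map(cm.metadata)
    )
    write_drug_panel(panel, DATA / "panel")

    n_rev = int(panel.truth["is_reversal"].sum())
    n_nc = int((~panel.truth["has_control"]).sum())
    summary = {
        "n_genes": cm.n_genes,
        "n_tumour": len(cm.tumour_samples()),
        "n_normal": len(cm.normal_samples()),
        "n_truth_records": len(truth),
        "n_drugs": len(panel.drugs),
        "n_reversal_drugs": n_rev,
        "n_drugs_without_controls": n_nc,
    }
    (DATA / "simulation_summary.json").write_text(json.dumps(summary, indent=1))
    print("cohort:", cm.counts.shape, f"({summary['n_tumour']} tumour, "
          f"{summary['n_normal']} normal), {summary['n_truth_records']} planted effects")
    print(f"panel: {summary['n_drugs']} drugs, {n_rev} reversal, "
          f"{n_nc} generated without controls")

if __name__ == "__main__":
    main()
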
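"""Filter lowly expressed genes (CPM > 0.5 in at least a sixth of samples)."""

import revcon
from revcon.io import read_counts

from analysis_config import DATA, RESULTS

def main() -> None:
    cm = read_counts(DATA / "cohort_counts.tsv", DATA / "cohort_gene_lengths.tsv",
                     DATA / "cohort_sample_metadata.tsv")
    filtered = revcon.filter_low_expressed(cm)
    filtered.counts.rename_axis("gene").to_csv(RESULTS / "filtered_counts.tsv", sep="\t")
    norm = revcon.normalize_length_depth(filtered)
    norm.values.rename_axis("gene").to_csv(RESULTS / "normalized_expression.tsv", sep="\t")
    pct = 100 * (1 - filtered.n_genes / cm.n_genes)
    print(f"retained {filtered.n_genes} of {cm.n_genes} genes "
          f"({pct:.0f}% removed by the CPM filter)")

if __name__ == "__main__":
    main()
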
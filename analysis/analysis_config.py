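"""Shared settings for the numbered analysis scripts.

One synthetic study at desk scale: a heterogeneous tumour cohort (group,
subtype and per-sample private expression programs) plus a drug panel in
which a fifth of the drugs reverse a tumour program.  All scripts write
under results/ and read what earlier scripts wrote.
"""

from pathlib import Path

import revcon

SEED = 17
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
DATA = RESULTS / "data"
SIGS = RESULTS / "tumour_signatures"
DSIGS = RESULTS / "drug_signatures"

COHORT = revcon.CohortConfig(
    n_tumour=30,
    n_normal=20,
    n_genes=1500,
    n_subtypes=4,
    effect_log2fc_sd=2.0,
    dispersion=0.1,
    stage_private_gradient=0.5,
    frac_paired_patients=0.4,
    seed=SEED,
)

PANEL = revcon.DrugPanelConfig(
    n_drugs=40,
    frac_reversal_drugs=0.2,
    frac_no_control=0.05,
    noise_sd=0.5,
    seed=SEED + 1,
)

QUERY_FDR = 0.01
DEG_FDR = 0.5
N_PERM = 1000
MIN_SHARED = 5
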
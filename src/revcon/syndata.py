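"""Synthetic tumour cohorts and drug-perturbation panels with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: negative-binomially distributed RNA-seq counts whose means carry a
cohort-wide tumour program, per-subtype programs and per-sample private
programs, and log-scale drug-perturbation experiments in which a subset of
"reversal" drugs move expression in the direction opposite to one of the
planted tumour programs, proportionally to drug concentration.

Every planted effect is recorded in a truth table so recovery can be tested
end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import TISSUE_NORMAL, TISSUE_TUMOUR, CountMatrix

SCOPE_GROUP = "group"


def _scope_subtype(k) -> str:
    return f"subtype:{k}"


def _scope_sample(sample_id) -> str:
    return f"sample:{sample_id}"


@dataclass
class CohortConfig:
    """Parameters of the synthetic tumour/normal cohort.

    Counts for gene g in sample i are NB with mean
    ``depth_i * mu_g * 2**(sum of planted log2 fold changes that apply)``
    and variance ``mu + dispersion * mu**2`` (size = 1/dispersion).
    Baseline means mu_g are log-normal (meanlog 4, sdlog 1.5 by default) to
    mimic the dynamic range of RNA-seq, which gives the CPM filter realistic
    behaviour.  Planted effects have fixed magnitude ``effect_log2fc_sd``
    with random sign, so recovery tolerances stay sharp.

    ``stage_private_gradient`` scales each tumour's private-program fraction
    with its stage: fraction = frac_private_de * (1 + gradient * (stage - 1)).
    ``frac_paired_patients`` makes that fraction of tumour samples arrive as
    two samples from one patient (shared subtype and stage, hence shared
    group/subtype programs, but independent private programs).
    ``count_noise_seed`` selects the count-noise stream independently of the
    cohort structure: changing it alone re-measures the same planted truth,
    i.e. produces a technical replicate.
    """

    n_tumour: int = 20
    n_normal: int = 10
    n_genes: int = 2000
    n_subtypes: int = 4
    subtype_props: tuple = None
    frac_group_de: float = 0.10
    frac_subtype_de: float = 0.05
    frac_private_de: float = 0.05
    effect_log2fc_sd: float = 1.0
    dispersion: float = 0.1
    depth_range: tuple = (0.5, 2.0)
    mu_meanlog: float = 4.0
    mu_sdlog: float = 1.5
    n_stages: int = 4
    stage_private_gradient: float = 0.0
    frac_paired_patients: float = 0.0
    seed: int = 0
    count_noise_seed: int = 0

    def __post_init__(self) -> None:
        if self.subtype_props is None:
            self.subtype_props = tuple([1.0 / self.n_subtypes] * self.n_subtypes)
        if self.n_genes <= 0 or self.n_tumour <= 0 or self.n_normal <= 0:
            raise ValueError("cohort needs at least one gene, tumour and normal sample")
        props = np.asarray(self.subtype_props, dtype=float)
        if len(props) != self.n_subtypes or not np.isclose(props.sum(), 1.0):
            raise ValueError("subtype_props must have n_subtypes entries summing to 1")
        for name in ("frac_group_de", "frac_subtype_de", "frac_private_de",
                     "frac_paired_patients"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not (0 < self.depth_range[0] <= self.depth_range[1]):
            raise ValueError("depth_range must be positive and ordered")


@dataclass
class DrugPanelConfig:
    """Parameters of the synthetic drug-perturbation panel.

    Each drug is profiled across cell lines x concentrations x durations;
    concentration 0 columns are the vehicle controls.  Reversal drugs get a
    per-gene effect of ``-reversal_strength`` times the log2 fold change of
    an assigned tumour program; the concentration covariate scales that
    effect linearly, so the fitted concentration slope targets
    ``-reversal_strength * true_log2fc``.  A fraction of drugs is generated
    without control columns, which downstream modelling must refuse.
    """

    n_drugs: int = 50
    n_cell_lines: int = 3
    concentrations: tuple = (0.0, 1.0, 10.0)
    durations: tuple = (6, 24)
    n_batches: int = 2
    frac_reversal_drugs: float = 0.2
    reversal_strength: float = 1.0
    frac_no_control: float = 0.0
    noise_sd: float = 0.5
    baseline_mean: float = 6.0
    baseline_sd: float = 1.5
    covariate_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_reversal_drugs", "frac_no_control"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_drugs <= 0:
            raise ValueError("need at least one drug")
        if 0.0 not in [float(c) for c in self.concentrations]:
            raise ValueError("concentrations must include 0 (controls)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class DrugPanel:
    """Per-drug expression matrices plus per-column metadata and truth labels."""

    expression: dict
    metadata: pd.DataFrame
    truth: pd.DataFrame

    @property
    def drugs(self) -> list:
        return list(self.expression)


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0.0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mean))


def generate_cohort(config: CohortConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw a synthetic cohort; returns the count matrix and its truth table.

    Normals carry no planted effects.  Private programs are sampled without
    replacement within a sample and may overlap between samples.
    """
    rng = np.random.default_rng(config.seed)
    genes = pd.Index([f"g{i:05d}" for i in range(config.n_genes)], name="gene")
    mu = rng.lognormal(config.mu_meanlog, config.mu_sdlog, size=config.n_genes)
    lengths = pd.Series(
        rng.integers(300, 10_000, size=config.n_genes), index=genes, name="length_bp"
    )

    tumour_ids = [f"T{i:04d}" for i in range(config.n_tumour)]
    normal_ids = [f"N{i:04d}" for i in range(config.n_normal)]
    sample_ids = tumour_ids + normal_ids
    n_samples = len(sample_ids)

    # patient ids: paired tumours share a patient (and subtype/stage)
    n_paired = int(round(config.frac_paired_patients * config.n_tumour / 2.0)) * 2
    patient_ids = []
    for i in range(config.n_tumour):
        if i < n_paired:
            patient_ids.append(f"P{i // 2:04d}")
        else:
            patient_ids.append(f"P{(n_paired // 2) + (i - n_paired):04d}")
    patient_ids += [f"PN{i:04d}" for i in range(config.n_normal)]

    subtypes_t = rng.choice(config.n_subtypes, size=config.n_tumour,
                            p=np.asarray(config.subtype_props, dtype=float))
    stages_t = rng.integers(1, config.n_stages + 1, size=config.n_tumour)
    for i in range(0, n_paired, 2):  # second of a pair inherits subtype/stage
        subtypes_t[i + 1] = subtypes_t[i]
        stages_t[i + 1] = stages_t[i]

    depth = np.exp(rng.uniform(np.log(config.depth_range[0]),
                               np.log(config.depth_range[1]), size=n_samples))

    effect = config.effect_log2fc_sd
    truth_rows: list[tuple] = []
    lfc = np.zeros((config.n_genes, n_samples))

    def plant(scope: str, n_de: int, columns: np.ndarray) -> None:
        if n_de == 0:
            return
        idx = rng.choice(config.n_genes, size=n_de, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        for g, s in zip(idx, signs):
            truth_rows.append((genes[g], scope, s * effect))
        lfc[np.ix_(idx, np.flatnonzero(columns))] += (signs * effect)[:, None]

    is_tumour = np.array([True] * config.n_tumour + [False] * config.n_normal)
    plant(SCOPE_GROUP, int(round(config.frac_group_de * config.n_genes)), is_tumour)
    for k in range(config.n_subtypes):
        cols = np.zeros(n_samples, dtype=bool)
        cols[:config.n_tumour] = subtypes_t == k
        if cols.any():
            plant(_scope_subtype(k), int(round(config.frac_subtype_de * config.n_genes)), cols)
    for i, sid in enumerate(tumour_ids):
        frac = config.frac_private_de * (1.0 + config.stage_private_gradient * (stages_t[i] - 1))
        cols = np.zeros(n_samples, dtype=bool)
        cols[i] = True
        plant(_scope_sample(sid), int(round(min(frac, 1.0) * config.n_genes)), cols)

    # count noise on its own stream: the same cohort structure can be
    # re-measured (a technical replicate) by changing count_noise_seed only
    mean = depth[None, :] * mu[:, None] * np.exp2(lfc)
    rng_counts = np.random.default_rng([config.seed, config.count_noise_seed])
    counts = _draw_counts(rng_counts, mean, config.dispersion)

    metadata = pd.DataFrame({
        "sample_id": sample_ids,
        "patient_id": patient_ids,
        "tissue": [TISSUE_TUMOUR] * config.n_tumour + [TISSUE_NORMAL] * config.n_normal,
        "subtype": [f"S{k}" for k in subtypes_t] + ["NA"] * config.n_normal,
        "stage": list(stages_t) + [0] * config.n_normal,
        "depth": depth,
    })
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=sample_ids),
        lengths=lengths,
        metadata=metadata,
    )
    truth = pd.DataFrame(truth_rows, columns=["gene", "scope", "true_log2fc"])
    cm.counts.attrs["baseline_mu"] = mu
    return cm, truth


def truth_program(
    truth: pd.DataFrame,
    scope: str,
    subtype_of: dict | None = None,
) -> pd.Series:
    """The planted expression program of one scope, as gene -> total log2fc.

    A scope's program is the full profile a sample of that scope carries:
    group effects apply to every tumour, subtype scopes add their subtype's
    effects, and sample scopes add that sample's private effects (plus its
    subtype's, when ``subtype_of`` maps sample id -> subtype scope label).
    Effects on the same gene sum, exactly as they do in the count means.
    """
    scopes = [SCOPE_GROUP]
    if scope.startswith("subtype:"):
        scopes.append(scope)
    elif scope.startswith("sample:"):
        scopes.append(scope)
        if subtype_of:
            sid = scope.split(":", 1)[1]
            if sid in subtype_of:
                scopes.append(subtype_of[sid])
    sub = truth[truth["scope"].isin(scopes)]
    return sub.groupby("gene")["true_log2fc"].sum()


def subtype_scope_map(metadata: pd.DataFrame) -> dict:
    """sample id -> subtype scope label, for tumour samples of a cohort."""
    tum = metadata[metadata["tissue"] == TISSUE_TUMOUR]
    return {
        sid: _scope_subtype(str(st).lstrip("S"))
        for sid, st in zip(tum["sample_id"], tum["subtype"])
    }


def generate_drug_panel(
    config: DrugPanelConfig,
    truth: pd.DataFrame,
    genes,
    subtype_of: dict | None = None,
) -> DrugPanel:
    """Draw a synthetic drug panel on the given gene universe.

    Expression of gene g in experiment e is
    ``baseline_g + cellline_offset + batch_offset + duration_offset
    + concentration_e * effect_g + N(0, noise_sd)``
    where effect_g is zero for null drugs and ``-k * true_log2fc`` of the
    assigned tumour program for reversal drugs.  Gene-level covariate
    offsets are shared panel-wide so cell line/batch/duration behave as
    genuine nuisance factors the linear model must absorb.
    """
    rng = np.random.default_rng(config.seed)
    genes = pd.Index(genes, name="gene")
    n_genes = len(genes)

    n_rev = int(round(config.frac_reversal_drugs * config.n_drugs))
    if n_rev > 0 and (truth is None or len(truth) == 0):
        raise ValueError("reversal drugs requested but the truth table is empty")

    # deterministic program assignment: sample-scoped programs first
    scopes: list[str] = []
    if truth is not None and len(truth):
        uniq = truth["scope"].unique().tolist()
        scopes = sorted([s for s in uniq if s.startswith("sample:")]) + \
            sorted([s for s in uniq if s.startswith("subtype:")]) + \
            [s for s in uniq if s == SCOPE_GROUP]
    drug_ids = [f"drug{i:04d}" for i in range(config.n_drugs)]
    is_reversal = np.array([i < n_rev for i in range(config.n_drugs)])
    target_scope = [scopes[i % len(scopes)] if is_reversal[i] else ""
                    for i in range(config.n_drugs)]

    n_nc = int(round(config.frac_no_control * config.n_drugs))
    # take no-control drugs from the tail (null drugs) so reversal truth stays scorable
    no_control = np.zeros(config.n_drugs, dtype=bool)
    no_control[config.n_drugs - n_nc:] = True

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_genes)
    cell_lines = [f"CL{j:02d}" for j in range(config.n_cell_lines)]
    batches = [f"B{j:02d}" for j in range(config.n_batches)]
    durations = list(config.durations)
    cl_off = {cl: rng.normal(0, config.covariate_sd, size=n_genes) for cl in cell_lines}
    b_off = {b: rng.normal(0, config.covariate_sd, size=n_genes) for b in batches}
    d_off = {d: rng.normal(0, config.covariate_sd, size=n_genes) for d in durations}

    expression: dict[str, pd.DataFrame] = {}
    meta_rows = []
    for d_i, drug in enumerate(drug_ids):
        effect = np.zeros(n_genes)
        if is_reversal[d_i]:
            prog = truth_program(truth, target_scope[d_i], subtype_of=subtype_of)
            loc = genes.get_indexer(prog.index)
            effect[loc[loc >= 0]] = -config.reversal_strength * prog.to_numpy()[loc >= 0]
        concs = [c for c in config.concentrations if not (no_control[d_i] and c == 0.0)]
        cols, col_ids = [], []
        for cl in cell_lines:
            for dur in durations:
                for conc in concs:
                    col = (baseline + cl_off[cl] + d_off[dur] + conc * effect)
                    batch = batches[int(rng.integers(len(batches)))]
                    col = col + b_off[batch]
                    if config.noise_sd > 0:
                        col = col + rng.normal(0, config.noise_sd, size=n_genes)
                    cid = f"{drug}_e{len(col_ids):03d}"
                    cols.append(col)
                    col_ids.append(cid)
                    meta_rows.append((cid, drug, conc, cl, dur, batch))
        expression[drug] = pd.DataFrame(np.column_stack(cols), index=genes, columns=col_ids)

    metadata = pd.DataFrame(
        meta_rows,
        columns=["column_id", "drug", "concentration", "cell_line", "duration", "batch"],
    )
    truth_labels = pd.DataFrame({
        "drug": drug_ids,
        "is_reversal": is_reversal,
        "target_scope": target_scope,
        "has_control": ~no_control,
    })
    return DrugPanel(expression=expression, metadata=metadata, truth=truth_labels)
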
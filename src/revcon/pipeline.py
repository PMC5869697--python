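"""End-to-end orchestration with a hash-based manifest for incremental re-runs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity, drug_sig, preprocess, simnull, summarize, syndata, tumour_sig
from .io import (
    read_counts,
    read_drug_panel,
    read_manifest,
    read_signature,
    sha256_file,
    write_counts,
    write_drug_panel,
    write_manifest,
    write_signature,
)

logger = logging.getLogger("revcon")


@dataclass
class RunConfig:
    """Every knob of a pipeline run; YAML round-trips to the identical object."""

    global_seed: int = 0
    cohort: dict = field(default_factory=dict)        # CohortConfig overrides
    drug_panel: dict = field(default_factory=dict)    # DrugPanelConfig overrides
    cpm_cutoff: float = 0.5
    min_fraction: float = 1.0 / 6.0
    query_fdr: float = 0.01
    deg_fdr: float = 0.5
    n_perm: int = 1000
    min_shared: int = 5
    null_deg_n_mc: int = 10_000
    run_simnull: bool = False
    simnull_n_batches: int = 200
    simnull_batch_size: int = 50
    simnull_n_perm: int = 200
    version: str = "0.1.0"

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def params_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()


class PipelineError(RuntimeError):
    pass


def _stage_current(manifest: dict, stage: str, input_paths: list, params_hash: str) -> bool:
    rec = manifest.get(stage)
    if rec is None or rec.get("params") != params_hash:
        return False
    for p, h in rec.get("inputs", {}).items():
        if not Path(p).exists() or sha256_file(p) != h:
            return False
    for p, h in rec.get("outputs", {}).items():
        if not Path(p).exists() or sha256_file(p) != h:
            return False
    return True


def _record_stage(manifest: dict, stage: str, inputs: list, outputs: list,
                  params_hash: str) -> None:
    manifest[stage] = {
        "params": params_hash,
        "inputs": {str(p): sha256_file(p) for p in inputs},
        "outputs": {str(p): sha256_file(p) for p in outputs},
    }


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Run simulate -> preprocess -> signatures -> connectivity -> summary.

    Stages whose inputs, outputs and parameters are unchanged (verified by
    content hash) are skipped, so deleting one intermediate re-runs only the
    stage that produces it.  All seeds derive from ``config.global_seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setLevel(logging.INFO)
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    manifest_path = outdir / "manifest.json"
    manifest = read_manifest(manifest_path)
    ph = config.params_hash()
    config.save(outdir / "config.yaml")

    try:
        # --- stage: simulate ------------------------------------------------
        data_dir = outdir / "data"
        cohort_cfg = syndata.CohortConfig(seed=config.global_seed, **config.cohort)
        panel_cfg = syndata.DrugPanelConfig(seed=config.global_seed + 1,
                                            **config.drug_panel)
        cohort_paths = [data_dir / f"cohort_{s}.tsv"
                        for s in ("counts", "gene_lengths", "sample_metadata")]
        truth_path = data_dir / "cohort_truth.tsv"
        if not _stage_current(manifest, "simulate", [], ph):
            logger.info("stage simulate: generating cohort and drug panel")
            cm, truth = syndata.generate_cohort(cohort_cfg)
            write_counts(cm, data_dir)
            truth.to_csv(truth_path, sep="\t", index=False)
            panel = syndata.generate_drug_panel(
                panel_cfg, truth, cm.genes,
                subtype_of=syndata.subtype_scope_map(cm.metadata),
            )
            write_drug_panel(panel, data_dir / "panel")
            outputs = cohort_paths + [truth_path] + sorted(
                (data_dir / "panel").glob("*.tsv")
            ) + [data_dir / "panel" / "panel_manifest.json"]
            _record_stage(manifest, "simulate", [], outputs, ph)
            write_manifest(manifest_path, manifest)
        else:
            logger.info("stage simulate: up to date, skipped")

        # --- stage: preprocess ---------------------------------------------
        filt_path = outdir / "filtered_counts.tsv"
        if not _stage_current(manifest, "preprocess", cohort_paths, ph):
            logger.info("stage preprocess: CPM filter")
            cm = read_counts(*cohort_paths)
            filtered = preprocess.filter_low_expressed(
                cm, cpm_cutoff=config.cpm_cutoff, min_fraction=config.min_fraction
            )
            logger.info("preprocess: retained %d of %d genes",
                        filtered.n_genes, cm.n_genes)
            filtered.counts.rename_axis("gene").to_csv(filt_path, sep="\t")
            _record_stage(manifest, "preprocess", cohort_paths, [filt_path], ph)
            write_manifest(manifest_path, manifest)

        # --- stage: tumour signatures ---------------------------------------
        sig_dir = outdir / "tumour_signatures"
        sig_inputs = [filt_path, cohort_paths[2]]
        disp_path = outdir / "dispersion.json"
        if not _stage_current(manifest, "tumour_signatures", sig_inputs, ph):
            logger.info("stage tumour_signatures")
            cm = read_counts(*cohort_paths)
            filtered_genes = pd.read_csv(filt_path, sep="\t", index_col=0).index
            cm = cm.subset_genes(filtered_genes)
            phi = tumour_sig.estimate_cohort_dispersion(cm)
            disp_path.write_text(json.dumps({"dispersion": phi}))
            logger.info("common dispersion estimate: %.4f", phi)
            outputs = [disp_path]
            for kind in ("group", "subtype", "sample", "normal_control"):
                for sig in tumour_sig.make_signatures(cm, phi, kind):
                    outputs.append(write_signature(sig, sig_dir))
            _record_stage(manifest, "tumour_signatures", sig_inputs, outputs, ph)
            write_manifest(manifest_path, manifest)

        # --- stage: drug signatures -----------------------------------------
        dsig_dir = outdir / "drug_signatures"
        panel_manifest = data_dir / "panel" / "panel_manifest.json"
        if not _stage_current(manifest, "drug_signatures", [panel_manifest], ph):
            logger.info("stage drug_signatures")
            panel = read_drug_panel(data_dir / "panel")
            sigs, status = drug_sig.fit_drug_panel(panel)
            n_unproc = sum(1 for s in status.values() if s != drug_sig.STATUS_OK)
            logger.info("drug signatures: %d drugs, %d UNPROCESSABLE",
                        len(status), n_unproc)
            dsig_dir.mkdir(parents=True, exist_ok=True)
            outputs = []
            panel_summary = {}
            for drug, st in status.items():
                entry = {"status": st}
                if st == drug_sig.STATUS_OK:
                    sig = sigs[drug]
                    p = dsig_dir / f"{drug}.tsv"
                    sig.table.rename_axis("gene").to_csv(p, sep="\t")
                    outputs.append(p)
                    entry["pct_deg"] = drug_sig.pct_deg(sig, config.deg_fdr)
                    entry["deg_count"] = int((sig.table["fdr"] < config.deg_fdr).sum())
                panel_summary[drug] = entry
            pj = dsig_dir / "panel_summary.json"
            pj.write_text(json.dumps(panel_summary, indent=1, sort_keys=True))
            outputs.append(pj)
            _record_stage(manifest, "drug_signatures", [panel_manifest], outputs, ph)
            write_manifest(manifest_path, manifest)

        # --- stage: connectivity --------------------------------------------
        results_path = outdir / "connectivity_results.tsv"
        conn_inputs = sorted(sig_dir.glob("sample_*.tsv")) + sorted(dsig_dir.glob("drug*.tsv"))
        if not _stage_current(manifest, "connect", conn_inputs, ph):
            logger.info("stage connect")
            queries = []
            for p in sorted(sig_dir.glob("sample_*.tsv")):
                q = connectivity.build_query(read_signature(p), fdr_cutoff=config.query_fdr)
                if q.empty:
                    logger.info("sample %s UNSCORABLE (empty query)", q.sample_id)
                    continue
                queries.append(q)
            panel_summary = json.loads((dsig_dir / "panel_summary.json").read_text())
            drug_sigs = {}
            for drug, entry in panel_summary.items():
                if entry["status"] != drug_sig.STATUS_OK:
                    continue
                table = pd.read_csv(dsig_dir / f"{drug}.tsv", sep="\t", index_col=0)
                drug_sigs[drug] = drug_sig.DrugSignature(
                    drug_id=drug, table=table, ebayes=None,
                    n_experiments=0, n_cell_lines=0,
                )
            results = connectivity.connect_all(
                queries, drug_sigs, n_perm=config.n_perm,
                min_shared=config.min_shared, global_seed=config.global_seed,
            )
            results.to_csv(results_path, sep="\t", index=False)
            # group/subtype queries get the scaled permutation budget
            agg_queries = []
            for pattern in ("group_*.tsv", "subtype_*.tsv"):
                for p in sorted(sig_dir.glob(pattern)):
                    q = connectivity.build_query(read_signature(p),
                                                 fdr_cutoff=config.query_fdr)
                    if not q.empty:
                        agg_queries.append(q)
            agg = connectivity.connect_all(
                agg_queries, drug_sigs,
                n_perm=connectivity.aggregated_n_perm(config.n_perm, len(queries)),
                min_shared=config.min_shared, global_seed=config.global_seed,
            )
            agg_path = outdir / "connectivity_results_aggregated.tsv"
            agg.to_csv(agg_path, sep="\t", index=False)
            _record_stage(manifest, "connect", conn_inputs,
                          [results_path, agg_path], ph)
            write_manifest(manifest_path, manifest)

        # --- stage: summarize -----------------------------------------------
        summary_path = outdir / "drug_summary.tsv"
        if not _stage_current(manifest, "summarize", [results_path], ph):
            logger.info("stage summarize")
            results = pd.read_csv(results_path, sep="\t")
            panel_summary = json.loads((dsig_dir / "panel_summary.json").read_text())
            ok = {d: e for d, e in panel_summary.items()
                  if e["status"] == drug_sig.STATUS_OK}
            n_genes_sig = len(pd.read_csv(
                dsig_dir / f"{next(iter(ok))}.tsv", sep="\t", index_col=0))
            thr = summarize.null_deg_threshold(
                n_genes_sig, fdr_cutoff=config.deg_fdr,
                n_mc=config.null_deg_n_mc, seed=config.global_seed,
            )
            logger.info("chance-DEG threshold: %d of %d genes", thr, n_genes_sig)
            summary = summarize.summarize_drugs(
                results,
                {d: e["pct_deg"] for d, e in ok.items()},
                {d: e["deg_count"] for d, e in ok.items()},
                null_threshold=thr,
            )
            summary.to_csv(summary_path, sep="\t", index=False)
            _record_stage(manifest, "summarize", [results_path], [summary_path], ph)
            write_manifest(manifest_path, manifest)

        # --- stage: simnull (optional) --------------------------------------
        if config.run_simnull:
            simnull_path = outdir / "simulation_null.json"
            if not _stage_current(manifest, "simnull", [results_path], ph):
                logger.info("stage simnull")
                cm = read_counts(*cohort_paths)
                filtered_genes = pd.read_csv(filt_path, sep="\t", index_col=0).index
                cm = cm.subset_genes(filtered_genes)
                phi = json.loads(disp_path.read_text())["dispersion"]
                out = _run_simnull_stage(cm, phi, config, dsig_dir, results_path)
                simnull_path.write_text(json.dumps(out, indent=1, sort_keys=True))
                _record_stage(manifest, "simnull", [results_path], [simnull_path], ph)
                write_manifest(manifest_path, manifest)
        return outdir
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(
            f"pipeline failed: {exc}; check {outdir / 'run.log'} and re-run after "
            "fixing the inputs (unchanged stages will be skipped)"
        ) from exc
    finally:
        logger.removeHandler(handler)


def _run_simnull_stage(cm, phi, config: RunConfig, dsig_dir: Path,
                       results_path: Path) -> dict:
    from .nbglm import fit_nb_glm

    counts = cm.counts.to_numpy(dtype=float)
    offsets = np.log(cm.library_sizes().to_numpy(dtype=float))
    tumour_mask = cm.tissue_mask("tumour")
    X = np.column_stack([np.ones(cm.n_samples), tumour_mask.astype(float)])
    fit = fit_nb_glm(counts, X, offsets, phi)
    depths = cm.library_sizes().to_numpy(dtype=float)[tumour_mask]
    gen = simnull.extract_generator(
        fit, np.array([1.0, 1.0]), depths, source="group", genes=cm.genes,
        fallback_mu=simnull.observed_group_mean(counts[:, tumour_mask], depths),
    )
    panel_summary = json.loads((dsig_dir / "panel_summary.json").read_text())
    drug_sigs = {}
    for drug, entry in panel_summary.items():
        if entry["status"] != drug_sig.STATUS_OK:
            continue
        table = pd.read_csv(dsig_dir / f"{drug}.tsv", sep="\t", index_col=0)
        drug_sigs[drug] = drug_sig.DrugSignature(
            drug_id=drug, table=table, ebayes=None, n_experiments=0, n_cell_lines=0)
    results = pd.read_csv(results_path, sep="\t")
    observed = results[results["negative_enriched"]].groupby("drug_id").size().to_dict()
    observed = {d: observed.get(d, 0) for d in drug_sigs}
    normal_mask = ~tumour_mask
    out = simnull.null_enrichment_distribution(
        gen, drug_sigs,
        normals=counts[:, normal_mask],
        normal_offsets=offsets[normal_mask],
        genes=cm.genes, phi=phi,
        n_batches=config.simnull_n_batches,
        batch_size=config.simnull_batch_size,
        observed_counts=observed,
        n_perm=config.simnull_n_perm,
        query_fdr=config.query_fdr,
        min_shared=config.min_shared,
        seed=config.global_seed,
    )
    return {
        drug: {
            "observed_count": entry.get("observed_count"),
            "interval": list(entry["interval"]),
            "fold_ratios": list(entry.get("fold_ratios", [])),
            "n_batches": entry["n_batches"],
            "batch_size": entry["batch_size"],
        }
        for drug, entry in out["per_drug"].items()
    }
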
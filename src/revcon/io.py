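"""TSV readers/writers, manifest helpers, seed derivation and gene-id mapping.

All interchange is plain TSV (genes as rows) so that intermediates are
diff-able; no operation in the package touches the network.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CountMatrix

logger = logging.getLogger("revcon")

MAX_SEED = 2**31 - 1


def stable_seed(*parts) -> int:
    """Deterministic 31-bit seed from a global seed plus string/int labels.

    Every random draw in the package flows from a global seed through this
    derivation, so (sample, drug) permutation streams and per-batch
    simulation streams are reproducible and independent of iteration order.
    """
    h = zlib.crc32(b"revcon")
    for part in parts:
        h = zlib.crc32(str(part).encode("utf-8"), h)
    return h % MAX_SEED


def rng_for(*parts) -> np.random.Generator:
    return np.random.default_rng(stable_seed(*parts))


# ---------------------------------------------------------------------------
# count matrices


def write_counts(cm: CountMatrix, outdir: str | Path, prefix: str = "cohort") -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / f"{prefix}_counts.tsv",
        "lengths": outdir / f"{prefix}_gene_lengths.tsv",
        "metadata": outdir / f"{prefix}_sample_metadata.tsv",
    }
    cm.counts.rename_axis("gene").to_csv(paths["counts"], sep="\t")
    cm.lengths.rename("length_bp").rename_axis("gene").to_csv(paths["lengths"], sep="\t")
    cm.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}


def read_counts(counts_path, lengths_path, metadata_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    lengths = pd.read_csv(lengths_path, sep="\t", index_col=0)["length_bp"]
    metadata = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str, "patient_id": str})
    return CountMatrix(counts=counts, lengths=lengths, metadata=metadata)


# ---------------------------------------------------------------------------
# signatures


def write_signature(sig, outdir: str | Path) -> Path:
    """Write one contrast signature as TSV plus a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = f"{sig.contrast_kind}_{sig.contrast_id}"
    path = outdir / f"{stem}.tsv"
    sig.table.rename_axis("gene").to_csv(path, sep="\t")
    sidecar = {
        "contrast_kind": sig.contrast_kind,
        "contrast_id": str(sig.contrast_id),
        "dispersion": float(sig.dispersion),
        "n_genes": int(len(sig.table)),
    }
    (outdir / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_signature(path: str | Path):
    from .tumour_sig import Signature

    path = Path(path)
    table = pd.read_csv(path, sep="\t", index_col=0)
    meta = json.loads(path.with_suffix(".json").read_text())
    return Signature(
        contrast_kind=meta["contrast_kind"],
        contrast_id=meta["contrast_id"],
        table=table,
        dispersion=meta["dispersion"],
    )


# ---------------------------------------------------------------------------
# drug panels


def write_drug_panel(panel, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for drug_id, expr in panel.expression.items():
        p = outdir / f"drug_{drug_id}.tsv"
        expr.rename_axis("gene").to_csv(p, sep="\t")
        paths[drug_id] = str(p)
    meta_path = outdir / "experiment_metadata.tsv"
    panel.metadata.to_csv(meta_path, sep="\t", index=False)
    truth_path = outdir / "drug_truth.tsv"
    panel.truth.to_csv(truth_path, sep="\t", index=False)
    manifest = {"drugs": paths, "metadata": str(meta_path), "truth": str(truth_path)}
    (outdir / "panel_manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_drug_panel(outdir: str | Path):
    from .syndata import DrugPanel

    outdir = Path(outdir)
    manifest = json.loads((outdir / "panel_manifest.json").read_text())
    expression = {
        drug: pd.read_csv(path, sep="\t", index_col=0)
        for drug, path in manifest["drugs"].items()
    }
    metadata = pd.read_csv(manifest["metadata"], sep="\t")
    truth = pd.read_csv(manifest["truth"], sep="\t")
    return DrugPanel(expression=expression, metadata=metadata, truth=truth)


def read_level3_matrix(path):
    """Adapter stub for real perturbation-database matrix archives.

    The pipeline consumes per-drug expression as genes x experiment-columns
    (gene ids on the rows, one column per perturbation instance, log-scale
    values), with a separate experiment-metadata table carrying
    column_id, drug, concentration, cell_line, duration and batch.  A
    converter from a binary level-3 archive must produce exactly that
    orientation; no downloader or binary parser ships with this package.
    """
    raise NotImplementedError(
        "convert the archive to per-drug TSVs (genes x experiments) plus an "
        "experiment-metadata TSV and load them with read_drug_panel()"
    )


# ---------------------------------------------------------------------------
# manifest / hashing


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, entries: dict) -> None:
    Path(path).write_text(json.dumps(entries, indent=1, sort_keys=True))


def read_manifest(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        return {}
    return json.loads(path.read_text())


# ---------------------------------------------------------------------------
# gene-id mapping


def map_gene_ids(mapping: pd.DataFrame, data: pd.DataFrame) -> pd.DataFrame:
    """Re-key a gene-indexed table via a two-column (source, target) mapping.

    Unmapped genes are dropped with a logged count.  When several source ids
    map to one target id, the row with the larger total (absolute) signal is
    kept; the collision count is logged.
    """
    if mapping.shape[0] == 0:
        raise ValueError("gene-id mapping table is empty")
    src_col, dst_col = mapping.columns[:2]
    lut = mapping.set_index(src_col)[dst_col]
    mapped = data.index.to_series().map(lut)
    dropped = int(mapped.isna().sum())
    if dropped:
        logger.info("map_gene_ids: dropped %d unmapped genes", dropped)
    keep = mapped.notna()
    out = data.loc[keep].copy()
    out.index = pd.Index(mapped[keep], name=data.index.name)
    if out.index.has_duplicates:
        totals = out.abs().sum(axis=1)
        order = np.argsort(-totals.to_numpy(), kind="stable")
        out = out.iloc[order]
        n_before = len(out)
        out = out[~out.index.duplicated(keep="first")]
        logger.info("map_gene_ids: resolved %d many-to-one collisions", n_before - len(out))
        out = out.sort_index()
    return out
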
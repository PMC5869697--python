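"""SVG figures: signature-size curves, tumour/normal size ratio, quality scatter."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .tumour_sig import Signature, signature_size

FDR_GRID = np.logspace(-3, 0, 40)


def signature_size_curves(signatures_by_kind: dict, path: str | Path) -> Path:
    """Median signature size vs FDR cutoff, one curve per signature kind."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for kind, sigs in signatures_by_kind.items():
        sizes = np.array([[signature_size(s, c) for s in sigs] for c in FDR_GRID])
        ax.plot(FDR_GRID, np.median(sizes, axis=1), label=kind)
    ax.set(xscale="log", yscale="symlog", xlabel="FDR cutoff",
           ylabel="median signature size (genes)")
    ax.legend(fontsize=8)
    return _save(fig, path)


def size_ratio_curve(sample_sigs: list, normal_sigs: list, path: str | Path) -> Path:
    """Mean tumour-sample / mean normal-control signature size vs FDR cutoff."""
    fig, ax = plt.subplots(figsize=(5, 4))
    num = np.array([[signature_size(s, c) for s in sample_sigs] for c in FDR_GRID])
    den = np.array([[signature_size(s, c) for s in normal_sigs] for c in FDR_GRID])
    ratio = num.mean(axis=1) / np.maximum(den.mean(axis=1), 1e-9)
    ax.plot(FDR_GRID, ratio)
    ax.axhline(1.0, ls="--", c="grey")
    ax.set(xscale="log", yscale="log", xlabel="FDR cutoff",
           ylabel="tumour / normal mean signature size")
    return _save(fig, path)


def negfreq_vs_pctdeg(summary: pd.DataFrame, path: str | Path) -> Path:
    """Per-drug negative-enrichment frequency vs %DEG quality score."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(summary["pct_deg"], summary["neg_freq"], s=12, alpha=0.6)
    ax.set(xlabel="% DEG in drug signature", ylabel="negative-enrichment frequency")
    return _save(fig, path)


def _save(fig, path: str | Path) -> Path:
    path = Path(path).with_suffix(".svg")
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
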
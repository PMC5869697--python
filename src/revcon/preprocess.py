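"""Within-sample length normalization, between-sample depth correction, CPM filter.

The expression filter retains genes above 0.5 CPM (strictly) in at least a
sixth of all samples, evaluated jointly on tumour and normal samples.
Normalized values feed diagnostics only: count models downstream consume raw
counts with library-size offsets.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .data import CountMatrix, NormalizedCounts

DEFAULT_CPM_CUTOFF = 0.5
DEFAULT_MIN_FRACTION = 1.0 / 6.0


def cpm(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Counts per million: each column rescaled to sum to 1e6."""
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    libsize = mat.sum(axis=0)
    zero = libsize[libsize <= 0]
    if len(zero):
        raise ValueError(f"zero library size for samples: {list(zero.index)}")
    return mat / libsize * 1e6


def expressed_genes(
    counts: CountMatrix,
    cpm_cutoff: float = DEFAULT_CPM_CUTOFF,
    min_fraction: float = DEFAULT_MIN_FRACTION,
):
    """Genes with CPM strictly above the cutoff in >= ceil(min_fraction * n) samples."""
    if cpm_cutoff < 0:
        raise ValueError("cpm_cutoff must be >= 0")
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    c = cpm(counts)
    min_samples = math.ceil(min_fraction * counts.n_samples)
    keep = (c > cpm_cutoff).sum(axis=1) >= min_samples
    return counts.genes[keep.to_numpy()]


def filter_low_expressed(
    counts: CountMatrix,
    cpm_cutoff: float = DEFAULT_CPM_CUTOFF,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> CountMatrix:
    """Drop lowly expressed genes; the filter pools tumour and normal samples."""
    return counts.subset_genes(expressed_genes(counts, cpm_cutoff, min_fraction))


def _upper_quartile_nonzero(col: np.ndarray) -> float:
    nz = col[col > 0]
    if len(nz) == 0:
        raise ValueError("a sample has no nonzero expression after length scaling")
    return float(np.percentile(nz, 75))


def normalize_length_depth(
    counts: CountMatrix,
    full_quantile: bool = False,
) -> NormalizedCounts:
    """Divide by gene length in kb, then equalize columns' upper quartiles.

    Step 1 (within sample): reads per kilobase, r = counts / (length/1000).
    Step 2 (between samples): by default each column is scaled so that its
    upper quartile of nonzero values matches the cohort target, defined as
    the median of the per-column upper quartiles (identical columns are
    left untouched, and rescaling one outlying sample does not move the
    target); ``full_quantile=True`` instead maps every column onto the mean
    sorted profile (full-quantile normalization).
    """
    lengths = counts.lengths.reindex(counts.genes)
    missing = counts.genes[lengths.isna() | (lengths <= 0)]
    if len(missing):
        raise ValueError(f"missing or non-positive gene lengths: {list(missing[:10])}")
    r = counts.counts.div(lengths / 1000.0, axis=0)
    arr = r.to_numpy(dtype=float)

    if full_quantile:
        order = np.argsort(arr, axis=0)
        target = np.mean(np.sort(arr, axis=0), axis=1)
        out = np.empty_like(arr)
        for j in range(arr.shape[1]):
            out[order[:, j], j] = target
    else:
        uq = np.array([_upper_quartile_nonzero(arr[:, j]) for j in range(arr.shape[1])])
        target_uq = float(np.median(uq))
        out = arr * (target_uq / uq)[None, :]

    eff = counts.library_sizes() * pd.Series(
        out.sum(axis=0) / np.maximum(arr.sum(axis=0), 1e-300), index=counts.samples
    )
    return NormalizedCounts(
        values=pd.DataFrame(out, index=counts.genes, columns=counts.samples),
        length_normalized=True,
        depth_normalized=True,
        effective_library_sizes=eff,
    )
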
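"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TISSUE_TUMOUR = "tumour"
TISSUE_NORMAL = "normal"

REQUIRED_METADATA_COLUMNS = ("sample_id", "patient_id", "tissue", "subtype", "stage", "depth")


@dataclass
class CountMatrix:
    """Integer gene-by-sample read counts with gene lengths and sample metadata.

    ``counts`` is genes x samples (gene ids on the index, sample ids on the
    columns).  ``lengths`` maps gene id to gene length in base pairs.
    ``metadata`` has one row per sample with at least the columns
    ``sample_id, patient_id, tissue, subtype, stage, depth``; ``tissue`` is
    'tumour' or 'normal' and ``depth`` the library-size factor used when the
    cohort was generated (observed cohorts carry the column-sum as depth).
    """

    counts: pd.DataFrame
    lengths: pd.Series
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.shape[0] == 0 or self.counts.shape[1] == 0:
            raise ValueError("count matrix must have at least one gene and one sample")
        self.metadata = self.metadata.set_index("sample_id", drop=False) if (
            self.metadata.index.name != "sample_id"
        ) else self.metadata
        missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise ValueError(f"sample metadata missing columns: {missing}")
        if list(self.metadata.index) != list(self.counts.columns):
            self.metadata = self.metadata.loc[list(self.counts.columns)]
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def tissue_mask(self, tissue: str) -> np.ndarray:
        return (self.metadata["tissue"] == tissue).to_numpy()

    def tumour_samples(self) -> pd.Index:
        return self.samples[self.tissue_mask(TISSUE_TUMOUR)]

    def normal_samples(self) -> pd.Index:
        return self.samples[self.tissue_mask(TISSUE_NORMAL)]

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts.loc[genes],
            lengths=self.lengths.loc[genes],
            metadata=self.metadata.copy(),
        )

    def subset_samples(self, samples) -> "CountMatrix":
        samples = list(samples)
        return CountMatrix(
            counts=self.counts[samples],
            lengths=self.lengths,
            metadata=self.metadata.loc[samples],
        )


@dataclass
class NormalizedCounts:
    """Length- and depth-normalized expression for diagnostics.

    Differential-expression models consume raw counts with offsets; this
    container only feeds plots and sanity checks.
    """

    values: pd.DataFrame
    length_normalized: bool
    depth_normalized: bool
    effective_library_sizes: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("normalized expression must be non-negative")
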
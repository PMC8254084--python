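"""Gene x sample count matrix with per-sample time-point/replicate metadata.

The matrix is the entry point of the whole pipeline: a featureCounts-style
table of non-negative integer read counts, one row per gene, one column per
library, plus a label assigning each library to a time point and a replicate
index within that time point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class CountMatrix:
    """Integer read counts for ``gene_ids`` (rows) x ``samples`` (columns).

    Parameters
    ----------
    gene_ids : sequence of str
        Unique gene identifiers, row order preserved everywhere downstream.
    counts : ndarray of shape (n_genes, n_samples)
        Non-negative integer read counts.
    samples : sequence of str
        Library (column) names.
    timepoints : sequence of str
        Time-point label per sample, e.g. ``"0h"``.
    replicates : sequence of int
        Replicate index per sample within its time point.
    """

    gene_ids: list[str]
    counts: np.ndarray
    samples: list[str]
    timepoints: list[str]
    replicates: list[int]

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.samples = list(self.samples)
        self.timepoints = list(self.timepoints)
        self.replicates = [int(r) for r in self.replicates]
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D gene x sample array")
        if self.counts.shape != (len(self.gene_ids), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.samples)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len({len(self.samples), len(self.timepoints), len(self.replicates)}) != 1:
            raise ValueError("samples, timepoints and replicates must align")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded):
                raise ValueError("counts must be integers")
            self.counts = rounded.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def lib_sizes(self) -> np.ndarray:
        """Per-sample column sums (total assigned reads)."""
        return self.counts.sum(axis=0)

    @property
    def timepoint_order(self) -> list[str]:
        """Distinct time-point labels in first-appearance order."""
        seen: dict[str, None] = {}
        for t in self.timepoints:
            seen.setdefault(t, None)
        return list(seen)

    def samples_at(self, timepoint: str) -> list[int]:
        """Column indices of the replicates measured at ``timepoint``."""
        idx = [j for j, t in enumerate(self.timepoints) if t == timepoint]
        if not idx:
            raise KeyError(f"no samples at time point {timepoint!r}")
        return idx

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        rows = [index[g] for g in genes]
        return CountMatrix(
            [self.gene_ids[i] for i in rows],
            self.counts[rows],
            self.samples,
            self.timepoints,
            self.replicates,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.samples)

    # --- I/O -----------------------------------------------------------

    def write_tsv(self, counts_path: str | Path, meta_path: str | Path) -> None:
        """Write counts (gene id first column) and sample metadata TSVs."""
        df = self.to_frame()
        df.index.name = "gene"
        df.to_csv(counts_path, sep="\t")
        meta = pd.DataFrame(
            {
                "sample": self.samples,
                "timepoint": self.timepoints,
                "replicate": self.replicates,
            }
        )
        meta.to_csv(meta_path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, counts_path: str | Path, meta_path: str | Path) -> "CountMatrix":
        df = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", dtype={"timepoint": str})
        meta = meta.set_index("sample").loc[df.columns]
        return cls(
            list(df.index.astype(str)),
            df.to_numpy(),
            list(df.columns),
            list(meta["timepoint"].astype(str)),
            list(meta["replicate"].astype(int)),
        )


@dataclass
class EmptyMatrixError(Exception):
    """Raised when a filter removes every gene."""

    message: str = "all genes removed by filtering"

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.message
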
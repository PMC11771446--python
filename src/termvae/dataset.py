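"""Count-matrix container and MatrixMarket/TSV persistence.

The on-disk layout mirrors the common cellranger-style triplet: a sparse
``matrix.mtx`` (genes are columns here, 1-based per the MatrixMarket
standard via :mod:`scipy.io`), a ``genes.tsv`` with one gene id per line,
and a ``cells.tsv`` with columns ``cell_id``, ``cell_type``, ``condition``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = ["ExpressionDataset", "read_dataset", "write_dataset"]


@dataclass
class ExpressionDataset:
    """Cells x genes non-negative integer counts with per-cell labels.

    ``obs`` is indexed by cell id and must carry a ``condition`` column
    (tissue source / study / batch); ``cell_type`` is optional but required
    for group-wise enrichment testing.
    """

    counts: sp.csr_matrix = field(repr=False)
    genes: list[str] = field(default_factory=list)
    obs: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.obs), len(self.genes)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.obs)} cells x {len(self.genes)} genes"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids")
        if "condition" not in self.obs.columns:
            raise ValueError("obs must have a 'condition' column")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_ids(self) -> list[str]:
        return list(self.obs.index.astype(str))

    @property
    def conditions(self) -> pd.Series:
        return self.obs["condition"]

    @property
    def cell_types(self) -> pd.Series:
        if "cell_type" not in self.obs.columns:
            raise KeyError("dataset has no 'cell_type' labels")
        return self.obs["cell_type"]

    def library_sizes(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def dense(self) -> np.ndarray:
        return self.counts.toarray()

    def subset(self, index: Sequence[int] | np.ndarray) -> "ExpressionDataset":
        idx = np.asarray(index)
        return ExpressionDataset(
            counts=self.counts[idx],
            genes=list(self.genes),
            obs=self.obs.iloc[idx].copy(),
        )

    def to_anndata(self):
        """Convenience export for scanpy-based downstream analysis."""
        import anndata

        return anndata.AnnData(
            X=self.counts.copy(), obs=self.obs.copy(), var=pd.DataFrame(index=self.genes)
        )


def write_dataset(dataset: ExpressionDataset, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), dataset.counts.astype(np.int64))
    (directory / "genes.tsv").write_text(
        "".join(g + "\n" for g in dataset.genes), encoding="utf-8"
    )
    obs = dataset.obs.copy()
    obs.insert(0, "cell_id", obs.index.astype(str))
    obs.to_csv(directory / "cells.tsv", sep="\t", index=False)


def read_dataset(directory: str | Path) -> ExpressionDataset:
    directory = Path(directory)
    counts = sp.csr_matrix(scipy.io.mmread(str(directory / "matrix.mtx")))
    genes = (directory / "genes.tsv").read_text(encoding="utf-8").split()
    obs = pd.read_csv(directory / "cells.tsv", sep="\t", dtype=str)
    obs = obs.set_index("cell_id")
    obs.index.name = None
    return ExpressionDataset(counts=counts, genes=genes, obs=obs)
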
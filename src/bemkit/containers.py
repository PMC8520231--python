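"""Core data container: a labeled count matrix, plus its TSV round-trip.

The whole pipeline operates on normalized per-gene read counts (genes x
samples) with a sample -> group label map, mirroring how sorted-population
bulk RNA-seq is usually handed around as a matrix plus a sample sheet.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "read_count_matrix", "write_count_matrix"]


@dataclass
class CountMatrix:
    """Genes x samples matrix of non-negative normalized counts.

    ``values`` is a DataFrame indexed by gene id with sample-id columns;
    ``sample_groups`` maps every sample id to its group label.
    """

    values: pd.DataFrame
    sample_groups: pd.Series

    def __post_init__(self):
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.sample_groups = pd.Series(self.sample_groups)
        missing = set(self.values.columns) - set(self.sample_groups.index)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)}")
        self.sample_groups = self.sample_groups.loc[self.values.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.sample_groups:
            seen.setdefault(g, None)
        return list(seen)

    def samples_of(self, group: str) -> list[str]:
        return [s for s, g in self.sample_groups.items() if g == group]

    def group_values(self, group: str) -> pd.DataFrame:
        cols = self.samples_of(group)
        if not cols:
            raise KeyError(f"no samples in group {group!r}")
        return self.values[cols]

    def group_means(self) -> pd.DataFrame:
        """Per-gene mean expression of each group (columns ordered as first seen)."""
        return pd.DataFrame(
            {g: self.group_values(g).mean(axis=1) for g in self.groups}
        )

    def subset_genes(self, gene_ids) -> "CountMatrix":
        keep = self.values.index.intersection(pd.Index(gene_ids))
        return CountMatrix(self.values.loc[keep], self.sample_groups.copy())


def write_count_matrix(cm: CountMatrix, matrix_path, sample_sheet_path) -> None:
    """Write counts as TSV (first column gene id) and a two-column sample sheet."""
    out = cm.values.copy()
    out.index.name = "gene_id"
    out.to_csv(matrix_path, sep="\t")
    sheet = cm.sample_groups.rename("group").rename_axis("sample_id").reset_index()
    sheet.to_csv(sample_sheet_path, sep="\t", index=False)


def read_count_matrix(matrix_path, sample_sheet_path) -> CountMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    sheet = pd.read_csv(sample_sheet_path, sep="\t")
    groups = pd.Series(sheet["group"].to_numpy(), index=sheet["sample_id"])
    return CountMatrix(values, groups)
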
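"""Containers for a multi-dataset expression compendium.

A compendium is a collection of independent expression datasets (genes x
samples) over a shared gene universe.  Individual datasets may cover only a
subset of the universe — real collections mix array platforms, so not every
gene is measured everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class Dataset:
    """One expression dataset: a genes x samples matrix with unique gene ids."""

    dataset_id: str
    expr: pd.DataFrame  # rows = gene ids, columns = sample ids

    def __post_init__(self) -> None:
        if self.expr.index.has_duplicates:
            dups = self.expr.index[self.expr.index.duplicated()].unique().tolist()
            raise ValueError(
                f"dataset {self.dataset_id!r}: duplicate gene rows {dups[:5]}"
            )
        if self.expr.shape[1] < 3:
            raise ValueError(
                f"dataset {self.dataset_id!r}: needs >= 3 samples, got {self.expr.shape[1]}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.expr.index)

    @property
    def n_samples(self) -> int:
        return self.expr.shape[1]


@dataclass
class Compendium:
    """A list of datasets over an ordered shared gene universe."""

    datasets: list[Dataset]
    gene_universe: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.gene_universe:
            seen: dict[str, None] = {}
            for ds in self.datasets:
                for g in ds.gene_ids:
                    seen.setdefault(g, None)
            self.gene_universe = list(seen)
        universe = set(self.gene_universe)
        for ds in self.datasets:
            extra = set(ds.gene_ids) - universe
            if extra:
                raise ValueError(
                    f"dataset {ds.dataset_id!r}: genes outside universe, e.g. {sorted(extra)[:5]}"
                )

    @property
    def n_datasets(self) -> int:
        return len(self.datasets)

    def presence_counts(self) -> dict[str, int]:
        """Number of datasets in which each universe gene is measured."""
        counts = dict.fromkeys(self.gene_universe, 0)
        for ds in self.datasets:
            for g in ds.gene_ids:
                counts[g] += 1
        return counts
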
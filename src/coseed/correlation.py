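"""Seed-centric correlate lists across a multi-dataset compendium.

For each seed transcript the engine returns the list of transcripts whose
expression correlates with it at or above a threshold across the compendium
— the building block from which the co-expression network and the ranked
master list are assembled.

Cross-dataset combination
-------------------------
A single pooled correlation across heterogeneous datasets would be
confounded by dataset-level shifts, so the Pearson correlation is computed
*within* each dataset where both genes are measured and non-constant, and
the per-dataset values are combined on the Fisher z scale with the standard
meta-analytic weights (n_samples - 3), then back-transformed.  Datasets with
fewer than 4 samples carry zero weight and are ignored.  The combination
rule is deliberately isolated here so it can be swapped.

Thresholding is applied to the signed combined r: only positive correlates
at r >= r_threshold enter a list; anticorrelated genes never do.  A seed is
*eligible* only if it is measured in at least ``min_presence_fraction`` of
datasets and non-constant in at least one — ineligible seeds yield empty
lists, emulating seeds dropped from a real compendium for scarce
representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .compendium import Compendium

_R_CLIP = 1.0 - 1e-15  # keep arctanh finite at |r| = 1


class CorrelateEntry(NamedTuple):
    gene_id: str
    r: float
    n_datasets_supporting: int


class PairwiseCorrelation(NamedTuple):
    """Combined correlation for one gene pair; ``r is None`` when undefined."""

    r: float | None
    n_datasets: int
    reason: str | None  # None | insufficient_datasets | constant_gene


@dataclass
class CorrelateList:
    seed_id: str
    entries: list[CorrelateEntry] = field(default_factory=list)
    r_threshold: float = 0.5
    eligible: bool = True

    def __post_init__(self) -> None:
        if not self.eligible and self.entries:
            raise ValueError("ineligible list must have no entries")
        if any(e.gene_id == self.seed_id for e in self.entries):
            raise ValueError("seed must not appear in its own correlate list")

    @property
    def gene_ids(self) -> list[str]:
        return [e.gene_id for e in self.entries]


class _PreparedDataset:
    """Row-standardized dataset: unit-norm centered rows, constant rows flagged."""

    __slots__ = ("index", "z", "nonconstant", "weight")

    def __init__(self, expr, weight: float):
        x = expr.to_numpy(dtype=float)
        mean = x.mean(axis=1, keepdims=True)
        xc = x - mean
        norms = np.linalg.norm(xc, axis=1)
        self.nonconstant = norms > 1e-12
        safe = np.where(self.nonconstant, norms, 1.0)
        self.z = xc / safe[:, None]
        self.index = {g: i for i, g in enumerate(expr.index)}
        self.weight = weight


class CorrelationEngine:
    """Computes combined correlations and correlate lists over a compendium."""

    def __init__(
        self,
        compendium: Compendium,
        r_threshold: float = 0.5,
        min_shared_datasets: int = 3,
        min_presence_fraction: float = 0.25,
    ):
        if min_shared_datasets < 1:
            raise ValueError("min_shared_datasets must be >= 1")
        self.compendium = compendium
        self.r_threshold = r_threshold
        self.min_shared_datasets = min_shared_datasets
        self.min_presence_fraction = min_presence_fraction
        self._universe = list(compendium.gene_universe)
        self._uindex = {g: i for i, g in enumerate(self._universe)}
        # weight n-3: the inverse variance of the Fisher z statistic
        self._prepared = [
            _PreparedDataset(ds.expr, max(ds.n_samples - 3, 0))
            for ds in compendium.datasets
        ]

    # -- single pair ----------------------------------------------------

    def pairwise(self, gene_a: str, gene_b: str) -> PairwiseCorrelation:
        for g in (gene_a, gene_b):
            if g not in self._uindex:
                raise KeyError(f"gene {g!r} not in compendium universe")
        sum_wz = 0.0
        sum_w = 0.0
        n_support = 0
        shared = 0
        constant_seen = False
        for prep in self._prepared:
            ia = prep.index.get(gene_a)
            ib = prep.index.get(gene_b)
            if ia is None or ib is None:
                continue
            shared += 1
            if not (prep.nonconstant[ia] and prep.nonconstant[ib]):
                constant_seen = True
                continue
            if prep.weight <= 0:
                continue
            r = float(np.dot(prep.z[ia], prep.z[ib]))
            r = min(max(r, -_R_CLIP), _R_CLIP)
            sum_wz += prep.weight * np.arctanh(r)
            sum_w += prep.weight
            n_support += 1
        if n_support < self.min_shared_datasets:
            reason = (
                "constant_gene"
                if shared > 0 and constant_seen and n_support == 0
                else "insufficient_datasets"
            )
            return PairwiseCorrelation(None, n_support, reason)
        return PairwiseCorrelation(float(np.tanh(sum_wz / sum_w)), n_support, None)

    # -- seed vs whole universe ------------------------------------------

    def _seed_eligible(self, seed_id: str) -> bool:
        n_present = 0
        nonconstant_somewhere = False
        for prep in self._prepared:
            i = prep.index.get(seed_id)
            if i is None:
                continue
            n_present += 1
            if prep.nonconstant[i]:
                nonconstant_somewhere = True
        frac = n_present / max(len(self._prepared), 1)
        return frac >= self.min_presence_fraction and nonconstant_somewhere

    def correlate_list(self, seed_id: str) -> CorrelateList:
        return self.correlate_lists([seed_id])[0]

    def correlate_lists(self, seed_ids: Sequence[str]) -> list[CorrelateList]:
        """Correlate lists for many seeds in one vectorized pass."""
        for s in seed_ids:
            if s not in self._uindex:
                raise KeyError(f"seed {s!r} not in compendium universe")
        n_genes = len(self._universe)
        n_seeds = len(seed_ids)
        sum_wz = np.zeros((n_seeds, n_genes))
        sum_w = np.zeros((n_seeds, n_genes))
        support = np.zeros((n_seeds, n_genes), dtype=int)

        for prep in self._prepared:
            if prep.weight <= 0:
                continue
            rows = [prep.index.get(s) for s in seed_ids]
            active = [
                (k, i)
                for k, i in enumerate(rows)
                if i is not None and prep.nonconstant[i]
            ]
            if not active:
                continue
            gene_cols = np.array([self._uindex[g] for g in prep.index], dtype=int)
            valid = prep.nonconstant
            seed_rows = np.array([i for _, i in active])
            seed_pos = np.array([k for k, _ in active])
            r = prep.z[seed_rows] @ prep.z.T  # (active seeds) x (dataset genes)
            r = np.clip(r, -_R_CLIP, _R_CLIP)
            wz = prep.weight * np.arctanh(r)
            cols = gene_cols[valid]
            sum_wz[seed_pos[:, None], cols[None, :]] += wz[:, valid]
            sum_w[seed_pos[:, None], cols[None, :]] += prep.weight
            support[seed_pos[:, None], cols[None, :]] += 1

        out: list[CorrelateList] = []
        universe = np.array(self._universe)
        for k, seed in enumerate(seed_ids):
            if not self._seed_eligible(seed):
                out.append(
                    CorrelateList(seed_id=seed, entries=[],
                                  r_threshold=self.r_threshold, eligible=False)
                )
                continue
            ok = support[k] >= self.min_shared_datasets
            ok &= sum_w[k] > 0
            with np.errstate(invalid="ignore"):
                r_comb = np.where(ok, np.tanh(sum_wz[k] / np.where(ok, sum_w[k], 1.0)), np.nan)
            keep = ok & (r_comb >= self.r_threshold)
            keep[self._uindex[seed]] = False
            idx = np.flatnonzero(keep)
            entries = [
                CorrelateEntry(str(universe[i]), float(r_comb[i]), int(support[k, i]))
                for i in idx
            ]
            entries.sort(key=lambda e: (-e.r, e.gene_id))
            out.append(
                CorrelateList(seed_id=seed, entries=entries,
                              r_threshold=self.r_threshold, eligible=True)
            )
        return out


# -- module-level convenience wrappers -----------------------------------


def pairwise_correlation(
    compendium: Compendium,
    gene_a: str,
    gene_b: str,
    min_shared_datasets: int = 3,
) -> PairwiseCorrelation:
    engine = CorrelationEngine(compendium, min_shared_datasets=min_shared_datasets)
    return engine.pairwise(gene_a, gene_b)


def correlate_list(
    compendium: Compendium,
    seed_id: str,
    r_threshold: float = 0.5,
    min_shared_datasets: int = 3,
    min_presence_fraction: float = 0.25,
) -> CorrelateList:
    engine = CorrelationEngine(
        compendium,
        r_threshold=r_threshold,
        min_shared_datasets=min_shared_datasets,
        min_presence_fraction=min_presence_fraction,
    )
    return engine.correlate_list(seed_id)
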
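"""Running-sum enrichment over a ranked list, its permutation null, the
leading edge, and the seed50 intra-correlation statistic.

The construction follows the unweighted Kolmogorov–Smirnov form of gene set
enrichment analysis.  Descending a ranked list of N transcripts containing
G members of a designated set ("seeds"), a running sum takes an up-step

    up = sqrt((N - G) / G)

at every seed and a down-step

    down = -sqrt(G / (N - G))

at every non-seed.  The steps satisfy up * |down| = 1 and G*up + (N-G)*down
= 0, so the walk always returns to zero at position N.  The maximum of the
walk is the enrichment score (max ES); all transcripts at or before the
earliest position attaining it form the leading edge (LE).  If all G seeds
occupy the top G positions the walk peaks at sqrt(G * (N - G)), the largest
value any arrangement can reach.

The permutation null reassigns the G seed labels uniformly at random over
the N positions — the list order stays fixed — and records each replicate's
max ES; the empirical p uses the add-one estimator
p = (1 + #{null >= observed}) / (B + 1), which can never return 0.

seed50 is the smallest top fraction of the list (as a percentage) holding
at least half (ceil(G/2)) of the seeds; smaller values mean a more
intra-correlated seed population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .network import RankedMasterList


@dataclass
class EnrichmentProfile:
    N: int
    G: int
    up_step: float
    down_step: float
    running_sum: np.ndarray
    max_es: float
    max_position: int  # 1-based, earliest position attaining max_es
    leading_edge: set[str]
    seed50_percent: float
    perm_p: float | None = None
    null_max_es: np.ndarray | None = None
    rng_seed: int | None = None
    is_seed: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))


def step_scores(N: int, G: int) -> tuple[float, float]:
    """Up- and down-step scores for a list of N transcripts with G seeds."""
    if not 0 < G < N:
        raise ValueError(f"require 0 < G < N, got G={G}, N={N}")
    up = math.sqrt((N - G) / G)
    return up, -1.0 / up


def _profile(ranked: RankedMasterList, seed_set: set[str]) -> EnrichmentProfile:
    genes = ranked.gene_ids
    n = len(genes)
    is_seed = np.fromiter((g in seed_set for g in genes), dtype=bool, count=n)
    g_count = int(is_seed.sum())
    if g_count == 0:
        raise ValueError("seed set does not intersect the ranked list")
    if g_count == n:
        raise ValueError("seed set covers the whole ranked list")
    up, down = step_scores(n, g_count)
    steps = np.where(is_seed, up, down)
    running = np.cumsum(steps)
    # earliest position attaining the maximum, with a float tolerance so
    # exact ties are not broken by accumulated rounding
    peak = float(running.max())
    max_pos = int(np.flatnonzero(running >= peak - 1e-9 * up)[0]) + 1
    max_es = float(running[max_pos - 1])
    le = set(genes[:max_pos])

    half = math.ceil(g_count / 2)
    prefix = int(np.searchsorted(np.cumsum(is_seed), half) + 1)
    s50 = 100.0 * prefix / n

    return EnrichmentProfile(
        N=n, G=g_count, up_step=up, down_step=down,
        running_sum=running, max_es=max_es, max_position=max_pos,
        leading_edge=le, seed50_percent=s50, is_seed=is_seed,
    )


def running_sum_enrichment(
    ranked: RankedMasterList, seed_set: set[str]
) -> EnrichmentProfile:
    """Running-sum profile, max ES, leading edge and seed50 (no null)."""
    return _profile(ranked, seed_set)


def seed50(ranked: RankedMasterList, seed_set: set[str]) -> float:
    """Smallest top percentage of the list containing half the seeds."""
    return _profile(ranked, seed_set).seed50_percent


def _null_max_es(
    n: int, g: int, up: float, down: float, B: int, rng: np.random.Generator
) -> np.ndarray:
    indicator = np.zeros(n, dtype=bool)
    indicator[:g] = True
    perms = np.tile(indicator, (B, 1))
    perms = rng.permuted(perms, axis=1)
    walks = np.cumsum(np.where(perms, up, down), axis=1)
    return walks.max(axis=1)


def permutation_null(
    ranked: RankedMasterList,
    seed_set: set[str],
    B: int = 1000,
    rng_seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Permutation null of the max ES by random seed-label reassignment.

    Each of the B replicates scatters the G seed labels uniformly over the
    fixed list order and re-derives the running sum; p is the add-one
    estimator against the observed max ES.  Deterministic given rng_seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    prof = _profile(ranked, seed_set)
    rng = np.random.default_rng(rng_seed)
    null = _null_max_es(prof.N, prof.G, prof.up_step, prof.down_step, B, rng)
    p = (1 + int((null >= prof.max_es - 1e-12).sum())) / (B + 1)
    return p, null


def enrich(
    ranked: RankedMasterList,
    seed_set: set[str],
    B: int = 1000,
    rng_seed: int = 0,
) -> EnrichmentProfile:
    """Full enrichment profile including the permutation null."""
    prof = _profile(ranked, seed_set)
    rng = np.random.default_rng(rng_seed)
    null = _null_max_es(prof.N, prof.G, prof.up_step, prof.down_step, B, rng)
    p = (1 + int((null >= prof.max_es - 1e-12).sum())) / (B + 1)
    return replace(prof, perm_p=p, null_max_es=null, rng_seed=rng_seed)
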
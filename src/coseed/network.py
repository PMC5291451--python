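"""Merge per-seed correlate lists into a network and a ranked master list.

The network is the union of all seed-correlate pairs; the master list
orders every transcript appearing in any eligible correlate list by its
*occurrence count* — the number of correlate lists that contain it.  Hub
transcripts that co-express with many seeds rise to the top, which is what
the downstream running-sum enrichment exploits.

Ties in occurrence count are broken by descending maximum correlation, then
ascending gene id, so the ranking is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .correlation import CorrelateList


@dataclass
class SeedNetwork:
    nodes: set[str] = field(default_factory=set)
    edges: dict[tuple[str, str], float] = field(default_factory=dict)  # pair -> max r
    r_threshold: float = 0.5

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_list(self) -> list[tuple[str, str, float]]:
        return sorted((a, b, r) for (a, b), r in self.edges.items())


@dataclass
class RankedMasterList:
    entries: list[tuple[str, int]] = field(default_factory=list)  # (gene, count)

    @property
    def N(self) -> int:
        return len(self.entries)

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.entries]

    def __post_init__(self) -> None:
        counts = [c for _, c in self.entries]
        if any(c < 1 for c in counts):
            raise ValueError("occurrence counts must be >= 1")
        if any(c2 > c1 for c1, c2 in zip(counts, counts[1:])):
            raise ValueError("occurrence counts must be non-increasing")


def assemble_network(correlate_lists: list[CorrelateList]) -> SeedNetwork:
    """Union of all seed-correlate pairs across eligible lists.

    Each unordered pair appears once; if a pair is discovered from both
    endpoints the maximum r is retained.  Nodes are all seeds with eligible
    lists plus every listed correlate.  Empty input yields an empty network.
    """
    thresholds = {cl.r_threshold for cl in correlate_lists}
    r_threshold = thresholds.pop() if len(thresholds) == 1 else 0.5
    net = SeedNetwork(r_threshold=r_threshold)
    for cl in correlate_lists:
        if not cl.eligible:
            continue
        net.nodes.add(cl.seed_id)
        for entry in cl.entries:
            net.nodes.add(entry.gene_id)
            pair = (
                (cl.seed_id, entry.gene_id)
                if cl.seed_id < entry.gene_id
                else (entry.gene_id, cl.seed_id)
            )
            prev = net.edges.get(pair)
            if prev is None or entry.r > prev:
                net.edges[pair] = entry.r
    return net


def ranked_master_list(
    correlate_lists: list[CorrelateList], include_seeds: bool = True
) -> RankedMasterList:
    """Order all listed transcripts by correlate-list occurrence count.

    ``occurrence_count(g)`` = number of eligible correlate lists containing
    g.  Seeds appearing in *other* seeds' lists are ranked like any other
    transcript unless ``include_seeds`` is False, in which case the seed ids
    of the supplied lists are excluded from the ranking.
    """
    eligible = [cl for cl in correlate_lists if cl.eligible]
    if not eligible:
        raise ValueError("no eligible correlate lists")
    counts: dict[str, int] = {}
    max_r: dict[str, float] = {}
    for cl in eligible:
        for entry in cl.entries:
            counts[entry.gene_id] = counts.get(entry.gene_id, 0) + 1
            if entry.r > max_r.get(entry.gene_id, float("-inf")):
                max_r[entry.gene_id] = entry.r
    if not include_seeds:
        for cl in correlate_lists:
            counts.pop(cl.seed_id, None)
    order = sorted(counts, key=lambda g: (-counts[g], -max_r[g], g))
    return RankedMasterList(entries=[(g, counts[g]) for g in order])
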
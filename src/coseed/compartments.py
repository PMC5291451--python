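"""Compartment panels: the full ranked-enrichment procedure per seed set.

Running the correlate-list -> network -> ranked-list -> enrichment chain
for several compartment seed sets over one compendium lets their
intra-correlation be compared directly: the compartment whose seeds are most
tightly co-regulated has the smallest seed50.  The same running-sum
machinery also scores an arbitrary transcript class (e.g. ribosomal-protein
transcripts) against an existing ranking.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

from .compendium import Compendium
from .correlation import CorrelationEngine
from .enrichment import EnrichmentProfile, enrich
from .network import RankedMasterList, ranked_master_list


@dataclass
class CompartmentPanel:
    compartments: dict[str, tuple[set[str], EnrichmentProfile]] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)

    @property
    def ordering(self) -> list[str]:
        """Compartment names by ascending seed50 (most intra-correlated first)."""
        return sorted(
            self.compartments,
            key=lambda name: (self.compartments[name][1].seed50_percent, name),
        )


def _compartment_seed(rng_seed: int, name: str) -> int:
    # stable per-compartment sub-seed, independent of processing order
    return (int(rng_seed) ^ zlib.crc32(name.encode())) & 0x7FFFFFFF


def run_panel(
    compendium: Compendium,
    seed_sets: dict[str, set[str]],
    r_threshold: float = 0.5,
    min_shared_datasets: int = 3,
    min_presence_fraction: float = 0.25,
    B: int = 1000,
    rng_seed: int = 0,
) -> CompartmentPanel:
    """Run the full enrichment chain for each compartment seed set.

    A compartment with fewer than 2 eligible seeds is recorded as skipped
    rather than failing the panel.  Per-compartment permutation seeds are
    derived from ``rng_seed`` and the compartment name, so results do not
    depend on processing order.
    """
    if not seed_sets:
        raise ValueError("at least one seed set required")
    engine = CorrelationEngine(
        compendium,
        r_threshold=r_threshold,
        min_shared_datasets=min_shared_datasets,
        min_presence_fraction=min_presence_fraction,
    )
    panel = CompartmentPanel()
    universe = set(compendium.gene_universe)
    for name in sorted(seed_sets):
        seeds = sorted(seed_sets[name] & universe)
        if len(seeds) < 2:
            panel.skipped[name] = "fewer_than_2_seeds_in_universe"
            continue
        lists = engine.correlate_lists(seeds)
        eligible = [cl for cl in lists if cl.eligible]
        if len(eligible) < 2:
            panel.skipped[name] = "fewer_than_2_eligible_seeds"
            continue
        ranked = ranked_master_list(eligible)
        seed_in_list = set(seeds) & set(ranked.gene_ids)
        if not seed_in_list or len(seed_in_list) == ranked.N:
            panel.skipped[name] = "degenerate_ranked_list"
            continue
        profile = enrich(
            ranked, set(seeds), B=B, rng_seed=_compartment_seed(rng_seed, name)
        )
        panel.compartments[name] = (set(seeds), profile)
    return panel


def class_enrichment(
    ranked: RankedMasterList,
    class_set: set[str],
    B: int = 1000,
    rng_seed: int = 0,
) -> EnrichmentProfile:
    """Running-sum enrichment of an arbitrary transcript class.

    Identical machinery to the seed enrichment, with the class taking the
    role of the seed designation — e.g. scoring ribosomal-protein
    transcripts against the mitochondrial ranking.
    """
    return enrich(ranked, class_set, B=B, rng_seed=rng_seed)
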
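"""Reference validation experiments on synthetic compendia.

Each function runs a replicated planted-truth experiment at the package's
reference study conditions (2,000 genes, 10 datasets of 12-30 samples, a
100-gene module, 50 seeds; see :class:`~coseed.simulate.SimParams`) and
returns the per-replicate measurements, leaving pass/fail judgements to the
caller.  They answer the qualitative questions the pipeline exists for:

* does seed50 fall as planted co-regulation strengthens?
* does the strongest compartment win a panel?
* is the leading edge enriched for planted regulator-responsive genes even
  after removing the seeds, and for planted interaction partners of the
  annotated set, increasingly so at higher partner thresholds?
* does EASE guilt-by-association rank the term-dense candidate first?
* are the permutation p and the per-seed above-chance test calibrated under
  the null?

The loading sweep fixes noise_sd = 1.0 so the strongest planted loading
(1.0) sits exactly at the correlation detection threshold (population
within-module r = 1/(1+1) = 0.5): the sweep then spans null, intermediate
and threshold-level co-regulation without saturating, which is what makes
seed50 informative across the whole grid.  Correlate lists in these
experiments accept single-dataset support (min_shared_datasets = 1), the
regime in which chance correlates populate the master list exactly as in a
real heterogeneous compendium.
"""

from __future__ import annotations

import numpy as np

from .compendium import Compendium
from .correlation import CorrelateList, CorrelationEngine
from .crossref import le_flag_chisq, mc_minus_le_fet, per_seed_chance_test, ppi_mc_filter
from .enrichment import EnrichmentProfile, permutation_null, running_sum_enrichment
from .network import RankedMasterList, ranked_master_list
from .prioritize import guilt_by_association, select_candidates
from .simulate import (
    ModuleSpec,
    SimParams,
    SimTruth,
    simulate_annotations,
    simulate_compendium,
    simulate_ppi,
)

MIN_SHARED = 1  # single-dataset support: the chance-background regime


def _eligible_lists(
    comp: Compendium, seeds: set[str]
) -> tuple[CorrelationEngine, list[CorrelateList]]:
    engine = CorrelationEngine(comp, min_shared_datasets=MIN_SHARED)
    lists = [cl for cl in engine.correlate_lists(sorted(seeds)) if cl.eligible]
    return engine, lists


def _profile(comp: Compendium, seeds: set[str]) -> tuple[RankedMasterList, EnrichmentProfile]:
    _, lists = _eligible_lists(comp, seeds)
    ranked = ranked_master_list(lists)
    return ranked, running_sum_enrichment(ranked, seeds)


def seed50_loading_sweep(
    loadings: tuple[float, ...] = (0.0, 0.5, 1.0),
    n_reps: int = 20,
    base_seed: int = 10_000,
    noise_sd: float = 1.0,
) -> dict[float, list[float]]:
    """seed50 per replicate at each planted loading strength, fixed noise."""
    out: dict[float, list[float]] = {l: [] for l in loadings}
    for loading in loadings:
        for rep in range(n_reps):
            params = SimParams(
                module_specs=(ModuleSpec("m1", 100, loading, 0.1),),
                noise_sd=noise_sd,
                rng_seed=base_seed + rep,
            )
            comp, truth = simulate_compendium(params)
            _, prof = _profile(comp, truth.seed_set)
            out[loading].append(prof.seed50_percent)
    return out


def panel_winner(
    n_reps: int = 20,
    base_seed: int = 20_000,
    strong: float = 1.0,
    weak: float = 0.3,
    noise_sd: float = 1.0,
) -> list[tuple[float, float]]:
    """(strong seed50, weak seed50) per replicate for a two-compartment panel."""
    out = []
    for rep in range(n_reps):
        params = SimParams(
            module_specs=(
                ModuleSpec("strong", 100, strong, 0.1),
                ModuleSpec("weak", 100, weak, 0.1),
            ),
            noise_sd=noise_sd,
            seed_overlap_fraction=0.0,
            rng_seed=base_seed + rep,
        )
        comp, truth = simulate_compendium(params)
        rng = np.random.default_rng(base_seed + rep + 1)
        pair = []
        for name in ("strong", "weak"):
            seeds = set(
                rng.choice(sorted(truth.module_genes(name)), 50, replace=False)
            )
            _, prof = _profile(comp, seeds)
            pair.append(prof.seed50_percent)
        out.append((pair[0], pair[1]))
    return out


def _default_truthful_run(rep_seed: int) -> tuple[Compendium, SimTruth, EnrichmentProfile]:
    comp, truth = simulate_compendium(SimParams(rng_seed=rep_seed))
    truth = simulate_annotations(truth, 0.8, 0.05, [], rng_seed=rep_seed + 1)
    _, prof = _profile(comp, truth.seed_set)
    return comp, truth, prof


def le_responsive_chisq(n_reps: int = 20, base_seed: int = 30_000) -> list[float]:
    """Seed-removed chi-square p for planted responsive genes in the LE."""
    out = []
    for rep in range(n_reps):
        comp, truth, prof = _default_truthful_run(base_seed + 10 * rep)
        res = le_flag_chisq(
            prof.leading_edge,
            truth.regulator_responsive_set,
            set(comp.gene_universe),
            exclude=truth.seed_set,
        )
        out.append(res.p_value)
    return out


def ppi_partner_trend(
    n_reps: int = 20,
    base_seed: int = 40_000,
    thresholds: tuple[int, ...] = (1, 2, 5, 10),
) -> list[list[float]]:
    """Odds ratios (per replicate, per partner threshold) for planted-PPI
    MC- partner residence in the LE."""
    out = []
    for rep in range(n_reps):
        comp, truth, prof = _default_truthful_run(base_seed + 10 * rep)
        ppi = simulate_ppi(truth, 0.5, 0.01, rng_seed=base_seed + 10 * rep + 2)
        _, partnership = ppi_mc_filter(ppi, truth.seed_set)
        ors = [
            mc_minus_le_fet(
                partnership, prof.leading_edge, set(comp.gene_universe),
                t, mc_set=truth.seed_set,
            ).odds_ratio
            for t in thresholds
        ]
        out.append(ors)
    return out


def candidate_ranking(n_reps: int = 20, base_seed: int = 50_000) -> list[bool]:
    """Whether the candidate with double the planted term density ranks first."""
    out = []
    for rep in range(n_reps):
        seed = base_seed + 10 * rep
        params = SimParams(
            module_specs=(
                ModuleSpec("dense", 100, 1.0, 0.1),
                ModuleSpec("sparse", 100, 1.0, 0.1),
            ),
            seed_overlap_fraction=0.0,
            rng_seed=seed,
        )
        comp, truth = simulate_compendium(params)
        truth = simulate_annotations(
            truth, 0.0, 0.0,
            [("T_dense", 0.8, 0.0, "dense"), ("T_sparse", 0.4, 0.02, "sparse")],
            rng_seed=seed + 1,
        )
        term = truth.pathway_annotations["T_dense"] | truth.pathway_annotations["T_sparse"]
        engine = CorrelationEngine(comp, min_shared_datasets=MIN_SHARED)
        dense_cands = [g for g in sorted(truth.module_genes("dense"))
                       if engine.correlate_list(g).eligible][:1]
        sparse_cands = [g for g in sorted(truth.module_genes("sparse"))
                        if engine.correlate_list(g).eligible][:4]
        reports = [
            guilt_by_association(c, engine, {"T": term}, ["T"],
                                 len(comp.gene_universe))
            for c in dense_cands + sparse_cands
        ]
        selected = select_candidates(reports)
        out.append(bool(selected) and bool(dense_cands)
                   and selected[0].candidate_id == dense_cands[0])
    return out


def above_chance_fractions(n_reps: int = 20, base_seed: int = 60_000) -> list[float]:
    """Fraction of eligible seeds above chance under a strong planted module
    (loading 1.0, noise_sd 0.2, 50 seeds)."""
    out = []
    for rep in range(n_reps):
        comp, truth = simulate_compendium(
            SimParams(noise_sd=0.2, rng_seed=base_seed + rep)
        )
        _, lists = _eligible_lists(comp, truth.seed_set)
        flags = [
            per_seed_chance_test(cl, truth.seed_set, len(comp.gene_universe))[3]
            for cl in lists
        ]
        out.append(sum(flags) / len(flags))
    return out


def null_above_chance_rate(
    n_reps: int = 10, base_seed: int = 70_000
) -> tuple[int, int]:
    """(false positives, eligible lists) under a compendium with no planted
    co-regulation (loading 0)."""
    fp = total = 0
    for rep in range(n_reps):
        comp, truth = simulate_compendium(
            SimParams(module_specs=(ModuleSpec("m1", 100, 0.0, 0.0),),
                      noise_sd=1.0, rng_seed=base_seed + rep)
        )
        _, lists = _eligible_lists(comp, truth.seed_set)
        for cl in lists:
            total += 1
            fp += per_seed_chance_test(
                cl, truth.seed_set, len(comp.gene_universe)
            )[3]
    return fp, total


def permutation_p_under_null(
    n_runs: int = 200,
    N: int = 200,
    G: int = 20,
    B: int = 500,
    base_seed: int = 80_000,
) -> list[float]:
    """Permutation p-values for randomly placed seed labels (null)."""
    ranked = RankedMasterList(entries=[(f"g{i:05d}", 1) for i in range(N)])
    genes = np.array(ranked.gene_ids)
    rng = np.random.default_rng(base_seed)
    out = []
    for run in range(n_runs):
        seeds = set(rng.choice(genes, size=G, replace=False))
        p, _ = permutation_null(ranked, seeds, B=B, rng_seed=base_seed + 1 + run)
        out.append(p)
    return out
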
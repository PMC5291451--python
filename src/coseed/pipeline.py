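"""End-to-end pipeline orchestration.

Stages: simulate (optional) -> correlate -> network -> enrich -> crossref
-> prioritize.  Every stage reads its inputs from files and writes its
artifact back to disk, so chaining the individual stage functions (or CLI
subcommands) is exactly equivalent to :func:`run_pipeline`.  All artifacts
carry a provenance header (tool version, config hash, rng seed) and every
stage logs its record counts.
"""

from __future__ import annotations

import logging
from pathlib import Path

from . import io
from .compendium import Compendium
from .config import PipelineConfig
from .correlation import CorrelationEngine
from .crossref import (
    count_above_chance,
    le_flag_chisq,
    mc_minus_le_fet,
    per_seed_chance_test,
    ppi_mc_filter,
)
from .enrichment import enrich
from .network import assemble_network, ranked_master_list
from .prioritize import guilt_by_association, recurrent_candidates, select_candidates
from .simulate import ModuleSpec, SimParams, simulate_annotations, simulate_compendium, simulate_ppi

log = logging.getLogger("coseed")


def _header(config: PipelineConfig) -> list[str]:
    return io.header_lines(config_hash=config.config_hash, rng_seed=config.rng_seed)


def _effective_genome_size(config: PipelineConfig, compendium: Compendium) -> int:
    # with simulated data the simulated universe *is* the genome
    if config.skip_simulate:
        return config.genome_size
    return len(compendium.gene_universe)


def _paths(config: PipelineConfig, base: Path) -> dict[str, Path]:
    out = base / config.out_dir
    return {
        "compendium": base / config.compendium_dir,
        "gene_sets": base / config.seeds_gmt,
        "ppi": base / config.ppi_tsv,
        "module_list": base / config.module_list,
        "pathways": base / config.pathway_gmt,
        "out": out,
        "correlate_lists": out / "correlate_lists.tsv",
        "network": out / "network.tsv",
        "master_list": out / "master_list.tsv",
        "profile": out / "enrichment_profile.tsv",
        "crossref": out / "crossref_report.tsv",
        "candidates": out / "candidates.tsv",
    }


def stage_simulate(config: PipelineConfig, base: Path) -> None:
    p = _paths(config, base)
    params = SimParams(
        n_datasets=config.sim_n_datasets,
        samples_per_dataset=config.sim_samples_per_dataset,
        n_genes=config.sim_n_genes,
        module_specs=(
            ModuleSpec("module1", config.sim_module_size,
                       config.sim_loading_mean, config.sim_loading_sd),
        ),
        noise_sd=config.sim_noise_sd,
        seed_overlap_fraction=config.sim_seed_overlap_fraction,
        dropout_fraction=config.sim_dropout_fraction,
        rng_seed=config.rng_seed,
    )
    compendium, truth = simulate_compendium(params)
    ppi = simulate_ppi(truth, config.sim_ppi_p_within, config.sim_ppi_p_between,
                       rng_seed=config.rng_seed + 1)
    truth = simulate_annotations(
        truth,
        config.sim_responsive_fraction_module,
        config.sim_responsive_fraction_background,
        [(t, config.sim_term_module_fraction, config.sim_term_background_fraction)
         for t in config.required_terms],
        rng_seed=config.rng_seed + 2,
    )
    header = _header(config)
    io.write_compendium_dir(compendium, p["compendium"], header)
    module_genes = truth.module_genes("module1")
    sets: dict[str, set[str]] = {
        config.seeds_set_name: truth.seed_set,
        config.responsive_set_name: truth.regulator_responsive_set,
        "module1": module_genes,
    }
    io.write_gmt(sets, p["gene_sets"])
    io.write_gmt(truth.pathway_annotations, p["pathways"])
    io.write_ppi_tsv(ppi, p["ppi"], header)
    io.write_gene_list(module_genes, p["module_list"])
    log.info("simulate: %d datasets, %d genes, %d seeds, %d PPI edges",
             compendium.n_datasets, len(compendium.gene_universe),
             len(truth.seed_set), len(ppi))


def _load_inputs(config: PipelineConfig, base: Path):
    p = _paths(config, base)
    compendium = io.read_compendium_dir(p["compendium"])
    gene_sets = io.read_gmt(p["gene_sets"])
    if config.seeds_set_name not in gene_sets:
        raise ValueError(f"seed set {config.seeds_set_name!r} missing from {p['gene_sets']}")
    seeds = gene_sets[config.seeds_set_name]
    return compendium, gene_sets, seeds


def _engine(config: PipelineConfig, compendium: Compendium) -> CorrelationEngine:
    return CorrelationEngine(
        compendium,
        r_threshold=config.r_threshold,
        min_shared_datasets=config.min_shared_datasets,
        min_presence_fraction=config.min_presence_fraction,
    )


def stage_correlate(config: PipelineConfig, base: Path) -> None:
    p = _paths(config, base)
    compendium, _sets, seeds = _load_inputs(config, base)
    engine = _engine(config, compendium)
    lists = engine.correlate_lists(sorted(seeds))
    io.write_correlate_lists(lists, p["correlate_lists"], _header(config))
    n_eligible = sum(cl.eligible for cl in lists)
    log.info("correlate: %d/%d eligible seeds, %d total entries",
             n_eligible, len(lists), sum(len(cl.entries) for cl in lists))


def stage_network(config: PipelineConfig, base: Path) -> None:
    p = _paths(config, base)
    lists = io.read_correlate_lists(p["correlate_lists"], config.r_threshold)
    net = assemble_network(lists)
    ranked = ranked_master_list(lists)
    io.write_network(net, p["network"], _header(config))
    io.write_master_list(ranked, p["master_list"], _header(config))
    log.info("network: %d nodes, %d edges; master list of %d transcripts",
             len(net.nodes), net.n_edges, ranked.N)


def stage_enrich(config: PipelineConfig, base: Path) -> None:
    p = _paths(config, base)
    _compendium, _sets, seeds = _load_inputs(config, base)
    ranked = io.read_master_list(p["master_list"])
    profile = enrich(ranked, seeds, B=config.B_permutations, rng_seed=config.rng_seed)
    io.write_enrichment_profile(profile, ranked, p["profile"], _header(config))
    log.info("enrich: N=%d G=%d max_es=%.3f seed50=%.2f%% perm_p=%.4g",
             profile.N, profile.G, profile.max_es, profile.seed50_percent,
             profile.perm_p)


def stage_crossref(config: PipelineConfig, base: Path) -> None:
    p = _paths(config, base)
    compendium, gene_sets, seeds = _load_inputs(config, base)
    genome_size = _effective_genome_size(config, compendium)
    universe = set(compendium.gene_universe)
    lists = io.read_correlate_lists(p["correlate_lists"], config.r_threshold)
    ranked = io.read_master_list(p["master_list"])
    from .enrichment import running_sum_enrichment

    profile = running_sum_enrichment(ranked, seeds)
    le = profile.leading_edge

    rows = ["analysis\ta\tb\tc\td\tstatistic\tp_value\tmethod\todds_ratio"]

    def add(name: str, res) -> None:
        (a, b), (c, d) = res.table
        stat = "na" if res.statistic is None else f"{res.statistic:.6f}"
        rows.append(f"{name}\t{a}\t{b}\t{c}\t{d}\t{stat}\t{res.p_value:.6g}"
                    f"\t{res.method}\t{res.odds_ratio:.6g}")

    count, fraction = count_above_chance(lists, seeds, genome_size, config.alpha_chance)
    n_eligible = sum(cl.eligible for cl in lists)
    rows.append(f"# above_chance_seeds\t{count}\tof\t{n_eligible}\tfraction\t{fraction:.4f}")
    for cl in lists:
        if not cl.eligible:
            continue
        obs, exp, res, above = per_seed_chance_test(
            cl, seeds, genome_size, config.alpha_chance
        )
        add(f"per_seed_chance:{cl.seed_id}:obs={obs:.4f}:exp={exp:.4f}:above={int(above)}", res)

    responsive = gene_sets.get(config.responsive_set_name, set())
    if responsive:
        add("le_responsive_chisq", le_flag_chisq(le, responsive, universe))
        add("le_responsive_chisq_seeds_removed",
            le_flag_chisq(le, responsive, universe, exclude=seeds))

    if p["ppi"].exists():
        ppi = io.read_ppi_tsv(p["ppi"])
        kept, partnership = ppi_mc_filter(ppi, seeds)
        rows.append(f"# ppi_kept_edges\t{len(kept)}\tmc_minus_proteins"
                    f"\t{len(partnership.mc_minus_partners)}")
        for t in config.partner_thresholds:
            add(f"mc_minus_le_fet:min_partners={t}",
                mc_minus_le_fet(partnership, le, universe, t, mc_set=seeds))

    io._write_with_header(p["crossref"], _header(config), "\n".join(rows) + "\n")
    log.info("crossref: %d/%d seeds above chance (%.1f%%)",
             count, n_eligible, 100 * fraction)


def stage_prioritize(config: PipelineConfig, base: Path) -> None:
    p = _paths(config, base)
    compendium, _gene_sets, seeds = _load_inputs(config, base)
    genome_size = _effective_genome_size(config, compendium)
    ranked = io.read_master_list(p["master_list"])
    from .enrichment import running_sum_enrichment

    le = running_sum_enrichment(ranked, seeds).leading_edge
    module = io.read_gene_list(p["module_list"])
    terms = io.read_gmt(p["pathways"])
    engine = _engine(config, compendium)
    candidates = sorted(recurrent_candidates(le, module))
    reports = [
        guilt_by_association(c, engine, terms, list(config.required_terms),
                             genome_size, alpha=config.alpha_ease)
        for c in candidates
    ]
    selected = select_candidates(reports, alpha=config.alpha_ease)
    rows = ["candidate\tpasses\trank_score\t" +
            "\t".join(f"{t}_p\t{t}_neglog10p\t{t}_k\t{t}_n" for t in config.required_terms)]
    ordered = selected + [r for r in reports if r not in selected]
    for rep in ordered:
        cells = [rep.candidate_id, str(int(rep.passes)), f"{rep.rank_score:.4f}"]
        for t in config.required_terms:
            s = rep.term_scores.get(t)
            if s is None:
                cells += ["na", "na", "na", "na"]
            else:
                cells += [f"{s.ease_p:.6g}", f"{s.neglog10_p:.4f}", str(s.k), str(s.n)]
        rows.append("\t".join(cells))
    io._write_with_header(p["candidates"], _header(config), "\n".join(rows) + "\n")
    log.info("prioritize: %d recurrent candidates, %d passing",
             len(candidates), len(selected))


STAGES = {
    "simulate": stage_simulate,
    "correlate": stage_correlate,
    "network": stage_network,
    "enrich": stage_enrich,
    "crossref": stage_crossref,
    "prioritize": stage_prioritize,
}


def run_pipeline(config: PipelineConfig, base: str | Path = ".") -> int:
    """Run every stage in order; returns 0 on success.

    Any stage failure raises :class:`PipelineError` naming the stage.
    Deterministic given ``config.rng_seed``: a rerun with an identical
    config produces byte-identical artifacts.
    """
    base = Path(base)
    order = ["simulate", "correlate", "network", "enrich", "crossref", "prioritize"]
    if config.skip_simulate:
        order = order[1:]
    for name in order:
        try:
            STAGES[name](config, base)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    return 0


class PipelineError(RuntimeError):
    pass
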
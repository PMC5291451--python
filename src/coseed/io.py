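"""Readers and writers for the pipeline's plain-text formats.

Everything is tab-separated text for inspectability: expression matrices
(genes x samples with a header row), GMT gene sets, two-column PPI edge
lists, one-id-per-line gene lists, and the per-stage result tables.  Output
files carry comment-prefixed header lines recording the tool version, a
config hash and the rng seed, so every artifact states its provenance.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import pandas as pd

from . import __version__
from .compendium import Compendium, Dataset
from .correlation import CorrelateEntry, CorrelateList
from .crossref import PPIEdgeList
from .enrichment import EnrichmentProfile
from .network import RankedMasterList, SeedNetwork

log = logging.getLogger("coseed")


def header_lines(config_hash: str | None = None, rng_seed: int | None = None) -> list[str]:
    parts = [f"coseed v{__version__}"]
    if config_hash is not None:
        parts.append(f"config_hash={config_hash}")
    if rng_seed is not None:
        parts.append(f"rng_seed={rng_seed}")
    return ["# " + " ".join(parts)]


def _write_with_header(path: Path, header: list[str], body: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header:
            fh.write(line + "\n")
        fh.write(body)


# -- expression matrices -------------------------------------------------


def read_expression_tsv(path: str | Path, dataset_id: str | None = None) -> Dataset:
    """Read one genes x samples expression matrix; duplicate gene rows are a
    hard error."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene rows: {dups[:5]}")
    return Dataset(dataset_id=dataset_id or path.stem, expr=df)


def write_expression_tsv(
    dataset: Dataset, path: str | Path, header: list[str] | None = None
) -> None:
    body = dataset.expr.to_csv(sep="\t", index_label="gene_id", float_format="%.10g")
    _write_with_header(Path(path), header or [], body)


def read_compendium_dir(directory: str | Path) -> Compendium:
    """Read every ``*.tsv`` in a directory as one dataset each."""
    directory = Path(directory)
    files = sorted(directory.glob("*.tsv"))
    if not files:
        raise FileNotFoundError(f"no .tsv datasets under {directory}")
    return Compendium(datasets=[read_expression_tsv(f) for f in files])


def write_compendium_dir(
    compendium: Compendium, directory: str | Path, header: list[str] | None = None
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for ds in compendium.datasets:
        write_expression_tsv(ds, directory / f"{ds.dataset_id}.tsv", header)


# -- gene sets -----------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: name <TAB> description <TAB> gene1 <TAB> gene2 ...

    Duplicate genes within a line are deduplicated with a warning; malformed
    lines are reported with their line number.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and >= 1 gene"
                )
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            unique = set(genes)
            if len(unique) < len(genes):
                log.warning("%s:%d: %d duplicate gene(s) in set %r deduplicated",
                            path, lineno, len(genes) - len(unique), name)
            sets[name] = unique
    return sets


def write_gmt(
    sets: dict[str, Iterable[str]],
    path: str | Path,
    descriptions: dict[str, str] | None = None,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name in sets:
            desc = (descriptions or {}).get(name, "na")
            genes = sorted(set(sets[name]))
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_gene_list(path: str | Path) -> set[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out: set[str] = set()
    with open(path) as fh:
        for raw in fh:
            g = raw.strip()
            if g and not g.startswith("#"):
                out.add(g)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for g in sorted(set(genes)):
            fh.write(g + "\n")


# -- PPI edges -----------------------------------------------------------


def read_ppi_tsv(path: str | Path) -> PPIEdgeList:
    """Two-column tab-separated protein pairs; self-pairs dropped and logged."""
    edges: set[tuple[str, str]] = set()
    n_self = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated ids")
            a, b = fields[0], fields[1]
            if a == b:
                n_self += 1
                continue
            edges.add((a, b) if a < b else (b, a))
    if n_self:
        log.warning("%s: dropped %d self-pair(s)", path, n_self)
    return PPIEdgeList(edges=edges)


def write_ppi_tsv(
    edges: PPIEdgeList, path: str | Path, header: list[str] | None = None
) -> None:
    body = "".join(f"{a}\t{b}\n" for a, b in sorted(edges.edges))
    _write_with_header(Path(path), header or [], body)


# -- stage artifacts -----------------------------------------------------


def write_correlate_lists(
    lists: list[CorrelateList], path: str | Path, header: list[str] | None = None
) -> None:
    rows = ["seed_id\tgene_id\tr\tn_datasets_supporting\teligible"]
    for cl in lists:
        if not cl.eligible:
            rows.append(f"{cl.seed_id}\t.\t.\t.\t0")
            continue
        for e in cl.entries:
            rows.append(f"{cl.seed_id}\t{e.gene_id}\t{e.r:.6f}\t{e.n_datasets_supporting}\t1")
    _write_with_header(Path(path), header or [], "\n".join(rows) + "\n")


def read_correlate_lists(path: str | Path, r_threshold: float = 0.5) -> list[CorrelateList]:
    by_seed: dict[str, CorrelateList] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("seed_id\t"):
                continue
            seed, gene, r, n, eligible = line.split("\t")
            if eligible == "0":
                by_seed[seed] = CorrelateList(
                    seed_id=seed, entries=[], r_threshold=r_threshold, eligible=False
                )
                continue
            cl = by_seed.setdefault(
                seed, CorrelateList(seed_id=seed, r_threshold=r_threshold)
            )
            cl.entries.append(CorrelateEntry(gene, float(r), int(n)))
    return list(by_seed.values())


def write_network(
    net: SeedNetwork,
    path: str | Path,
    header: list[str] | None = None,
    min_r: float | None = None,
) -> None:
    """Edge-list export; ``min_r`` is a display-only filter for viewing."""
    rows = ["gene_a\tgene_b\tr"]
    for a, b, r in net.edge_list():
        if min_r is not None and r < min_r:
            continue
        rows.append(f"{a}\t{b}\t{r:.6f}")
    _write_with_header(Path(path), header or [], "\n".join(rows) + "\n")


def write_master_list(
    ranked: RankedMasterList, path: str | Path, header: list[str] | None = None
) -> None:
    rows = ["rank\tgene_id\toccurrence_count"]
    for i, (g, c) in enumerate(ranked.entries, start=1):
        rows.append(f"{i}\t{g}\t{c}")
    _write_with_header(Path(path), header or [], "\n".join(rows) + "\n")


def read_master_list(path: str | Path) -> RankedMasterList:
    entries: list[tuple[str, int]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("rank\t"):
                continue
            _rank, gene, count = line.split("\t")
            entries.append((gene, int(count)))
    return RankedMasterList(entries=entries)


def write_enrichment_profile(
    profile: EnrichmentProfile,
    ranked: RankedMasterList,
    path: str | Path,
    header: list[str] | None = None,
) -> None:
    summary = [
        f"# N={profile.N} G={profile.G} up_step={profile.up_step:.6f} "
        f"down_step={profile.down_step:.6f} max_es={profile.max_es:.6f} "
        f"max_position={profile.max_position} seed50_percent={profile.seed50_percent:.4f} "
        f"perm_p={profile.perm_p if profile.perm_p is not None else 'na'} "
        f"B={len(profile.null_max_es) if profile.null_max_es is not None else 0} "
        f"rng_seed={profile.rng_seed if profile.rng_seed is not None else 'na'}"
    ]
    rows = ["position\tgene_id\tis_seed\trunning_sum"]
    for i, (g, _c) in enumerate(ranked.entries):
        rows.append(f"{i + 1}\t{g}\t{int(profile.is_seed[i])}\t{profile.running_sum[i]:.6f}")
    _write_with_header(Path(path), (header or []) + summary, "\n".join(rows) + "\n")
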
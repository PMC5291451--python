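"""Cross-referencing the network against external gene sets.

Three families of checks, all reducing to 2x2 contingency analysis:

* per-seed "above chance" tests — does a seed's correlate list contain more
  annotated (e.g. mitochondrial) transcripts than its genome-wide share
  predicts? — and their count over all eligible seeds;
* leading-edge x flag-set chi-square (e.g. regulator-responsive genes in vs
  out of the leading edge), with an optional exclusion set so enrichment can
  be re-tested after removing the seeds themselves;
* protein-interaction screening: keep only edges joining one annotated (MC+)
  and one unannotated (MC-) protein, count each MC- protein's distinct MC+
  partners, and Fisher-test the residence of high-partner-count MC- proteins
  inside the leading edge at increasing partner thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

from .stats import ContingencyResult, chi_square_2x2, fisher_exact_2x2

if TYPE_CHECKING:  # pragma: no cover
    from .correlation import CorrelateList


def _norm_edge(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


@dataclass
class PPIEdgeList:
    """Unordered, deduplicated protein-interaction pairs; no self-pairs."""

    edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        cleaned = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-pair {a!r}")
            cleaned.add(_norm_edge(a, b))
        self.edges = cleaned

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def proteins(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out


@dataclass
class MCPartnership:
    """Distinct annotated-partner counts per unannotated protein."""

    mc_minus_partners: dict[str, int] = field(default_factory=dict)

    def retained(self, min_partners: int) -> set[str]:
        return {p for p, c in self.mc_minus_partners.items() if c >= min_partners}


def per_seed_chance_test(
    clist: "CorrelateList",
    seed_universe: set[str],
    genome_size: int,
    alpha: float = 1e-4,
) -> tuple[float, float, ContingencyResult, bool]:
    """Test one correlate list for above-chance annotated-gene content.

    The by-chance expectation for the annotated fraction of any list is
    ``|seed_universe| / genome_size``.  The observed fraction is compared to
    it by a one-sided Fisher exact test on

        (annotated in list, unannotated in list;
         annotated not in list, remainder of genome)

    ``above_chance`` requires both observed > expected and Fisher p < alpha.
    Returns ``(observed_fraction, expected_fraction, result, above_chance)``.
    """
    if genome_size < len(seed_universe):
        raise ValueError("genome_size must be >= |seed_universe|")
    expected = len(seed_universe) / genome_size
    genes = [e.gene_id for e in clist.entries]
    if not genes:
        result = ContingencyResult(
            table=((0, 0), (len(seed_universe), genome_size - len(seed_universe))),
            statistic=None, p_value=1.0,
            method="fisher_one_sided_greater", odds_ratio=0.0,
        )
        return 0.0, expected, result, False
    a = sum(1 for g in genes if g in seed_universe)
    b = len(genes) - a
    c = len(seed_universe) - a
    d = genome_size - a - b - c
    if d < 0:
        raise ValueError("genome_size too small for list and universe counts")
    result = fisher_exact_2x2(((a, b), (c, d)))
    observed = a / len(genes)
    above = observed > expected and result.p_value < alpha
    return observed, expected, result, above


def count_above_chance(
    lists: Iterable["CorrelateList"],
    seed_universe: set[str],
    genome_size: int,
    alpha: float = 1e-4,
) -> tuple[int, float]:
    """Count eligible correlate lists with above-chance annotated content."""
    eligible = [cl for cl in lists if cl.eligible]
    if not eligible:
        raise ValueError("no eligible correlate lists")
    count = sum(
        1
        for cl in eligible
        if per_seed_chance_test(cl, seed_universe, genome_size, alpha)[3]
    )
    return count, count / len(eligible)


def le_flag_chisq(
    le_set: set[str],
    flag_set: set[str],
    universe: set[str],
    exclude: set[str] = frozenset(),
) -> ContingencyResult:
    """Chi-square for flag-set enrichment inside the leading edge.

    The 2x2 table crosses (in / out of leading edge) with (flagged /
    unflagged) over ``universe - exclude``; pass the seed set as ``exclude``
    to ask whether the enrichment persists once the seeds are removed.
    """
    pop = set(universe) - set(exclude)
    le = le_set & pop
    flag = flag_set & pop
    a = len(le & flag)
    b = len(le) - a
    c = len(flag) - a
    d = len(pop) - a - b - c
    return chi_square_2x2(((a, b), (c, d)))


def ppi_mc_filter(
    edges: PPIEdgeList, mc_set: set[str]
) -> tuple[PPIEdgeList, MCPartnership]:
    """Keep edges with exactly one annotated endpoint; count MC- partnerships.

    Edges joining two annotated (MC+/MC+) or two unannotated (MC-/MC-)
    proteins are dropped.  For each MC- protein appearing in a kept edge the
    partnership records its number of *distinct* MC+ partners.
    """
    kept: set[tuple[str, str]] = set()
    partners: dict[str, set[str]] = {}
    for a, b in edges.edges:
        a_in, b_in = a in mc_set, b in mc_set
        if a_in == b_in:
            continue
        kept.add(_norm_edge(a, b))
        minus, plus = (b, a) if a_in else (a, b)
        partners.setdefault(minus, set()).add(plus)
    counts = {p: len(s) for p, s in partners.items()}
    return PPIEdgeList(edges=kept), MCPartnership(mc_minus_partners=counts)


def mc_minus_le_fet(
    partnership: MCPartnership,
    le_set: set[str],
    universe: set[str],
    min_partners: int,
    mc_set: set[str] = frozenset(),
) -> ContingencyResult:
    """Fisher test: MC- proteins with >= min_partners annotated partners in
    vs out of the leading edge.

    The population is ``universe - mc_set`` (MC- transcripts only, since the
    classification concerns unannotated proteins).  An empty retained set
    yields p = 1.
    """
    if min_partners < 1:
        raise ValueError("min_partners must be positive")
    pop = set(universe) - set(mc_set)
    retained = partnership.retained(min_partners) & pop
    le = le_set & pop
    if not retained:
        return ContingencyResult(
            table=((0, len(le)), (0, len(pop) - len(le))),
            statistic=None, p_value=1.0,
            method="fisher_one_sided_greater", odds_ratio=0.0,
        )
    a = len(retained & le)
    b = len(le) - a
    c = len(retained) - a
    d = len(pop) - a - b - c
    return fisher_exact_2x2(((a, b), (c, d)))
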
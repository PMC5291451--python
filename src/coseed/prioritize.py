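"""Guilt-by-association candidate prioritization.

Candidates are the transcripts nominated twice: once by the leading edge of
the compendium-wide enrichment and once by an externally supplied disease
module gene list.  Each recurrent candidate's own correlate list is then
scored for enrichment of required pathway terms with the EASE statistic —
the premise being that a transcript whose co-expressed partners are
saturated with a disease term is itself a plausible participant.  A
candidate passes when every required term scores EASE p <= alpha, and
passing candidates are ranked by the sum of their -log10 p values (largest
first), i.e. by the product of their term p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

from .correlation import CorrelationEngine
from .stats import ease_score


class TermScore(NamedTuple):
    ease_p: float
    neglog10_p: float
    k: int
    n: int
    K: int
    M: int


@dataclass
class CandidateReport:
    candidate_id: str
    term_scores: dict[str, TermScore] = field(default_factory=dict)
    passes: bool = False
    rank_score: float = 0.0
    reason: str | None = None  # set when the candidate could not be scored


def recurrent_candidates(le_set: set[str], module_genes: set[str]) -> set[str]:
    """Transcripts nominated by both the leading edge and the disease module."""
    return set(le_set) & set(module_genes)


def guilt_by_association(
    candidate: str,
    engine: CorrelationEngine,
    term_annotations: dict[str, set[str]],
    required_terms: list[str],
    genome_size: int,
    alpha: float = 0.05,
) -> CandidateReport:
    """Score one candidate's correlate list for required-term enrichment.

    For each required term the EASE score is computed on (k = term genes in
    the candidate's correlate list, n = list size, K = term genes in the
    population, M = genome_size).  ``passes`` requires EASE p <= alpha for
    every required term; ``rank_score`` is the sum of -log10 p.
    """
    for term in required_terms:
        if term not in term_annotations:
            raise KeyError(f"required term {term!r} has no annotation set")
    clist = engine.correlate_list(candidate)
    if not clist.eligible:
        return CandidateReport(candidate_id=candidate, passes=False,
                               reason="ineligible_in_engine")
    genes = set(clist.gene_ids)
    n = len(genes)
    scores: dict[str, TermScore] = {}
    for term in required_terms:
        term_genes = term_annotations[term]
        big_k = len(term_genes)
        k = len(genes & term_genes)
        result = ease_score(k, n, big_k, genome_size)
        p = result.p_value
        scores[term] = TermScore(
            ease_p=p, neglog10_p=-math.log10(p), k=k, n=n, K=big_k, M=genome_size
        )
    passes = bool(scores) and all(s.ease_p <= alpha for s in scores.values())
    rank = sum(s.neglog10_p for s in scores.values())
    return CandidateReport(
        candidate_id=candidate, term_scores=scores, passes=passes, rank_score=rank
    )


def select_candidates(
    reports: list[CandidateReport],
    alpha: float = 0.05,
    rank_method: str = "sum",
) -> list[CandidateReport]:
    """Retain passing candidates and rank them, best first.

    ``rank_method="sum"`` ranks by the sum of -log10 p over required terms
    (the default); ``"min"`` ranks by the weakest term alone.  Ties break by
    ascending candidate id, so the output is independent of input order.
    """
    if rank_method not in ("sum", "min"):
        raise ValueError(f"unknown rank_method {rank_method!r}")
    kept = []
    for rep in reports:
        if not rep.term_scores or rep.reason is not None:
            continue
        if not all(s.ease_p <= alpha for s in rep.term_scores.values()):
            continue
        if rank_method == "sum":
            score = sum(s.neglog10_p for s in rep.term_scores.values())
        else:
            score = min(s.neglog10_p for s in rep.term_scores.values())
        kept.append((score, rep))
    kept.sort(key=lambda t: (-t[0], t[1].candidate_id))
    out = []
    for score, rep in kept:
        rep.rank_score = score
        rep.passes = True
        out.append(rep)
    return out
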
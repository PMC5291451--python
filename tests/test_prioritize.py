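"""Candidate prioritization: recurrence intersection, EASE
guilt-by-association, ranking contract."""

import numpy as np
import pytest

from coseed import (
    CorrelationEngine,
    ModuleSpec,
    SimParams,
    guilt_by_association,
    recurrent_candidates,
    select_candidates,
    simulate_annotations,
    simulate_compendium,
)
from coseed.prioritize import CandidateReport, TermScore

from test_stats import hypergeom_upper_tail


def _report(cand, scores):
    return CandidateReport(
        candidate_id=cand,
        term_scores={
            t: TermScore(p, nl, 5, 10, 20, 100) for t, (p, nl) in scores.items()
        },
    )


class TestRecurrentCandidates:
    def test_set_semantics(self):
        assert recurrent_candidates({"A", "B", "C"}, {"B", "C", "D"}) == {"B", "C"}
        assert recurrent_candidates({"A"}, {"B"}) == set()
        assert recurrent_candidates({"A", "B"}, {"A", "B"}) == {"A", "B"}

    def test_commutative_and_idempotent(self):
        x, y = {"A", "B"}, {"B", "C"}
        assert recurrent_candidates(x, y) == recurrent_candidates(y, x)
        r = recurrent_candidates(x, y)
        assert recurrent_candidates(r, r) == r


class TestSelectCandidates:
    def test_no_passing_reports_gives_empty_list(self):
        reports = [_report("A", {"t": (0.5, 0.3)})]
        assert select_candidates(reports, alpha=0.05) == []

    def test_rank_by_sum_of_neglog10(self):
        r1 = _report("A", {"t1": (1e-3, 3.0), "t2": (1e-3, 3.0)})
        r2 = _report("B", {"t1": (1e-2, 2.0), "t2": (1e-2, 2.0)})
        out = select_candidates([r2, r1], alpha=0.05)
        assert [r.candidate_id for r in out] == ["A", "B"]
        assert out[0].rank_score == pytest.approx(6.0)
        assert out[1].rank_score == pytest.approx(4.0)

    def test_order_invariant_to_input_order(self):
        rs = [_report(c, {"t": (10 ** -(i + 2), float(i + 2))})
              for i, c in enumerate("ABCD")]
        fwd = [r.candidate_id for r in select_candidates(rs)]
        rev = [r.candidate_id for r in select_candidates(rs[::-1])]
        assert fwd == rev == ["D", "C", "B", "A"]

    def test_min_rank_method(self):
        r1 = _report("A", {"t1": (1e-6, 6.0), "t2": (0.04, 1.4)})
        r2 = _report("B", {"t1": (1e-3, 3.0), "t2": (1e-3, 3.0)})
        out = select_candidates([r1, r2], rank_method="min")
        assert [r.candidate_id for r in out] == ["B", "A"]

    def test_unknown_rank_method_rejected(self):
        with pytest.raises(ValueError):
            select_candidates([], rank_method="median")


@pytest.fixture(scope="module")
def planted():
    params = SimParams(
        n_genes=600,
        module_specs=(ModuleSpec("m1", 60, 1.0, 0.1),),
        rng_seed=77,
    )
    comp, truth = simulate_compendium(params)
    truth = simulate_annotations(truth, 0.0, 0.0, [("T", 0.8, 0.02)], rng_seed=78)
    engine = CorrelationEngine(comp, min_shared_datasets=1)
    return comp, truth, engine


class TestGuiltByAssociation:
    def test_zero_term_overlap_scores_p_one_and_fails(self, planted):
        comp, truth, engine = planted
        candidate = next(
            g for g in sorted(truth.module_genes("m1"))
            if engine.correlate_list(g).eligible
        )
        report = guilt_by_association(
            candidate, engine, {"T": set()}, ["T"], len(comp.gene_universe)
        )
        assert report.term_scores["T"].ease_p == 1.0
        assert report.term_scores["T"].neglog10_p == 0.0
        assert not report.passes

    def test_planted_dense_term_passes(self, planted):
        comp, truth, engine = planted
        candidate = next(
            g for g in sorted(truth.module_genes("m1"))
            if engine.correlate_list(g).eligible
        )
        report = guilt_by_association(
            candidate, engine, truth.pathway_annotations, ["T"],
            len(comp.gene_universe), alpha=0.05,
        )
        assert report.passes
        assert report.term_scores["T"].ease_p < 0.05

    def test_emitted_ease_values_match_enumeration_oracle(self, planted):
        comp, truth, engine = planted
        genes = [g for g in sorted(truth.module_genes("m1"))[:5]
                 if engine.correlate_list(g).eligible]
        for candidate in genes:
            report = guilt_by_association(
                candidate, engine, truth.pathway_annotations, ["T"],
                len(comp.gene_universe),
            )
            s = report.term_scores["T"]
            if s.k == 0:
                assert s.ease_p == 1.0
                continue
            a, b = s.k - 1, s.n - s.k
            c, d = s.K - s.k + 1, s.M - s.n - s.K + s.k
            assert s.ease_p == pytest.approx(
                hypergeom_upper_tail(a, b, c, d), rel=1e-9
            )

    def test_ineligible_candidate_reports_reason(self, planted):
        comp, truth, engine = planted
        absent = [g for g in comp.gene_universe
                  if not engine.correlate_list(g).eligible]
        if not absent:
            pytest.skip("every gene eligible in this draw")
        report = guilt_by_association(
            absent[0], engine, truth.pathway_annotations, ["T"],
            len(comp.gene_universe),
        )
        assert not report.passes and report.reason == "ineligible_in_engine"

    def test_missing_required_term_rejected(self, planted):
        comp, truth, engine = planted
        with pytest.raises(KeyError):
            guilt_by_association("g0000", engine, {}, ["T"], 600)

    def test_rank_score_monotone_in_overlap(self):
        # increasing k (all else fixed) never decreases -log10 EASE p
        from coseed import ease_score

        prev = -1.0
        for k in range(0, 15):
            p = ease_score(k, 20, 30, 500).p_value
            score = -np.log10(p)
            assert score >= prev - 1e-12
            prev = score
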
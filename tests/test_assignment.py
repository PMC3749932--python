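"""Paralog assignment: anchoring, exact parsimony search, ambiguity."""

import pytest

from tandemsweep.assignment import (
    AssignmentProblem,
    InfeasibleError,
    anchor_from_reference,
    anchor_from_s8,
    problem_from_cleaning,
    shared_haplotype_report,
    solve_assignment,
)
from tandemsweep.segments import COPIES


class TestAnchors:
    def test_s8_overlap_match(self):
        haps = {"h01": "AAAATTTT", "h02": "AAAACCCC"}
        s8 = {"1.1": ["TTTTGGGG"]}  # 5' end == 3' overlap of h01
        anchors = anchor_from_s8(haps, s8, overlap=4)
        assert anchors == [("1.1", "h01", "HMA4-2")]

    def test_no_match_no_anchor(self):
        haps = {"h01": "AAAATTTT"}
        assert anchor_from_s8(haps, {"1.1": ["GGGGAAAA"]}, overlap=4) == []

    def test_both_s8_alleles_anchored(self):
        haps = {"h01": "AAAATTTT", "h02": "AAAACCCC"}
        s8 = {"1.1": ["TTTTGGGG", "CCCCGGGG"]}
        anchors = anchor_from_s8(haps, s8, overlap=4)
        assert {(a[1], a[2]) for a in anchors} == {("h01", "HMA4-2"), ("h02", "HMA4-2")}

    def test_carrier_restriction(self):
        haps = {"h01": "AAAATTTT"}
        s8 = {"1.1": ["TTTTGGGG"]}
        anchors = anchor_from_s8(haps, s8, overlap=4, carried_by={"1.1": []})
        assert anchors == []

    def test_reference_exact_match(self):
        haps = {"h01": "AAAA", "h02": "CCCC"}
        anchors = anchor_from_reference(haps, {"HMA4-1": "AAAA"})
        assert anchors == [(None, "h01", "HMA4-1")]

    def test_reference_near_match_unanchored(self):
        haps = {"h01": "AAAT"}
        assert anchor_from_reference(haps, {"HMA4-1": "AAAA", "HMA4-3": "AAAC"}) == []

    def test_ambiguous_reference_no_anchor(self):
        haps = {"h01": "AAAA"}
        anchors = anchor_from_reference(haps, {"HMA4-1": "AAAA", "HMA4-3": "AAAA"})
        assert anchors == []

    def test_empty_reference(self):
        assert anchor_from_reference({"h01": "AAAA"}, {}) == []


class TestSolver:
    def test_slot_bound_infeasible(self):
        prob = AssignmentProblem({"1.1": [f"h{i:02d}" for i in range(7)]})
        with pytest.raises(InfeasibleError, match="6 allele slots"):
            solve_assignment(prob)

    def test_six_haplotypes_two_anchored(self):
        # six distinct haplotypes: every slot filled once; anchors pin two
        # to copy 2, the rest split 2/2 over copies 1 and 3
        prob = AssignmentProblem(
            {"1.1": ["h01", "h02", "h03", "h04", "h05", "h06"]},
            anchors=[("1.1", "h03", "HMA4-2"), ("1.1", "h04", "HMA4-2")],
        )
        sol = solve_assignment(prob)
        assert sol.cost == 0
        for opt in sol.optima:
            placing = opt["1.1"]
            assert set(placing["HMA4-2"]) == {"h03", "h04"}
            assert len(set(placing["HMA4-1"])) == 2
        # without further carriers the 1-vs-3 split is symmetric: ambiguity
        assert sol.haplotypes["h01"].ambiguous
        assert sol.haplotypes["h03"].assigned_copies == {"HMA4-2"}
        assert not sol.haplotypes["h03"].ambiguous

    def test_three_haplotypes_homozygous_per_copy(self):
        prob = AssignmentProblem(
            {"1.1": ["h01", "h02", "h03"]},
            anchors=[
                ("1.1", "h01", "HMA4-1"),
                ("1.1", "h02", "HMA4-2"),
                ("1.1", "h03", "HMA4-3"),
            ],
        )
        sol = solve_assignment(prob)
        assert sol.n_optima == 1 and sol.cost == 0
        placing = sol.optima[0]["1.1"]
        assert placing["HMA4-1"] == ("h01", "h01")
        assert placing["HMA4-3"] == ("h03", "h03")

    def test_species_wide_propagation(self):
        # 1.1 resolves h01 (reference, copy 1) homozygous and h02 to copy 3;
        # 2.1 then inherits h02's copy-3 label through the shared objective
        prob = AssignmentProblem(
            {
                "1.1": ["h01", "h02", "h03", "h04"],
                "2.1": ["h02", "h08", "h09", "h10"],
            },
            anchors=[
                ("1.1", "h03", "HMA4-2"),
                ("1.1", "h04", "HMA4-2"),
                ("2.1", "h09", "HMA4-2"),
                ("2.1", "h10", "HMA4-2"),
                (None, "h01", "HMA4-1"),
            ],
        )
        sol = solve_assignment(prob)
        assert sol.cost == 0 and sol.n_optima == 1
        assert sol.haplotypes["h02"].assigned_copies == {"HMA4-3"}
        assert not sol.haplotypes["h02"].ambiguous
        # 2.1: h02 keeps its copy-3 label, so h08 resolves to copy 1
        assert sol.haplotypes["h08"].assigned_copies == {"HMA4-1"}
        assert not sol.haplotypes["h08"].ambiguous

    def test_forced_sharing_detected(self):
        # h01 sits at copy 1 by reference evidence, but individual 2.1's
        # downstream-overlap anchor proves it also present at copy 2 there:
        # a conversion haplotype shared across loci in every optimum
        prob = AssignmentProblem(
            {
                "1.1": ["h01", "h02", "h03", "h04", "h05", "h06"],
                "2.1": ["h01", "h07"],
            },
            anchors=[
                ("1.1", "h03", "HMA4-2"),
                ("1.1", "h04", "HMA4-2"),
                ("2.1", "h01", "HMA4-2"),
                (None, "h01", "HMA4-1"),
            ],
        )
        sol = solve_assignment(prob)
        rep = shared_haplotype_report(sol)
        h01 = rep[rep.h_id == "h01"].iloc[0]
        assert h01["shared"]
        assert {"HMA4-1", "HMA4-2"} <= set(h01["copies"].split(","))

    def test_anchor_conflict_infeasible(self):
        prob = AssignmentProblem(
            {"1.1": ["h01"]},
            anchors=[("1.1", "h01", "HMA4-1")],
        )
        # h01 must fill all six slots (sole allele) so anchors to 1 are fine;
        # but anchoring a hap absent from the individual is a hard error
        prob2 = AssignmentProblem(
            {"1.1": ["h01"]},
            anchors=[("1.1", "h99", "HMA4-2")],
        )
        solve_assignment(prob)
        with pytest.raises(InfeasibleError, match="h99"):
            solve_assignment(prob2)

    def test_single_haplotype_triple_homozygote(self):
        sol = solve_assignment(AssignmentProblem({"1.1": ["h01"]}))
        assert sol.n_optima == 1
        assert sol.haplotypes["h01"].assigned_copies == set(COPIES)
        assert sol.haplotypes["h01"].shared  # occupies all three loci

    def test_order_invariance(self):
        alleles = {
            "1.1": ["h01", "h02", "h03"],
            "2.1": ["h02", "h03", "h04"],
            "3.1": ["h01", "h04"],
        }
        anchors = [("1.1", "h02", "HMA4-2"), ("2.1", "h02", "HMA4-2")]
        sol1 = solve_assignment(AssignmentProblem(alleles, anchors))
        rev = {k: list(reversed(v)) for k, v in reversed(list(alleles.items()))}
        sol2 = solve_assignment(AssignmentProblem(rev, list(reversed(anchors))))
        rep1 = shared_haplotype_report(sol1)
        rep2 = shared_haplotype_report(sol2)
        assert rep1.equals(rep2)
        assert sol1.cost == sol2.cost and sol1.n_optima == sol2.n_optima


class TestSharedReport:
    def test_all_single_copy_zero_shared(self):
        prob = AssignmentProblem(
            {"1.1": ["h01", "h02", "h03"]},
            anchors=[
                ("1.1", "h01", "HMA4-1"),
                ("1.1", "h02", "HMA4-2"),
                ("1.1", "h03", "HMA4-3"),
            ],
        )
        rep = shared_haplotype_report(solve_assignment(prob))
        assert int(rep["shared"].sum()) == 0

    def test_ambiguous_not_shared(self):
        # symmetric 1-vs-3 alternatives: union spans several copies but no
        # optimum is multi-copy
        prob = AssignmentProblem(
            {"1.1": ["h01", "h02", "h03", "h04", "h05", "h06"]},
            anchors=[("1.1", "h03", "HMA4-2"), ("1.1", "h04", "HMA4-2")],
        )
        rep = shared_haplotype_report(solve_assignment(prob))
        h01 = rep[rep.h_id == "h01"].iloc[0]
        assert h01["ambiguous"] and not h01["shared"]


def test_problem_from_cleaning_ids_stable():
    problem, seqs = problem_from_cleaning(
        {"1.1": ["TTTT", "AAAA"], "2.1": ["AAAA", "CCCC"]}
    )
    assert problem.alleles_per_individual["1.1"] == sorted(
        [k for k, v in seqs.items() if v in ("AAAA", "TTTT")]
    )
    assert len(seqs) == 3 and set(seqs) == {"h01", "h02", "h03"}
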
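"""Column mapping, residue-rule classification and conservation consensus."""

import numpy as np
import pytest

from hgtscan import (
    Alignment, Call, build_column_map, classify_sequence,
    conservation_report, default_rules,
)
from hgtscan.synapomorphy import AlignmentRow, ResidueRule
from hgtscan.fixtures import REFERENCE_ID, synthetic_padi_alignment


@pytest.fixture(scope="module")
def fixture_alignment():
    return synthetic_padi_alignment()


@pytest.fixture(scope="module")
def fixture_map(fixture_alignment):
    return build_column_map(fixture_alignment, REFERENCE_ID)


class TestColumnMap:
    def test_simple_gapped_reference(self):
        aln = Alignment([AlignmentRow("r", "g", "A-CD"),
                         AlignmentRow("x", "g", "AACD")])
        cmap = build_column_map(aln, "r")
        assert cmap.mapping == {1: 0, 2: 2, 3: 3}

    def test_all_gap_column_absent_from_image(self):
        aln = Alignment([AlignmentRow("r", "g", "A-C"),
                         AlignmentRow("x", "g", "A-C")])
        cmap = build_column_map(aln, "r")
        assert 1 not in cmap.mapping.values()

    def test_roundtrip_recovers_ungapped_sequence(self):
        rng = np.random.default_rng(19)
        residues = rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=80)
        gapped = []
        for ch in residues:
            if rng.random() < 0.3:
                gapped.append("-")
            gapped.append(ch)
        row = "".join(gapped)
        aln = Alignment([AlignmentRow("r", "g", row),
                         AlignmentRow("x", "g", "A" * len(row))])
        cmap = build_column_map(aln, "r")
        recovered = "".join(row[cmap.mapping[p]] for p in sorted(cmap.mapping))
        assert recovered == "".join(residues)

    def test_mapping_strictly_increasing(self, fixture_map):
        cols = [fixture_map.mapping[p] for p in sorted(fixture_map.mapping)]
        assert all(a < b for a, b in zip(cols, cols[1:]))

    def test_missing_reference_rejected(self, fixture_alignment):
        with pytest.raises(KeyError):
            build_column_map(fixture_alignment, "nonexistent")


class TestClassification:
    def test_reference_is_ai_like_with_all_ai_rules_matched(
            self, fixture_alignment, fixture_map):
        call = classify_sequence(fixture_alignment, fixture_map,
                                 default_rules(), REFERENCE_ID)
        assert call.call is Call.Ai_like
        for obs in call.per_rule:
            if obs.matches_ai is not None and obs.severity == "critical":
                assert obs.matches_ai

    def test_calcium_switch_glycine_with_triple_his_is_bi_like(
            self, fixture_alignment, fixture_map):
        for rid in ("fungal_Bi_synthetic", "actino_Bi_synthetic"):
            call = classify_sequence(fixture_alignment, fixture_map,
                                     default_rules(), rid)
            assert call.call is Call.Bi_like
            by_name = {o.rule: o for o in call.per_rule}
            assert by_name["ca_switch_389"].observed == ("G",)
            assert by_name["triple_his_300_302"].observed == ("H", "H", "H")

    def test_gaps_at_rule_positions_give_ambiguous(
            self, fixture_alignment, fixture_map):
        call = classify_sequence(fixture_alignment, fixture_map,
                                 default_rules(), "fragment_synthetic")
        assert call.call is Call.ambiguous
        critical = [o for o in call.per_rule if o.severity == "critical"]
        assert all(not o.evaluable for o in critical)

    def test_never_both_types(self, fixture_alignment, fixture_map):
        # rule-level disjointness is enforced at construction
        with pytest.raises(ValueError):
            ResidueRule("bad", "diagnostic", "critical", (1,),
                        (frozenset("DG"),), (frozenset("G"),))
        for rid in fixture_alignment.ids():
            call = classify_sequence(fixture_alignment, fixture_map,
                                     default_rules(), rid)
            assert call.call in (Call.Ai_like, Call.Bi_like, Call.ambiguous)

    def test_invariant_to_row_order_and_non_rule_columns(self, fixture_alignment):
        rules = default_rules()
        cmap = build_column_map(fixture_alignment, REFERENCE_ID)
        calls = {rid: classify_sequence(fixture_alignment, cmap, rules, rid).call
                 for rid in fixture_alignment.ids()}

        reordered = Alignment(list(reversed(fixture_alignment.rows)))
        cmap2 = build_column_map(reordered, REFERENCE_ID)
        for rid in reordered.ids():
            assert classify_sequence(reordered, cmap2, rules, rid).call == calls[rid]

        # perturb a column far from every rule position (reference pos 500)
        col = cmap.mapping[500]
        mutated = Alignment([
            AlignmentRow(r.id, r.group,
                         r.seq[:col] + ("W" if r.id != REFERENCE_ID else
                                        r.seq[col]) + r.seq[col + 1:])
            for r in fixture_alignment.rows
        ])
        for rid in mutated.ids():
            assert classify_sequence(mutated, cmap, rules, rid).call == calls[rid]

    def test_fixture_reference_residues_at_named_sites(self, fixture_alignment,
                                                       fixture_map):
        ref = fixture_alignment.row(REFERENCE_ID).seq
        expected = {389: "D", 125: "D", 131: "E", 300: "T", 301: "V", 302: "S"}
        for pos, aa in expected.items():
            assert ref[fixture_map.mapping[pos]] == aa


class TestConservationReport:
    def test_identical_group_single_letter_consensus(self):
        aln = Alignment([AlignmentRow(f"s{i}", "grp", "ACDEF") for i in range(3)]
                        + [AlignmentRow("x", "other", "ACDEF")])
        cmap = build_column_map(aln, "s0")
        rep = conservation_report(aln, cmap, [1, 2, 3, 4, 5], ["grp"])
        assert [rep[p]["grp"] for p in (1, 2, 3, 4, 5)] == list("ACDEF")

    def test_two_state_and_nonconserved_positions(self):
        aln = Alignment([
            AlignmentRow("a", "grp", "DW"),
            AlignmentRow("b", "grp", "NY"),
            AlignmentRow("c", "grp", "DF"),
            AlignmentRow("r", "other", "DW"),
        ])
        cmap = build_column_map(aln, "r")
        rep = conservation_report(aln, cmap, [1, 2], ["grp"])
        assert rep[1]["grp"] == "D/N"
        assert rep[2]["grp"] == "nc"

    def test_gapped_member_excluded(self):
        aln = Alignment([
            AlignmentRow("a", "grp", "D"),
            AlignmentRow("b", "grp", "-"),
            AlignmentRow("r", "other", "D"),
        ])
        cmap = build_column_map(aln, "r")
        assert conservation_report(aln, cmap, [1], ["grp"])[1]["grp"] == "D"

    def test_empty_group_rejected(self, fixture_alignment, fixture_map):
        with pytest.raises(ValueError):
            conservation_report(fixture_alignment, fixture_map, [1], ["martian"])


def test_default_rules_content():
    rules = default_rules()
    names = {r.name for r in rules.rules}
    assert {"catalytic_site", "ca_switch_389", "triple_his_300_302",
            "ca_site6"} <= names
    switch = next(r for r in rules.rules if r.name == "ca_switch_389")
    assert switch.positions == (389,)
    assert switch.ai_states == (frozenset("D"),)
    assert switch.bi_states == (frozenset("G"),)
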
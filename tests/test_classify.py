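"""LINE-signature classification rules and the inverted-repeat detector."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import best_inverted_arms, sw_inverted_repeat_oracle
from potevo.classify import (
    GROUP_II_INTRON9_CLUSTER,
    GROUP_IV_INTRON9_CLUSTER,
    GeneModel,
    LineSignature,
    assign_group,
    build_feature_table,
    extract_line_signature,
    find_inverted_repeat,
    read_gene_models,
)
from potevo.datasets import pote_gene_table
from potevo.seqio import GenomicInterval, RepeatHit, RepeatTrack
from potevo.synthetic_data import template_gene_model

COMP = str.maketrans("ACGT", "TGCA")


def _hit(gene, start, end, name, rclass="LINE/L1"):
    return RepeatHit(
        query=gene,
        interval=GenomicInterval(chrom=gene, start=start, end=end),
        strand="+",
        repeat_name=name,
        repeat_class=rclass,
        score=500.0,
    )


@pytest.fixture
def model():
    return template_gene_model("g")


class TestExtractLineSignature:
    def test_l1m5_in_intron_one_detected(self, model):
        intron1 = model.intron(1)
        track = RepeatTrack(
            gene_id="g", hits=[_hit("g", intron1.start + 10, intron1.start + 400, "L1M5")]
        )
        sig = extract_line_signature(track, model)
        assert sig.l1m5_intron1 is True
        assert sig.l1pa_invasion is False

    def test_intron9_cluster_order_preserved_and_non_lines_ignored(self, model):
        intron9 = model.intron(9)
        s = intron9.start
        track = RepeatTrack(
            gene_id="g",
            hits=[
                _hit("g", s, s + 300, "L1M5"),
                _hit("g", s + 400, s + 500, "AluY", rclass="SINE/Alu"),
                _hit("g", s + 600, s + 900, "L1PA15"),
                _hit("g", s + 1000, s + 1300, "L1M5"),
            ],
        )
        sig = extract_line_signature(track, model)
        assert sig.intron9_cluster == ("L1M5", "L1PA15", "L1M5")

    def test_fragmented_element_collapses_to_one_cluster_member(self, model):
        intron9 = model.intron(9)
        s = intron9.start
        track = RepeatTrack(
            gene_id="g",
            hits=[
                _hit("g", s, s + 100, "L1M5"),
                _hit("g", s + 120, s + 200, "L1M5"),  # same element, fragmented
                _hit("g", s + 300, s + 600, "L1PA15"),
                _hit("g", s + 700, s + 900, "L1M5"),
            ],
        )
        sig = extract_line_signature(track, model)
        assert sig.intron9_cluster == ("L1M5", "L1PA15", "L1M5")

    def test_empty_track_gives_null_signature(self, model):
        sig = extract_line_signature(RepeatTrack(gene_id="g"), model)
        assert sig == LineSignature(False, False, (), False)

    def test_invasion_threshold_on_locus_fraction(self, model):
        # one 400 bp L1PA hit is far below 20% of a ~25 kb locus
        intron1 = model.intron(1)
        small = RepeatTrack(
            gene_id="g", hits=[_hit("g", intron1.start, intron1.start + 399, "L1PA2")]
        )
        assert extract_line_signature(small, model).l1pa_invasion is False
        # hits covering most introns clear it
        big_hits = [
            _hit("g", model.intron(k).start, model.intron(k).start + 3000, "L1PA3")
            for k in (1, 2, 9)
        ]
        big_hits[1] = _hit("g", model.intron(2).start, model.intron(2).start + 900, "L1PA3")
        big = RepeatTrack(gene_id="g", hits=big_hits)
        assert extract_line_signature(big, model).l1pa_invasion is True

    def test_coordinate_frame_mismatch_rejected(self, model):
        beyond = model.locus_length + 1000
        track = RepeatTrack(gene_id="g", hits=[_hit("g", beyond, beyond + 100, "L1M5")])
        with pytest.raises(ValueError, match="coordinate frame"):
            extract_line_signature(track, model)

    def test_gene_id_mismatch_rejected(self, model):
        with pytest.raises(ValueError, match="!= model gene"):
            extract_line_signature(RepeatTrack(gene_id="other"), model)


class TestAssignGroup:
    def test_group_two_signature(self):
        sig = LineSignature(
            l1pa_invasion=False,
            l1m5_intron1=True,
            intron9_cluster=GROUP_II_INTRON9_CLUSTER,
            exon6_9_dup_content=False,
        )
        a = assign_group(sig)
        assert a.group == "II" and a.fired_rules == ("R2",)

    def test_conflicting_rules_yield_ambiguous(self):
        sig = LineSignature(
            l1pa_invasion=True,
            l1m5_intron1=True,
            intron9_cluster=GROUP_II_INTRON9_CLUSTER,
            exon6_9_dup_content=False,
        )
        a = assign_group(sig)
        assert a.group == "ambiguous"
        assert set(a.conflicts) == {"R1", "R2"}

    def test_group_three_requires_duplication_without_intron1_l1m5(self):
        sig = LineSignature(
            l1pa_invasion=False,
            l1m5_intron1=False,
            intron9_cluster=GROUP_IV_INTRON9_CLUSTER,
            exon6_9_dup_content=True,
        )
        assert assign_group(sig).group == "III"

    def test_group_four(self):
        sig = LineSignature(False, False, GROUP_IV_INTRON9_CLUSTER, False)
        assert assign_group(sig).group == "IV"

    def test_group_one(self):
        sig = LineSignature(True, True, GROUP_IV_INTRON9_CLUSTER, False)
        a = assign_group(sig)
        assert a.group == "I" and a.fired_rules == ("R1",)

    def test_no_rule_fires_gives_ambiguous_without_conflicts(self):
        sig = LineSignature(False, True, (), False)
        a = assign_group(sig)
        assert a.group == "ambiguous" and a.conflicts == ()

    @given(
        invasion=st.booleans(),
        l1m5=st.booleans(),
        cluster=st.sampled_from(
            [(), GROUP_II_INTRON9_CLUSTER, GROUP_IV_INTRON9_CLUSTER]
        ),
        dup=st.booleans(),
    )
    @settings(max_examples=48, deadline=None)
    def test_pure_function_and_ambiguity_contract(self, invasion, l1m5, cluster, dup):
        sig = LineSignature(invasion, l1m5, cluster, dup)
        a1, a2 = assign_group(sig), assign_group(sig)
        assert a1 == a2
        groups = {
            {"R1": "I", "R2": "II", "R3": "III", "R4": "IV"}[r]
            for r in a1.fired_rules
        }
        assert (a1.group == "ambiguous") == (len(groups) != 1)


class TestFindInvertedRepeat:
    def _palindrome(self, rng, arm_len=300, loop_len=400):
        arm = "".join(rng.choice(list("ACGT"), arm_len))
        loop = "".join(rng.choice(list("ACGT"), loop_len))
        return arm + loop + arm.translate(COMP)[::-1]

    def test_perfect_palindrome_matches_quadratic_sw_oracle(self, rng):
        seq = self._palindrome(rng)
        call = find_inverted_repeat(seq, min_arm=200, full_arm=250)
        _, arm1, arm2 = sw_inverted_repeat_oracle(seq)
        assert call.status == "full"
        assert (call.arm1, call.arm2) == (arm1, arm2)
        # the planted 300 bp stem is contained in the detected arms
        assert call.arm1[0] == 0 and call.arm1[1] >= 300
        assert call.arm2[0] <= 700 and call.arm2[1] == 1000

    def test_noisy_palindrome_still_matches_sw_oracle(self, rng):
        seq = list(self._palindrome(rng))
        for k in range(5, 300, 40):  # scatter mismatches into arm 1
            seq[k] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[k]]
        seq = "".join(seq)
        call = find_inverted_repeat(seq, min_arm=200, full_arm=250)
        score, arm1, arm2 = sw_inverted_repeat_oracle(seq)
        assert (call.arm1, call.arm2) == (arm1, arm2)
        assert 0.9 < call.arm_identity < 1.0

    def test_poly_a_loop_palindrome_matches_ungapped_scan(self, rng):
        # a poly-A loop cannot pair with itself, so gapped and ungapped
        # optima coincide and the planted arm is recovered exactly
        arm = "".join(rng.choice(list("ACGT"), 300))
        seq = arm + "A" * 400 + arm.translate(COMP)[::-1]
        call = find_inverted_repeat(seq, min_arm=200, full_arm=250)
        score, coords = best_inverted_arms(seq)
        assert (call.arm1, call.arm2) in coords
        assert call.arm_identity == 1.0 and call.arm_length >= 300

    def test_random_sequence_has_no_long_arm(self, rng):
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), 2000))
            call = find_inverted_repeat(seq, min_arm=200, min_identity=0.8)
            assert call.status == "none"

    def test_half_versus_full_thresholds(self, rng):
        seq = self._palindrome(rng, arm_len=300)
        assert find_inverted_repeat(seq, min_arm=200, full_arm=250).status == "full"
        assert find_inverted_repeat(seq, min_arm=200, full_arm=500).status == "half"
        assert find_inverted_repeat(seq, min_arm=350, full_arm=500).status == "none"

    def test_short_sequence_returns_none(self):
        assert find_inverted_repeat("ACGT" * 10, min_arm=100).status == "none"

    def test_windowed_long_input_agrees_with_direct_call(self, rng):
        # embed the palindrome in a sequence long enough to trigger the
        # score-only + windowed-traceback path
        pal = self._palindrome(rng)
        flank1 = "".join(rng.choice(list("ACGT"), 3500))
        flank2 = "".join(rng.choice(list("ACGT"), 3500))
        call = find_inverted_repeat(flank1 + pal + flank2, min_arm=200, full_arm=250)
        assert call.status == "full"
        assert call.arm1[0] >= 3500 and call.arm2[1] <= 3500 + len(pal)


class TestFeatureTable:
    def test_fourteen_gene_fixture_counts(self):
        # the bundled 14-gene feature fixture: 8 full- and 6 half-sized
        # inverted repeats across the family
        table = pote_gene_table()
        assert (table["lir"] == "full").sum() == 8
        assert (table["lir"] == "half").sum() == 6

    def test_join_of_computed_and_external_columns(self):
        from potevo.classify import GroupAssignment, LirCall

        assignments = [
            GroupAssignment("g1", "II", ("R2",)),
            GroupAssignment("g2", "IV", ("R4",)),
        ]
        lir = {
            "g1": LirCall("half", 220, 0.9, 100, (0, 220), (320, 540)),
            "g2": LirCall("full", 600, 0.95, 50, (0, 600), (650, 1250)),
        }
        import pandas as pd

        ext = pd.DataFrame(
            {"gene_id": ["g1", "g2"], "ankyrin_repeats": [7, 7]}
        )
        table = build_feature_table(assignments, lir, ext)
        assert list(table["gene_id"]) == ["g1", "g2"]
        assert list(table["lir"]) == ["half", "full"]
        assert list(table["ankyrin_repeats"]) == [7, 7]

    def test_empty_external_table_gives_computed_columns_only(self):
        from potevo.classify import GroupAssignment, LirCall

        table = build_feature_table(
            [GroupAssignment("g1", "I", ("R1",))],
            {"g1": LirCall("none", 0, 0.0, 0, None, None)},
            None,
        )
        assert set(table.columns) == {
            "gene_id", "group", "fired_rules", "lir", "lir_arm_bp",
            "lir_arm_identity",
        }

    def test_duplicate_external_gene_rejected(self):
        from potevo.classify import GroupAssignment, LirCall
        import pandas as pd

        with pytest.raises(ValueError, match="duplicate"):
            build_feature_table(
                [GroupAssignment("g1", "I", ("R1",))],
                {"g1": LirCall("none", 0, 0.0, 0, None, None)},
                pd.DataFrame({"gene_id": ["g1", "g1"], "x": [1, 2]}),
            )

    def test_one_source_gene_warns_and_keeps_row(self):
        from potevo.classify import GroupAssignment, LirCall
        import pandas as pd

        with pytest.warns(UserWarning, match="only one feature source"):
            table = build_feature_table(
                [GroupAssignment("g1", "I", ("R1",))],
                {"g1": LirCall("none", 0, 0.0, 0, None, None)},
                pd.DataFrame({"gene_id": ["g2"], "x": [1]}),
            )
        assert set(table["gene_id"]) == {"g1", "g2"}


def test_read_gene_models_splits_canonical_and_extra(tmp_path):
    path = tmp_path / "models.tsv"
    rows = ["gene_id\texon_label\tstart\tend"]
    pos = 1
    for k in range(1, 12):
        rows.append(f"gX\t{k}\t{pos}\t{pos + 149}")
        pos += 1150
    rows.append(f"gX\t6'\t{pos}\t{pos + 149}")
    path.write_text("\n".join(rows) + "\n")
    models = read_gene_models(path)
    assert len(models["gX"].exons) == 11
    assert models["gX"].extra_exons[0][0] == "6'"
    assert models["gX"].total_exon_count == 12
    # a primed extra exon on top of the 11 canonical ones marks the gene
    # as carrying exon 6-9 duplication content
    assert models["gX"].has_exon6_9_duplication is True
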
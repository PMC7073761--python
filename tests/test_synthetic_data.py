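"""Ground-truth generator: event trees, K2P evolution, repeat histories."""

import math

import numpy as np
import pytest

from potevo.classify import assign_group, extract_line_signature
from potevo.distances import (
    SitePatternCounts,
    complete_deletion,
    count_patterns,
    k2p_distance,
)
from potevo.synthetic_data import (
    DuplicationEvent,
    DuplicationScenario,
    RepeatInsertion,
    build_event_tree,
    duplication_scenario_presets,
    evolve_sequences,
    group_insertion_plan,
    inject_gaps,
    insert_repeats,
    simulate_family,
    template_gene_model,
)


def _leaf_depths(tree):
    out = {}
    for leaf in tree.leaf_node_iter():
        depth, node = 0.0, leaf
        while node.parent_node is not None:
            depth += node.edge.length or 0.0
            node = node.parent_node
        out[leaf.taxon.label] = depth
    return out


class TestBuildEventTree:
    def test_single_split_at_six_myr(self):
        sc = DuplicationScenario(
            name="s", root_label="A",
            species_splits=[("A", "B", 6.0)], events=[],
        )
        tree = build_event_tree(sc)
        assert _leaf_depths(tree) == {"A": 6.0, "B": 6.0}

    def test_nested_duplications_have_correct_node_depths(self):
        sc = DuplicationScenario(
            name="s", root_label="A",
            species_splits=[("A", "O", 16.0)],
            events=[
                DuplicationEvent("e1", 1.9, "A", "B"),
                DuplicationEvent("e2", 0.55, "A", "C"),
            ],
        )
        tree = build_event_tree(sc)
        depths = _leaf_depths(tree)
        assert set(depths) == {"A", "B", "C", "O"}
        assert all(d == pytest.approx(16.0) for d in depths.values())
        # the A-C split must be the 0.55 node: path A->C = 2 * 0.55
        mrca = tree.mrca(taxon_labels=["A", "C"])
        assert sum(
            e.length for e in _path_edges(tree, "A", mrca)
        ) == pytest.approx(0.55)

    def test_child_older_than_parent_rejected(self):
        sc = DuplicationScenario(
            name="s", root_label="A",
            species_splits=[("A", "B", 6.0)],
            events=[DuplicationEvent("e", 7.0, "A", "C")],
        )
        with pytest.raises(ValueError, match="older than its parent"):
            build_event_tree(sc)

    def test_presets_are_ultrametric(self):
        for sc in duplication_scenario_presets():
            depths = _leaf_depths(build_event_tree(sc))
            assert max(depths.values()) - min(depths.values()) < 1e-9


def _path_edges(tree, leaf_label, ancestor):
    node = [l for l in tree.leaf_node_iter() if l.taxon.label == leaf_label][0]
    edges = []
    while node is not ancestor:
        edges.append(node.edge)
        node = node.parent_node
    return edges


class TestEvolveSequences:
    def test_zero_rate_gives_identical_sequences(self):
        sc = duplication_scenario_presets()[0]
        tree = build_event_tree(sc)
        fam = evolve_sequences(tree, rate=0.0, seq_length=500, seed=1)
        seqs = {r.seq for r in fam.alignment.records}
        assert len(seqs) == 1

    def test_same_seed_reproduces_alignment(self):
        sc = duplication_scenario_presets()[1]
        tree = build_event_tree(sc)
        a = evolve_sequences(tree, seq_length=1000, seed=42).alignment
        b = evolve_sequences(tree, seq_length=1000, seed=42).alignment
        assert a == b

    def test_pair_distance_matches_2rt_expectation(self):
        # two lineages split 6 Myr at R = 1e-3: expected K2P distance
        # 2 * R * T = 0.012, checked within 3 analytic SEs at 100 kb
        sc = DuplicationScenario(
            name="pair", root_label="A",
            species_splits=[("A", "B", 6.0)], events=[],
            seq_length=100_000,
        )
        fam = simulate_family(sc, seed=7)
        c = count_patterns(fam.alignment["A"], fam.alignment["B"])
        est = k2p_distance(c)
        assert abs(est.d - 0.012) < 3 * est.se

    def test_ts_tv_ratio_converges_to_kappa_expectation(self):
        # on a short branch the instantaneous ts:tv rate ratio kappa/2
        # per transversion class means ts/tv counts -> kappa / 2 * 2/2:
        # with kappa=2 and two tv classes, expect ts:tv = 1:1 at d->0
        sc = DuplicationScenario(
            name="pair", root_label="A",
            species_splits=[("A", "B", 0.5)], events=[],
            seq_length=200_000, kappa=2.0,
        )
        fam = simulate_family(sc, seed=3)
        c = count_patterns(fam.alignment["A"], fam.alignment["B"])
        ratio = c.ts / c.tv
        se = ratio * math.sqrt(1 / c.ts + 1 / c.tv)
        assert abs(ratio - 1.0) < 3 * se

    def test_zero_length_rejected(self):
        sc = duplication_scenario_presets()[0]
        tree = build_event_tree(sc)
        with pytest.raises(ValueError, match="seq_length"):
            evolve_sequences(tree, seq_length=0)


class TestInsertRepeats:
    def test_root_insertion_present_in_every_track(self):
        fam = simulate_family(duplication_scenario_presets()[0], seed=0)
        insert_repeats(
            fam, [RepeatInsertion(lineage="root", repeat_name="L1M5", intron=1)]
        )
        assert all(
            any(h.repeat_name == "L1M5" for h in t.hits)
            for t in fam.tracks.values()
        )

    def test_leaf_insertion_present_only_there(self):
        fam = simulate_family(duplication_scenario_presets()[0], seed=0)
        insert_repeats(
            fam,
            [RepeatInsertion(lineage="POTEB", repeat_name="L1PA2", intron=4)],
        )
        for gene, track in fam.tracks.items():
            present = any(h.repeat_name == "L1PA2" for h in track.hits)
            assert present == (gene == "POTEB")

    def test_unknown_lineage_rejected(self):
        fam = simulate_family(duplication_scenario_presets()[0], seed=0)
        with pytest.raises(ValueError, match="unknown lineage"):
            insert_repeats(
                fam, [RepeatInsertion(lineage="nope", repeat_name="X", intron=1)]
            )

    @pytest.mark.parametrize("group", ["I", "II", "III", "IV"])
    def test_group_presets_classify_back_to_their_group(self, group):
        fam = simulate_family(duplication_scenario_presets()[0], seed=0)
        dup = group == "III"
        for leaf in fam.tree.leaf_node_iter():
            fam.gene_models[leaf.taxon.label] = template_gene_model(
                leaf.taxon.label, with_exon6_9_duplication=dup
            )
        insert_repeats(fam, group_insertion_plan(group))
        for gene, track in fam.tracks.items():
            sig = extract_line_signature(track, fam.gene_models[gene])
            assert assign_group(sig, gene_id=gene).group == group


class TestPresets:
    def test_six_presets_with_documented_truth_times(self):
        presets = {sc.name: sc for sc in duplication_scenario_presets()}
        assert len(presets) == 6
        expected = {
            "groupII_first": 1.07,
            "groupII_second": 0.55,
            "groupIII_EF": 1.90,
            "groupIII_IJ": 1.57,
            "groupIV_first": 1.06,
            "groupIV_second": 0.44,
        }
        for name, t in expected.items():
            assert presets[name].events[0].time_myr == pytest.approx(t)

    def test_presets_carry_both_calibrations(self):
        for sc in duplication_scenario_presets():
            times = sorted(c.split_time for c in sc.calibrations)
            assert times == [6.0, 16.0]


class TestGapInjection:
    def test_injected_gaps_are_removed_by_complete_deletion(self):
        fam = simulate_family(duplication_scenario_presets()[0], seed=5)
        gapped = inject_gaps(fam.alignment, n_columns=37, seed=2)
        assert sum("-" in r.seq for r in gapped.records) > 0
        cleaned = complete_deletion(gapped)
        assert cleaned.length == fam.alignment.length - 37
        assert all("-" not in r.seq for r in cleaned.records)


def test_written_family_round_trips_through_pipeline_readers(tmp_path):
    from potevo.classify import read_gene_models
    from potevo.clock import read_calibrations
    from potevo.seqio import parse_fasta_alignment, parse_repeatmasker_out

    sc = duplication_scenario_presets()[2]
    sc.seq_length = 1_000
    fam = simulate_family(sc, seed=9)
    for leaf in fam.tree.leaf_node_iter():
        fam.gene_models[leaf.taxon.label] = template_gene_model(
            leaf.taxon.label, with_exon6_9_duplication=True
        )
    insert_repeats(fam, group_insertion_plan("III"))
    fam.write(tmp_path)
    aln = parse_fasta_alignment(tmp_path / "alignment.fasta")
    assert aln.ids == fam.alignment.ids
    cals = read_calibrations(tmp_path / "calibrations.tsv")
    assert len(cals) == 2
    tracks = parse_repeatmasker_out(tmp_path / "repeats.out")
    assert {t.gene_id for t in tracks} == set(aln.ids)
    models = read_gene_models(tmp_path / "gene_models.tsv")
    assert models[aln.ids[0]].has_exon6_9_duplication
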
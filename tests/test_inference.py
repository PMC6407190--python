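"""Parsing chromosome paints back into fusion-event trajectories."""

import pytest
from hypothesis import given, settings, strategies as st

from karyoevo.inference import (
    AmbiguousPaintError,
    NoCallError,
    assemble_trajectory,
    compare_trajectories,
    infer_chromosome_events,
    infer_translocations,
    parse_units,
)
from karyoevo.model import EventType
from karyoevo.painting import Karyogram, PaintSegment, truth_karyogram
from karyoevo.simulate import SimulationConfig, make_proto_genome, random_trajectory


def paint_of(labels, chrom="c"):
    return [
        PaintSegment(chrom_id=chrom, start_bp=1 + i * 1000, end_bp=(i + 1) * 1000,
                     ref_label=lab, n_anchors=10)
        for i, lab in enumerate(labels)
    ]


def karyo_of(chrom_labels: dict) -> Karyogram:
    k = Karyogram(genome_id="g")
    for chrom, labels in chrom_labels.items():
        k.paints[chrom] = paint_of(labels, chrom)
    return k


def event_keys(events):
    return sorted(e.key() for e in events
                  if e.event_type not in ("NONE", "AMBIGUOUS"))


class TestChromosomeEventParsing:
    def test_simple_nest(self):
        events = infer_chromosome_events(paint_of(["Os5", "Os10", "Os5"]))
        assert event_keys(events) == [("NCF", "Os10", "Os5")]

    def test_single_origin_is_none(self):
        events = infer_chromosome_events(paint_of(["Os4"]))
        assert [e.event_type for e in events] == ["NONE"]

    def test_sequential_double_nest(self):
        events = infer_chromosome_events(paint_of(["Os2", "Os8", "Os2", "Os10", "Os2"]))
        assert event_keys(events) == [("NCF", "Os10", "Os2"), ("NCF", "Os8", "Os2")]

    def test_adjacent_double_nest_two_ncfs(self):
        # X,Y,Z,X parses as the unique two-NCF history (both nested into the
        # host X; the insertion order is not recoverable and not asserted)
        events = infer_chromosome_events(paint_of(["Os3", "Os7", "Os6", "Os3"]))
        assert event_keys(events) == [("NCF", "Os6", "Os3"), ("NCF", "Os7", "Os3")]

    def test_plain_concatenation_is_eej(self):
        events = infer_chromosome_events(paint_of(["Os12", "Os9"]))
        assert event_keys(events) == [("EEJ", "Os12", "Os9")]

    def test_alternating_labels_ambiguous(self):
        events = infer_chromosome_events(paint_of(["A", "B", "A", "B"]))
        assert [e.event_type for e in events] == ["AMBIGUOUS"]
        with pytest.raises(AmbiguousPaintError):
            parse_units(["A", "B", "A", "B"])

    def test_empty_paint_no_call(self):
        with pytest.raises(NoCallError):
            infer_chromosome_events([])

    def test_homoeology_flag_from_pair_map(self):
        pair_map = {frozenset(("Os1", "Os5"))}
        events = infer_chromosome_events(paint_of(["Os1", "Os5", "Os1"]), pair_map)
        assert events[0].is_homoeologous

    def test_nest_inside_nest(self):
        events = infer_chromosome_events(paint_of(["X", "Y", "Z", "Y", "X"]))
        assert event_keys(events) == [("NCF", "Y", "X"), ("NCF", "Z", "Y")]


label_seqs = st.lists(
    st.sampled_from(["A", "B", "C", "D", "E"]), min_size=1, max_size=7)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(label_seqs)
def test_parsing_is_orientation_agnostic(labels):
    """Reversing a chromosome's paint yields the same event multiset."""
    fwd = paint_of(labels)
    rev = paint_of(list(reversed(labels)))
    try:
        e_fwd = event_keys(infer_chromosome_events(fwd))
    except NoCallError:
        return
    e_rev = event_keys(infer_chromosome_events(rev))
    assert e_fwd == e_rev


class TestTranslocations:
    def test_replayed_arm_exchange_detected(self, triticeae_analysis):
        events = infer_translocations(triticeae_analysis.karyogram)
        assert len(events) == 1
        ev = events[0]
        assert {ev.carrier, ev.partner} == {"T4", "T5"}
        assert {ev.left_label, ev.right_label} == {"Os3", "Os9"}

    def test_single_origin_karyogram_empty(self):
        karyo = karyo_of({"c1": ["Os1"], "c2": ["Os2"]})
        assert infer_translocations(karyo) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_single_scripted_translocation_recovered(self, seed):
        # a random NCF background plus one scripted arm exchange: exactly
        # that chromosome pair is reported, with the exchanged labels
        from karyoevo.model import apply_reciprocal_translocation

        cfg = SimulationConfig(
            n_proto=8, genes_per_chrom=60, n_events=2,
            event_mix={EventType.NCF: 1.0},
        )
        g = make_proto_genome(cfg, prefix="C")
        out = random_trajectory(g, cfg, seed=seed)
        untouched = [c for c in out.chromosomes
                     if len(c.origin_runs()) == 1][:2]
        assert len(untouched) == 2
        a, b = untouched
        out = apply_reciprocal_translocation(
            out, a.chrom_id, b.chrom_id,
            int(0.75 * len(a)), int(0.75 * len(b)))
        events = infer_translocations(truth_karyogram(out))
        assert len(events) == 1
        ev = events[0]
        assert {ev.carrier, ev.partner} == {a.chrom_id, b.chrom_id}
        assert {ev.left_label, ev.right_label} == {a.loci[0].origin_label,
                                                   b.loci[0].origin_label}


class TestTrajectoryAssembly:
    def test_triticeae_counts(self, triticeae_analysis):
        t = triticeae_analysis.trajectory
        assert t.count("NCF") == 4
        assert t.count("EEJ") == 1
        assert t.count("RECIPROCAL_TRANSLOCATION") == 1
        assert t.n_satellites_implied == 5
        assert (t.chrom_count_initial, t.chrom_count_final) == (12, 7)
        assert not any(e.is_homoeologous for e in t.events)

    def test_brachypodium_counts(self, brachypodium_analysis):
        t = brachypodium_analysis.trajectory
        assert t.count("NCF") == 7
        assert t.n_satellites_implied == 7
        assert (t.chrom_count_initial, t.chrom_count_final) == (12, 5)
        assert sum(1 for e in t.events
                   if e.event_type == "NCF" and e.is_homoeologous) == 3

    def test_unrearranged_genome_zero_events(self):
        karyo = karyo_of({f"c{i}": [f"Os{i}"] for i in range(1, 6)})
        t = assemble_trajectory(karyo)
        assert t.n_satellites_implied == 0
        assert t.chrom_count_initial == t.chrom_count_final == 5
        assert all(e.event_type == "NONE" for e in t.events)

    def test_satellite_arithmetic_invariant(self, brachypodium_analysis):
        t = brachypodium_analysis.trajectory
        assert not t.ambiguous_chroms
        assert t.chrom_count_final == t.chrom_count_initial - t.n_satellites_implied

    def test_ambiguous_chromosome_excluded_with_warning(self):
        karyo = karyo_of({"bad": ["A", "B", "A", "B"], "ok": ["C", "D", "C"]})
        t = assemble_trajectory(karyo)
        assert t.ambiguous_chroms == ["bad"]
        assert event_keys(t.events) == [("NCF", "D", "C")]


class TestCompareTrajectories:
    def test_fixture_lineages_share_nothing(self, triticeae_analysis,
                                            brachypodium_analysis):
        shared = compare_trajectories(triticeae_analysis.trajectory,
                                      brachypodium_analysis.trajectory)
        assert shared == []

    def test_self_comparison_shares_everything(self, brachypodium_analysis):
        t = brachypodium_analysis.trajectory
        assert len(compare_trajectories(t, t)) == 7

    def test_ncf_direction_matters(self):
        t1 = assemble_trajectory(karyo_of({"c": ["Os1", "Os5", "Os1"]}))
        t2 = assemble_trajectory(karyo_of({"c": ["Os5", "Os1", "Os5"]}))
        assert compare_trajectories(t1, t2) == []

    def test_disjoint_alphabets_rejected(self):
        t1 = assemble_trajectory(karyo_of({"c": ["Os1", "Os5", "Os1"]}))
        t2 = assemble_trajectory(karyo_of({"c": ["Bx", "By", "Bx"]}))
        with pytest.raises(ValueError):
            compare_trajectories(t1, t2)
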
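"""The rearrangement algebra: fusions, translocations, inversions, replay."""

import pytest

from karyoevo.model import (
    BreakpointError,
    EventType,
    InvalidParticipantError,
    ScriptError,
    apply_eej,
    apply_inversion,
    apply_ncf,
    apply_reciprocal_translocation,
    drop_satellites,
    replay_script,
)
from karyoevo import io as kio
from karyoevo.pipeline import make_reference_genome

from conftest import make_genome


def origin_runs(genome, chrom_id):
    return [lab for lab, _, _ in genome.get(chrom_id).origin_runs()]


class TestNCF:
    def test_gene_counts_of_fused_and_satellite(self):
        # donor of 10 genes with cuts (2, 8): interior 6 genes join the
        # 10-gene recipient (16 total); the two distal fragments (2 + 2)
        # form the satellite
        g = make_genome({"D": 10, "R": 10})
        out = apply_ncf(g, "D", "R", 2, 8, 5)
        fused = out.get("D/R")
        sat = next(c for c in out.chromosomes if c.is_satellite)
        assert len(fused) == 16
        assert len(sat) == 4
        assert out.n_genes == g.n_genes
        assert out.n_chromosomes == g.n_chromosomes  # one lost, one satellite

    def test_nested_origin_pattern(self):
        ref = make_reference_genome(genes_per_chrom=40)
        out = apply_ncf(ref, "Os10", "Os5", 4, 36, 20)
        assert origin_runs(out, "Os10/Os5") == ["Os5", "Os10", "Os5"]

    def test_gene_conservation(self):
        g = make_genome({"D": 20, "R": 30})
        out = apply_ncf(g, "D", "R", 2, 18, 15)
        assert sorted(out.gene_ids()) == sorted(g.gene_ids())

    def test_donor_centromere_inactivated_recipient_active(self):
        g = make_genome({"D": 10, "R": 10})
        out = apply_ncf(g, "D", "R", 2, 8, 5)
        fused = out.get("D/R")
        assert fused.active_centromere
        assert fused.centromere_index == 5 + 0  # recipient's, insertion at it
        assert fused.inactive_centromeres  # donor centromere retained, inactive

    @pytest.mark.parametrize("cuts", [(0, 8), (2, 10), (8, 2), (5, 5)])
    def test_bad_cuts_raise(self, cuts):
        g = make_genome({"D": 10, "R": 10})
        with pytest.raises(BreakpointError):
            apply_ncf(g, "D", "R", cuts[0], cuts[1], 5)

    def test_satellite_donor_rejected(self):
        g = make_genome({"D": 10, "R": 10, "X": 10})
        out = apply_ncf(g, "D", "R", 2, 8, 5)
        sat = next(c for c in out.chromosomes if c.is_satellite)
        with pytest.raises(InvalidParticipantError):
            apply_ncf(out, sat.chrom_id, "X", 1, 3, 5)

    def test_insertion_outside_pericentromeric_window_rejected(self):
        g = make_genome({"D": 40, "R": 40})
        with pytest.raises(BreakpointError):
            apply_ncf(g, "D", "R", 4, 36, 2)  # far from centromere (20)
        # same point allowed when window enforcement is off
        out = apply_ncf(g, "D", "R", 4, 36, 2, enforce_windows=False)
        assert out.get("D/R")

    def test_event_logged_with_homoeology(self):
        g = make_genome({"D": 10, "R": 10}, homoeolog_pairs=[("D", "R")])
        out = apply_ncf(g, "D", "R", 2, 8, 5)
        ev = out.event_log[-1]
        assert ev.event_type == EventType.NCF
        assert ev.is_homoeologous
        assert ev.donor_origin == "D" and ev.recipient_origin == "R"


class TestEEJ:
    def test_gene_counts(self):
        # a of 8 genes cut at 7, b of 8 genes cut at 1: merged 7+7, satellite 2
        g = make_genome({"A": 8, "B": 8})
        out = apply_eej(g, "A", "B", 7, 1)
        assert len(out.get("A/B")) == 14
        sat = next(c for c in out.chromosomes if c.is_satellite)
        assert len(sat) == 2
        assert out.n_genes == g.n_genes

    def test_concatenation_origin_order(self):
        ref = make_reference_genome(genes_per_chrom=40)
        out = apply_eej(ref, "Os12", "Os9", 36, 4)
        assert origin_runs(out, "Os12/Os9") == ["Os12", "Os9"]

    def test_empty_satellite_still_recorded(self):
        g = make_genome({"A": 8, "B": 8})
        out = apply_eej(g, "A", "B", 8, 0)
        sat = next(c for c in out.chromosomes if c.is_satellite)
        assert len(sat) == 0
        assert out.event_log[-1].products[-1] == sat.chrom_id

    def test_telomere_window_enforced(self):
        g = make_genome({"A": 40, "B": 40})
        with pytest.raises(BreakpointError):
            apply_eej(g, "A", "B", 20, 2)  # cut_a not telomere-proximal


class TestReciprocalTranslocation:
    def test_arm_exchange(self):
        g = make_genome({"A": (["A"] * 4, 2), "B": (["B"] * 2, 1)})
        out = apply_reciprocal_translocation(g, "A", "B", 2, 1)
        assert origin_runs(out, "A") == ["A", "B"]
        assert [l.origin_label for l in out.get("A").loci] == ["A", "A", "B"]
        assert [l.origin_label for l in out.get("B").loci] == ["B", "A", "A"]
        assert out.n_genes == g.n_genes

    def test_empty_arms_logged_but_unchanged(self):
        g = make_genome({"A": 6, "B": 6})
        out = apply_reciprocal_translocation(g, "A", "B", 6, 6)
        assert [l.gene_id for l in out.get("A").loci] == [
            l.gene_id for l in g.get("A").loci]
        assert out.event_log[-1].event_type == EventType.RECIPROCAL_TRANSLOCATION

    def test_no_satellite_produced(self):
        g = make_genome({"A": 10, "B": 10})
        out = apply_reciprocal_translocation(g, "A", "B", 7, 6)
        assert not any(c.is_satellite for c in out.chromosomes)


class TestInversion:
    def test_involution_restores_order(self):
        g = make_genome({"A": 12})
        once = apply_inversion(g, "A", 0, 12)
        twice = apply_inversion(once, "A", 0, 12)
        assert [l.gene_id for l in twice.get("A").loci] == [
            l.gene_id for l in g.get("A").loci]
        assert [l.strand for l in twice.get("A").loci] == [
            l.strand for l in g.get("A").loci]

    def test_interior_inversion_flips_order_and_strand(self):
        g = make_genome({"A": 4})
        out = apply_inversion(g, "A", 1, 3)
        ids = [l.gene_id for l in out.get("A").loci]
        assert ids == ["Ag0000", "Ag0002", "Ag0001", "Ag0003"]
        strands = [l.strand for l in out.get("A").loci]
        assert strands == ["+", "-", "-", "+"]

    def test_bad_range(self):
        g = make_genome({"A": 4})
        with pytest.raises(BreakpointError):
            apply_inversion(g, "A", 3, 3)


class TestSatelliteLossAndReplay:
    def test_no_satellites_noop(self):
        g = make_genome({"A": 10})
        assert drop_satellites(g).n_chromosomes == 1

    def test_one_loss_event_per_satellite(self):
        g = make_genome({"A": 20, "B": 20, "C": 20, "D": 20})
        g = apply_ncf(g, "A", "B", 2, 18, 10)
        g = apply_eej(g, "C", "D", 18, 2)
        out = drop_satellites(g)
        losses = [e for e in out.event_log if e.event_type == EventType.SATELLITE_LOSS]
        assert len(losses) == 2
        assert out.n_chromosomes == 2

    def test_empty_script_identity(self):
        g = make_reference_genome(genes_per_chrom=20)
        out = replay_script(g, [])
        assert out.to_dict() == g.to_dict()

    def test_first_invalid_step_aborts_with_index(self):
        g = make_reference_genome(genes_per_chrom=20)
        script = [
            {"type": "NCF", "donor": "Os1", "recipient": "Os2",
             "donor_cuts": [0.1, 0.9]},
            {"type": "NCF", "donor": "NoSuch", "recipient": "Os3",
             "donor_cuts": [0.1, 0.9]},
        ]
        with pytest.raises(ScriptError) as err:
            replay_script(g, script)
        assert err.value.step == 1

    def test_replay_deterministic_serialization(self):
        g = make_reference_genome(genes_per_chrom=30)
        script = kio.load_fixture_script("brachypodium")
        a = replay_script(g, script).to_json()
        b = replay_script(g, script).to_json()
        assert a == b

    @pytest.mark.parametrize("name,n_final,n_sats", [
        ("triticeae", 7, 5), ("brachypodium", 5, 7)])
    def test_fixture_scripts_reduce_chromosome_number(self, name, n_final, n_sats):
        g = make_reference_genome()
        out = replay_script(g, kio.load_fixture_script(name))
        assert out.n_chromosomes == n_final
        losses = [e for e in out.event_log
                  if e.event_type == EventType.SATELLITE_LOSS]
        assert len(losses) == n_sats
        # chromosome arithmetic: final = initial - #NCF - #EEJ
        n_fusions = sum(1 for e in out.event_log
                        if e.event_type in (EventType.NCF, EventType.EEJ))
        assert out.n_chromosomes == g.n_chromosomes - n_fusions

    def test_json_round_trip(self):
        from karyoevo.model import Genome

        g = make_reference_genome(genes_per_chrom=10)
        out = replay_script(g, kio.load_fixture_script("triticeae")["events"][:1])
        back = Genome.from_json(out.to_json())
        assert back.to_dict() == out.to_dict()
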
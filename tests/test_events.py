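"""Overlap statistic, MH classification, event typing, IR folding of events
and deduplication — including the simulator round trip."""

import pytest

from plastidrearr import (
    JunctionEvent,
    JunctionSpec,
    classify_mh,
    compute_overlap,
    deduplicate,
    fold_event,
    intact_molecule,
    plant_cohort,
    run_pipeline,
    simulate_read_pairs,
)
from plastidrearr.align import LocalAln
from plastidrearr.events import classify_event_type
from plastidrearr.pipeline import evaluate_recovery, expected_event
from plastidrearr.simulate import Molecule
from plastidrearr.split import SplitReadCandidate


def _aln(read_id="r", mate=1, rs=0, re=75, name="pt", s=0, e=75, strand="+", score=None):
    return LocalAln(
        read_id=read_id, mate=mate, read_start=rs, read_end=re, ref_name=name,
        ref_start=s, ref_end=e, strand=strand, mismatches=0,
        score=score if score is not None else re - rs,
    )


class TestComputeOverlap:
    @pytest.mark.parametrize(
        "len_a,len_b,expected",
        [(80, 90, 20), (75, 75, 0), (70, 72, -8)],
    )
    def test_printed_formula(self, len_a, len_b, expected):
        a = _aln(rs=0, re=len_a, s=1000, e=1000 + len_a)
        b = _aln(rs=150 - len_b, re=150, s=5000, e=5000 + len_b)
        assert compute_overlap(a, b, 150) == expected

    def test_different_reads_rejected(self):
        a = _aln(read_id="r1")
        b = _aln(read_id="r2", rs=75, re=150)
        with pytest.raises(ValueError, match="different reads"):
            compute_overlap(a, b, 150)


class TestClassifyMH:
    @pytest.mark.parametrize(
        "overlap,expected",
        [(5, "+MH"), (4, "-MH"), (0, "-MH"), (-3, "-MH"), (25, "+MH")],
    )
    def test_five_bp_threshold(self, overlap, expected):
        assert classify_mh(overlap) == expected


class TestClassifyEventType:
    def _cand(self, a, b):
        return SplitReadCandidate(read_id="r", aln_a=a, aln_b=b, read_len=150)

    def test_forward_skip_is_deletion(self, small_ref):
        a = _aln(rs=0, re=80, s=1000, e=1080)
        b = _aln(rs=80, re=150, s=3000, e=3070)
        assert classify_event_type(self._cand(a, b), small_ref) == "deletion"

    def test_backward_junction_is_duplication(self, small_ref):
        a = _aln(rs=0, re=80, s=5000, e=5080)
        b = _aln(rs=80, re=150, s=2000, e=2070)
        assert classify_event_type(self._cand(a, b), small_ref) == "duplication"

    def test_strand_change_is_inversion(self, small_ref):
        a = _aln(rs=0, re=80, s=1000, e=1080, strand="+")
        b = _aln(rs=80, re=150, s=3000, e=3070, strand="-")
        assert classify_event_type(self._cand(a, b), small_ref) == "inversion"

    def test_minus_strand_pair_mirrors_plus_classification(self, small_ref):
        # the same deletion read sequenced from the other strand
        a = _aln(rs=0, re=70, s=3000, e=3070, strand="-")
        b = _aln(rs=70, re=150, s=1000, e=1080, strand="-")
        assert classify_event_type(self._cand(a, b), small_ref) == "deletion"

    def test_zero_length_adjacency_rejected(self, small_ref):
        a = _aln(rs=0, re=80, s=1000, e=1080)
        b = _aln(rs=80, re=150, s=1080, e=1150)
        with pytest.raises(ValueError, match="adjacency"):
            classify_event_type(self._cand(a, b), small_ref)


class TestFoldEvent:
    def _ev(self, pa, sa, pb, sb, hom=0):
        return JunctionEvent(
            pos_a=pa, pos_b=pb, strand_a=sa, strand_b=sb, homology_len=hom,
            mh_class=classify_mh(hom), event_type="deletion", support=1,
        )

    def test_single_copy_positions_unchanged(self, small_ref):
        ev = self._ev(2000, "+", 6000, "+")
        assert fold_event(ev, small_ref) == ev

    def test_irb_breakpoints_mirrored_with_strand_flip(self, small_ref):
        ia_s, ia_e = small_ref.ira
        ib_s, ib_e = small_ref.irb
        ev = self._ev(2000, "+", ib_s + 500, "+")
        folded = fold_event(ev, small_ref)
        assert folded.pos_a == 2000
        assert folded.pos_b == ia_s + (ib_e - (ib_s + 500))
        assert folded.strand_b == "-"
        # both breakpoints now outside the second IR
        assert folded.pos_b <= ib_s

    def test_idempotent(self, small_ref):
        ib_s, _ = small_ref.irb
        ev = self._ev(ib_s + 100, "+", ib_s + 900, "+")
        once = fold_event(ev, small_ref)
        assert fold_event(once, small_ref) == once


class TestDeduplicate:
    def _ev(self, pa, pb, hom, etype="deletion"):
        return JunctionEvent(
            pos_a=pa, pos_b=pb, strand_a="+", strand_b="+", homology_len=hom,
            mh_class=classify_mh(hom), event_type=etype, support=1,
        )

    def test_identical_keys_merge_with_support(self, small_ref):
        evs = [self._ev(2000, 6000, 7)] * 3 + [self._ev(2000, 6000, 6)]
        out = deduplicate(evs, small_ref, merge_tol=0)
        assert [(e.homology_len, e.support) for e in out] == [(6, 1), (7, 3)]

    def test_support_is_conserved(self, small_ref):
        evs = [self._ev(2000, 6000, 7), self._ev(2000, 6000, 7), self._ev(3000, 9000, 0)]
        out = deduplicate(evs, small_ref, merge_tol=0)
        assert sum(e.support for e in out) == len(evs)

    def test_merge_tol_absorbs_error_shifted_reads(self, small_ref):
        evs = [self._ev(2000, 6000, 6)] + [self._ev(2000, 6000, 7)] * 2 + [self._ev(2001, 6001, 7)]
        out = deduplicate(evs, small_ref, merge_tol=2)
        assert len(out) == 1
        assert out[0].support == 4
        assert out[0].homology_len == 7  # majority vote


class TestSimulatorRoundTrip:
    """Planted junction parameters are recovered exactly from error-free
    reads at high coverage, across MH lengths, insertions and all kinds."""

    @pytest.mark.parametrize(
        "kind,mh,ins",
        [
            ("deletion", 0, 0), ("deletion", 4, 0), ("deletion", 5, 0),
            ("deletion", 25, 0), ("deletion", 0, 1), ("deletion", 0, 20),
            ("duplication", 12, 0), ("inversion", 9, 0), ("inversion", 0, 7),
        ],
    )
    def test_single_junction_recovery(self, kind, mh, ins):
        from plastidrearr import make_reference

        ref = make_reference(10000, 2000, 4000, seed=42)
        pa = 2000
        pb = 6000 if kind != "duplication" else 16500
        spec = JunctionSpec(kind, pa, pb, mh_len=mh, ins_len=ins)
        mols, truths = plant_cohort(ref, [spec], flank_len=400, seed=3)
        reads, _ = simulate_read_pairs(mols, 150, seed=8)  # ~50x over the molecule
        res = run_pipeline(ref, reads)
        df = evaluate_recovery(res.events, truths, ref)
        assert df["recovered"].all()
        assert df["homology_exact"].all()
        assert df.attrs["false_positives"] == []
        expected = mh if ins == 0 else -ins
        assert res.events[0].homology_len == expected
        assert classify_mh(expected) == res.events[0].mh_class

    def test_mh_boundary_4_vs_5(self, small_ref):
        specs = [
            JunctionSpec("deletion", 2000, 6000, mh_len=4),
            JunctionSpec("deletion", 3500, 8000, mh_len=5),
        ]
        mols, truths = plant_cohort(small_ref, specs, flank_len=400, seed=3)
        reads, _ = simulate_read_pairs(mols, 300, seed=8)
        res = run_pipeline(small_ref, reads)
        by_pos = {e.pos_a: e for e in res.events}
        assert by_pos[2000].mh_class == "-MH" and by_pos[2000].homology_len == 4
        assert by_pos[3500].mh_class == "+MH" and by_pos[3500].homology_len == 5

    def test_ir_internal_junction_folds_to_single_event(self, small_ref):
        ia_s, _ = small_ref.ira
        spec = JunctionSpec("deletion", ia_s + 300, ia_s + 1500, mh_len=6)
        mols, truths = plant_cohort(small_ref, [spec], flank_len=400, seed=3)
        reads, _ = simulate_read_pairs(mols, 200, seed=8)
        res = run_pipeline(small_ref, reads)
        assert len(res.events) == 1
        ev = res.events[0]
        exp = expected_event(truths[0], small_ref)
        assert (ev.pos_a, ev.pos_b, ev.strand_a, ev.strand_b) == (
            exp.pos_a, exp.pos_b, exp.strand_a, exp.strand_b
        )
        assert ev.homology_len == 6
        ib_s, _ = small_ref.irb
        assert ev.pos_a <= ib_s and ev.pos_b <= ib_s

    def test_fold_conservation_of_support(self, small_ref):
        spec = JunctionSpec("deletion", 2000, 6000, mh_len=6)
        mols, _ = plant_cohort(small_ref, [spec], flank_len=400, seed=3)
        mix = [intact_molecule(small_ref), mols[0]]
        reads, _ = simulate_read_pairs(mix, 600, seed=8)
        res = run_pipeline(small_ref, reads)
        assert sum(e.support for e in res.events) == res.read_counts["split_reads"]
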
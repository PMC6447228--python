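"""Alignment engine: identity cases, decoys, tabular IO, and equivalence
with an exhaustive dynamic-programming oracle."""

import numpy as np
import pytest

from plastidrearr import (
    ReferenceIndex,
    align_read,
    build_decoys,
    make_reference,
    make_reference_set,
    revcomp,
)
from plastidrearr.align import read_alignments_tsv, write_alignments_tsv

BASES = np.array(list("ACGT"))


def dp_local_score(read: str, ref: str, match: int = 1, mismatch: int = -2) -> int:
    """Best gap-free local alignment score by the full O(nm) recurrence
    H[i,j] = max(0, H[i-1,j-1] + s(read[i], ref[j])), independent of the
    seed-and-extend engine."""
    n, m = len(read), len(ref)
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    s = np.frombuffer(ref.encode(), dtype=np.uint8)
    best = 0
    prev = np.zeros(m + 1, dtype=np.int64)
    for i in range(n):
        sub = np.where(s == r[i], match, mismatch)
        cur = np.zeros(m + 1, dtype=np.int64)
        cur[1:] = np.maximum(0, prev[:-1] + sub)
        best = max(best, int(cur.max()))
        prev = cur
    return best


def _random_seq(rng, n):
    return "".join(BASES[rng.integers(0, 4, size=n)])


class TestAlignIdentity:
    def test_exact_substring_aligns_full_length(self, small_ref):
        seqs, circ, _ = make_reference_set(small_ref)
        index = ReferenceIndex(seqs, circular=circ)
        read = small_ref.seq[5000:5150]
        alns = align_read(read, index, read_id="r")
        top = alns[0]
        assert (top.read_start, top.read_end) == (0, 150)
        assert (top.ref_name, top.ref_start, top.ref_end) == (small_ref.name, 5000, 5150)
        assert top.strand == "+" and top.mismatches == 0 and top.score == 150

    def test_reverse_strand_alignment(self, small_ref):
        seqs, circ, _ = make_reference_set(small_ref)
        index = ReferenceIndex(seqs, circular=circ)
        read = revcomp(small_ref.seq[5000:5150])
        top = align_read(read, index, read_id="r")[0]
        assert top.strand == "-"
        assert (top.ref_start, top.ref_end) == (5000, 5150)

    def test_ir_read_reports_both_copies(self, small_ref):
        ia_s, _ = small_ref.ira
        seqs, circ, _ = make_reference_set(small_ref)
        index = ReferenceIndex(seqs, circular=circ)
        read = small_ref.seq[ia_s + 500 : ia_s + 650]
        alns = [a for a in align_read(read, index) if a.ref_name == small_ref.name]
        full = [a for a in alns if a.read_span == 150]
        assert len(full) >= 2  # the IRa copy and its IRb mirror
        strands = {a.strand for a in full}
        assert strands == {"+", "-"}

    def test_origin_spanning_read_wraps_coordinates(self, small_ref):
        L = len(small_ref)
        seqs, circ, _ = make_reference_set(small_ref)
        index = ReferenceIndex(seqs, circular=circ)
        read = small_ref.circ_slice(L - 70, L + 80)
        alns = [a for a in align_read(read, index) if a.ref_name == small_ref.name]
        top = max(alns, key=lambda a: a.score)
        assert top.read_span == 150
        assert top.ref_start == L - 70 and top.ref_end == L + 80  # wraps past L

    def test_invalid_reads_rejected(self, small_ref):
        seqs, circ, _ = make_reference_set(small_ref)
        index = ReferenceIndex(seqs, circular=circ)
        with pytest.raises(ValueError):
            align_read("", index)
        with pytest.raises(ValueError):
            align_read("ACGTN" * 30, index)

    def test_unalignable_read_returns_empty(self, small_ref):
        seqs, circ, _ = make_reference_set(small_ref)
        index = ReferenceIndex(seqs, circular=circ)
        rng = np.random.default_rng(0)
        assert align_read(_random_seq(rng, 150), index) == []


class TestDecoys:
    def test_decoy_geometry(self, small_ref):
        decoys = build_decoys(small_ref, width=400)
        ib_s, _ = small_ref.irb
        L = len(small_ref)
        assert decoys["decoy_ssc_irb"] == small_ref.seq[ib_s - 200 : ib_s + 200]
        assert decoys["decoy_irb_lsc"] == small_ref.seq[L - 200 :] + small_ref.seq[:200]
        assert all(len(s) == 400 for s in decoys.values())

    def test_boundary_read_aligns_full_length_to_decoy(self, small_ref):
        ib_s, _ = small_ref.irb
        seqs, circ, _ = make_reference_set(small_ref)
        index = ReferenceIndex(seqs, circular=circ)
        read = small_ref.seq[ib_s - 75 : ib_s + 75]
        decoy_alns = [a for a in align_read(read, index) if a.ref_name == "decoy_ssc_irb"]
        assert any(a.read_span == 150 for a in decoy_alns)

    def test_oversized_decoy_rejected(self, small_ref):
        with pytest.raises(ValueError):
            build_decoys(small_ref, width=9000)
        with pytest.raises(ValueError):
            build_decoys(small_ref, width=401)


class TestEngineOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_dp_on_random_instances(self, seed):
        """Best engine score equals the exhaustive DP score on <=60 bp reads
        vs <=2 kb references, including planted noisy homologies."""
        rng = np.random.default_rng(seed)
        ref = _random_seq(rng, int(rng.integers(300, 2000)))
        if seed % 2 == 0:
            read = _random_seq(rng, int(rng.integers(25, 61)))
        else:  # plant a mutated substring so strong alignments exist
            n = int(rng.integers(30, 61))
            start = int(rng.integers(0, len(ref) - n))
            sub = list(ref[start : start + n])
            for _ in range(int(rng.integers(0, 4))):
                p = int(rng.integers(0, n))
                sub[p] = "ACGT"[rng.integers(0, 4)]
            read = "".join(sub)
            if rng.integers(0, 2):
                read = revcomp(read)
        index = ReferenceIndex({"chr": ref}, seed_len=8)
        alns = align_read(read, index, min_seg=10, score_threshold=10, exhaustive=True)
        engine_best = max((a.score for a in alns), default=0)
        oracle_best = max(dp_local_score(read, ref), dp_local_score(revcomp(read), ref))
        if oracle_best >= 10:
            assert engine_best == oracle_best
        else:
            assert engine_best == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_seeded_mode_equals_exhaustive_on_junction_reads(self, seed):
        """For junction-style reads (clean >=20 bp segments) the k-mer
        seeded search finds exactly what the exhaustive scan finds."""
        rng = np.random.default_rng(100 + seed)
        ref = _random_seq(rng, 1500)
        k = int(rng.integers(30, 120))
        read = ref[200 : 200 + k] + ref[800 : 800 + 150 - k]
        index = ReferenceIndex({"chr": ref}, seed_len=12)
        a1 = align_read(read, index, read_id="r")
        a2 = align_read(read, index, read_id="r", exhaustive=True)
        assert a1 == a2


class TestTabularIO:
    def test_round_trip(self, small_ref, tmp_path):
        seqs, circ, _ = make_reference_set(small_ref)
        index = ReferenceIndex(seqs, circular=circ)
        reads = [
            small_ref.seq[5000:5150],
            revcomp(small_ref.seq[7000:7150]),
            small_ref.seq[1000:1075] + small_ref.seq[4000:4075],
        ]
        alns = []
        for i, r in enumerate(reads):
            alns.extend(align_read(r, index, read_id=f"r{i}", mate=1 + i % 2))
        path = tmp_path / "aln.tsv"
        write_alignments_tsv(alns, path)
        back = read_alignments_tsv(path)
        assert [
            (a.read_id, a.mate, a.read_start, a.read_end, a.ref_name,
             a.ref_start, a.ref_end, a.strand, a.mismatches)
            for a in back
        ] == [
            (a.read_id, a.mate, a.read_start, a.read_end, a.ref_name,
             a.ref_start, a.ref_end, a.strand, a.mismatches)
            for a in alns
        ]
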
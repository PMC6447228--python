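"""Gap-free local alignment of reads against a plastome reference set.

The engine is a seed-and-extend local aligner restricted to gap-free
(single-diagonal) alignments, which is what the split-read overlap
statistic requires: on a gap-free alignment the read-interval length and
reference-interval length coincide, so the homology at a junction is simply
``len_a + len_b - read_len`` for the two flanking segments.

Scoring is match +1 / mismatch -2 with a reporting threshold of 20, i.e. a
perfect 20 bp segment is the smallest reportable alignment.  On each
candidate diagonal every maximal-scoring segment above the threshold is
reported (recursive maximum-subarray decomposition), on both strands,
including alignments to the decoy junction sequences.

The circular plastome is handled by appending the first ``pad`` bases to
the end of the sequence before indexing; alignment coordinates are reduced
modulo L afterwards, so an alignment crossing the origin keeps
``ref_start < L <= ref_end``.

External aligners can be substituted through the 12-column tabular
import/export (query id, subject id, percent identity, alignment length,
mismatches, gap opens, query start, query end, subject start, subject end,
e-value, score; 1-based inclusive coordinates, minus strand encoded by
subject start > subject end).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reference import PlastomeRef, revcomp

__all__ = [
    "LocalAln",
    "ReferenceIndex",
    "build_decoys",
    "make_reference_set",
    "align_read",
    "write_alignments_tsv",
    "read_alignments_tsv",
    "DECOY_SSC_IRB",
    "DECOY_IRB_LSC",
]

DECOY_SSC_IRB = "decoy_ssc_irb"
DECOY_IRB_LSC = "decoy_irb_lsc"


@dataclass(frozen=True)
class LocalAln:
    """One gap-free local alignment of a read segment.

    Read coordinates are 0-based half-open on the read *as sequenced*;
    reference coordinates are 0-based half-open on the forward strand.  For
    minus-strand alignments the read interval still refers to the original
    read, so read position ``read_start`` pairs with reference position
    ``ref_end - 1``.
    """

    read_id: str
    mate: int
    read_start: int
    read_end: int
    ref_name: str
    ref_start: int
    ref_end: int
    strand: str
    mismatches: int
    score: int

    @property
    def read_span(self) -> int:
        return self.read_end - self.read_start

    def diagonal(self) -> int:
        """Strand-aware diagonal; equal diagonals mean collinear placement."""
        if self.strand == "+":
            return self.ref_start - self.read_start
        return self.ref_start + self.read_end


def build_decoys(ref: PlastomeRef, width: int = 400) -> dict[str, str]:
    """Decoy sequences spanning the two natural IRb joins.

    Reads crossing the SSC|IRb boundary or the circular IRb|LSC origin are
    structurally normal, but their split alignments (after IR folding) mimic
    rearrangement junctions.  Adding ``width`` bp sequences centred on each
    join to the reference set lets such reads align full length and drop out
    of junction calling.
    """
    if width % 2 != 0:
        raise ValueError("decoy width must be even")
    half = width // 2
    ib_s, ib_e = ref.irb
    for rn in ("SSC", "IRb", "LSC"):
        s, e = ref.regions[rn]
        if e - s < half:
            raise ValueError(f"decoy width {width} larger than region {rn}")
    d1 = ref.seq[ib_s - half : ib_s + half]
    d2 = ref.seq[ref.length - half :] + ref.seq[:half]
    return {DECOY_SSC_IRB: d1, DECOY_IRB_LSC: d2}


def make_reference_set(
    ref: PlastomeRef,
    decoy_width: int = 400,
    extra: dict[str, str] | None = None,
) -> tuple[dict[str, str], set[str], set[str]]:
    """Reference sequences for alignment: plastome + decoys (+ extras).

    Returns ``(seqs, circular_names, decoy_names)``.  ``extra`` may hold
    additional compartments (nuclear/mitochondrial contigs); junctions with
    a side on them are excluded from plastid statistics downstream.
    """
    seqs = {ref.name: ref.seq}
    decoys = build_decoys(ref, decoy_width)
    seqs.update(decoys)
    if extra:
        seqs.update(extra)
    return seqs, {ref.name}, set(decoys)


class ReferenceIndex:
    """Exact k-mer seed index over a set of reference sequences."""

    def __init__(
        self,
        seqs: dict[str, str],
        circular: set[str] = frozenset(),
        seed_len: int = 12,
        pad: int = 200,
    ):
        self.seed_len = seed_len
        self.names = list(seqs)
        self.circular = set(circular)
        self.lengths = {n: len(s) for n, s in seqs.items()}
        self.padded: dict[str, str] = {}
        self.arrays: dict[str, np.ndarray] = {}
        self.index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in seqs.items():
            if set(seq) - set("ACGT"):
                raise ValueError(f"reference {name} contains non-ACGT characters")
            p = seq + seq[: min(pad, len(seq))] if name in self.circular else seq
            self.padded[name] = p
            self.arrays[name] = np.frombuffer(p.encode(), dtype=np.uint8)
            k = seed_len
            for i in range(len(p) - k + 1):
                self.index.setdefault(p[i : i + k], []).append((name, i))


def _maximal_segments(match: np.ndarray, threshold: int, min_len: int):
    """All disjoint maximal-scoring segments (+1/-2) with score >= threshold
    and length >= min_len, by recursive best-subarray decomposition."""
    scores = np.where(match, 1, -2).astype(np.int64)
    cs = np.concatenate([[0], np.cumsum(scores)])
    out: list[tuple[int, int, int]] = []

    def rec(lo: int, hi: int) -> None:
        if hi - lo < min_len:
            return
        # best subarray of scores[lo:hi] via prefix sums: for each end j,
        # score = cs[j+1] - min(cs[lo..j]); ties resolve to the leftmost end
        # and the leftmost (longest) start.
        seg = cs[lo : hi + 1]
        runmin = np.minimum.accumulate(seg[:-1])
        diffs = seg[1:] - runmin
        bj = int(np.argmax(diffs))
        best = int(diffs[bj])
        if best < threshold:
            return
        bi = int(np.argmin(seg[: bj + 1]))
        if bj + 1 - bi >= min_len:
            out.append((lo + bi, lo + bj + 1, best))
        rec(lo, lo + bi)
        rec(lo + bj + 1, hi)

    rec(0, len(scores))
    return sorted(out)


def align_read(
    read: str,
    index: ReferenceIndex,
    min_seg: int = 20,
    score_threshold: int = 20,
    exhaustive: bool = False,
    read_id: str = "",
    mate: int = 1,
) -> list[LocalAln]:
    """All maximal gap-free local alignments of a read, both strands.

    With ``exhaustive=True`` every diagonal is scanned (guaranteed complete;
    used for small references and the dynamic-programming cross-checks);
    otherwise only diagonals holding an exact ``seed_len``-mer seed are
    extended, which can in principle miss a segment whose longest exact
    stretch is shorter than the seed.

    Raises ValueError for empty or non-ACGT reads; returns an empty list if
    nothing aligns.
    """
    if not read:
        raise ValueError("empty read")
    if set(read) - set("ACGT"):
        raise ValueError("read contains non-ACGT characters")
    n = len(read)
    if n < min_seg:
        return []
    found: dict[tuple, LocalAln] = {}
    k = index.seed_len
    for strand in "+-":
        s = read if strand == "+" else revcomp(read)
        sarr = np.frombuffer(s.encode(), dtype=np.uint8)
        diags: dict[str, set[int]] = {}
        if exhaustive:
            for name in index.names:
                plen = len(index.padded[name])
                diags[name] = set(range(-(n - min_seg), plen - min_seg + 1))
        else:
            for i in range(n - k + 1):
                for name, p in index.index.get(s[i : i + k], ()):
                    diags.setdefault(name, set()).add(p - i)
        for name, ds in diags.items():
            rarr = index.arrays[name]
            plen = len(rarr)
            L = index.lengths[name]
            for d in sorted(ds):
                i0 = max(0, -d)
                i1 = min(n, plen - d)
                if i1 - i0 < min_seg:
                    continue
                match = sarr[i0:i1] == rarr[i0 + d : i1 + d]
                for a, b, score in _maximal_segments(match, score_threshold, min_seg):
                    rs, re_ = i0 + a, i0 + b  # on strand-oriented read
                    ref_s, ref_e = rs + d, re_ + d
                    if strand == "+":
                        q_s, q_e = rs, re_
                    else:
                        q_s, q_e = n - re_, n - rs
                    if name in index.circular and ref_s >= L:
                        ref_s -= L
                        ref_e -= L
                    key = (name, strand, ref_s, q_s)
                    mm = int((~match[a:b]).sum())
                    aln = LocalAln(
                        read_id=read_id, mate=mate, read_start=q_s, read_end=q_e,
                        ref_name=name, ref_start=ref_s, ref_end=ref_e,
                        strand=strand, mismatches=mm, score=int(score),
                    )
                    prev = found.get(key)
                    if prev is None or aln.score > prev.score:
                        found[key] = aln
    return sorted(
        found.values(),
        key=lambda a: (-a.score, a.read_start, a.ref_name, a.ref_start, a.strand),
    )


# ---------------------------------------------------------------------------
# 12-column tabular interchange
# ---------------------------------------------------------------------------

_TAB_COLS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def write_alignments_tsv(alns: list[LocalAln], path) -> None:
    """Export alignments in 12-column tabular form (1-based inclusive
    subject coordinates; minus strand has sstart > send)."""
    rows = []
    for a in alns:
        length = a.read_span
        pident = 100.0 * (length - a.mismatches) / length
        if a.strand == "+":
            sstart, send = a.ref_start + 1, a.ref_end
        else:
            sstart, send = a.ref_end, a.ref_start + 1
        rows.append(
            (
                f"{a.read_id}/{a.mate}", a.ref_name, round(pident, 2), length,
                a.mismatches, 0, a.read_start + 1, a.read_end, sstart, send,
                0.0, a.score,
            )
        )
    pd.DataFrame(rows, columns=_TAB_COLS).to_csv(path, sep="\t", index=False, header=False)


def read_alignments_tsv(path) -> list[LocalAln]:
    """Import 12-column tabular alignments (e.g. from an external local
    search tool).  Gapped records are accepted; their subject span may then
    differ from the query span."""
    df = pd.read_csv(path, sep="\t", header=None, names=_TAB_COLS)
    out = []
    for _, r in df.iterrows():
        qid = str(r["qseqid"])
        if "/" in qid:
            read_id, mate_s = qid.rsplit("/", 1)
            mate = int(mate_s)
        else:
            read_id, mate = qid, 1
        sstart, send = int(r["sstart"]), int(r["send"])
        if sstart <= send:
            strand, ref_s, ref_e = "+", sstart - 1, send
        else:
            strand, ref_s, ref_e = "-", send - 1, sstart
        length = int(r["length"])
        mism = int(r["mismatch"])
        out.append(
            LocalAln(
                read_id=read_id, mate=mate,
                read_start=int(r["qstart"]) - 1, read_end=int(r["qend"]),
                ref_name=str(r["sseqid"]), ref_start=ref_s, ref_end=ref_e,
                strand=strand, mismatches=mism,
                score=int(round(float(r["bitscore"]))),
            )
        )
    return out
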
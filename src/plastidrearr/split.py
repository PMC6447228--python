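"""Split-read selection and fully-aligned-pair filtering.

Every read ends up in exactly one of three classes: *full* (a single
alignment explains essentially the whole read), *split candidate* (two
end-anchored alignments jointly explain the read but imply a non-reference
adjacency), or *unassigned*.  Fully aligned plastid pairs feed the coverage
profile; split candidates feed junction classification.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import LocalAln
from .reference import PlastomeRef

__all__ = ["SplitReadCandidate", "detect_split", "filter_full_pairs", "is_full"]


@dataclass(frozen=True)
class SplitReadCandidate:
    """Two read-ordered alignments spanning a candidate junction;
    ``aln_a`` covers the 5' part of the read."""

    read_id: str
    aln_a: LocalAln
    aln_b: LocalAln
    read_len: int

    def __post_init__(self):
        if self.aln_a.read_start >= self.aln_b.read_start:
            raise ValueError("aln_a must precede aln_b on the read")


def is_full(aln: LocalAln, read_len: int, max_mismatch_full: int = 5) -> bool:
    """Whether one alignment explains the whole read, counting trimmed end
    bases as mismatches."""
    return (read_len - aln.read_span) + aln.mismatches <= max_mismatch_full


def _collinear(a: LocalAln, b: LocalAln, L: int | None, tol: int) -> bool:
    if a.ref_name != b.ref_name or a.strand != b.strand:
        return False
    d = a.diagonal() - b.diagonal()
    if L is not None:
        d %= L
        d = min(d, L - d)
    return abs(d) <= tol


def detect_split(
    alns: list[LocalAln],
    read_len: int,
    plastome_name: str,
    decoy_names: set[str] = frozenset(),
    circular_len: int | None = None,
    min_covered_fraction: float = 0.9,
    max_gap: int = 50,
    collinear_tol: int = 3,
) -> SplitReadCandidate | None:
    """Pick the best junction-spanning alignment pair for one read, if any.

    A valid pair (a, b) must anchor the 5' and 3' read ends, jointly cover
    at least ``min_covered_fraction`` of the read with an unaligned middle
    of at most ``max_gap`` bases (which caps detectable insertions), imply
    an adjacency that is not collinear with the reference, and have both
    sides on the plastome (not on a decoy).  Reads with a (near-)full-length
    alignment anywhere — including to a decoy — are not split candidates.

    Among valid pairs the highest combined score wins; ties break by
    smallest absolute overlap, then lexicographic reference position.
    """
    if not alns:
        return None
    # a read that one alignment essentially explains is not split
    if any(a.read_span >= min_covered_fraction * read_len for a in alns):
        return None
    slack = int(round((1 - min_covered_fraction) * read_len))
    plast = [a for a in alns if a.ref_name == plastome_name]
    decoy = [a for a in alns if a.ref_name in decoy_names]
    best = None
    best_key = None
    for a in plast:
        if a.read_start > slack:
            continue
        for b in plast:
            if b.read_end < read_len - slack:
                continue
            if not (a.read_start < b.read_start and a.read_end < b.read_end):
                continue
            overlap_on_read = a.read_end - b.read_start
            # the unaligned middle (inserted bases) counts as explained, so
            # the requirement is end anchoring: [a.read_start, b.read_end)
            # must span min_covered_fraction of the read
            if b.read_end - a.read_start < min_covered_fraction * read_len:
                continue
            if -overlap_on_read > max_gap:
                continue
            if _collinear(a, b, circular_len, collinear_tol):
                continue
            if _decoy_dominates(a, decoy) or _decoy_dominates(b, decoy):
                continue
            ov = a.read_span + b.read_span - read_len
            key = (
                -(a.score + b.score), abs(ov),
                a.ref_name, a.ref_start, b.ref_name, b.ref_start,
                a.strand, b.strand,
            )
            if best_key is None or key < best_key:
                best_key = key
                best = (a, b)
    if best is None:
        return None
    a, b = best
    return SplitReadCandidate(read_id=a.read_id, aln_a=a, aln_b=b, read_len=read_len)


def _decoy_dominates(seg: LocalAln, decoy_alns: list[LocalAln]) -> bool:
    """True if a decoy alignment covering the same read interval scores
    strictly better — the segment is then explained by a natural boundary
    the plastome placement missed (e.g. an external aligner without
    circular awareness).  Ties never dominate: decoys are verbatim
    plastome subsequences, so equal-scoring decoy hits are expected for
    any segment near an IR boundary."""
    for d in decoy_alns:
        lo = max(seg.read_start, d.read_start)
        hi = min(seg.read_end, d.read_end)
        if hi - lo >= 0.8 * seg.read_span and d.score > seg.score:
            return True
    return False


def filter_full_pairs(
    alns1: list[LocalAln],
    alns2: list[LocalAln],
    ref: PlastomeRef,
    read_len: int,
    max_mismatch_full: int = 5,
) -> tuple[tuple[LocalAln, LocalAln] | None, str]:
    """Keep a pair only if both mates align full length to the plastome.

    A mate qualifies when it has a full-length plastid placement that is
    unique up to the IR ambiguity (placements in the two IR copies fold to
    the same position).  Returns ``(pair, reason)`` where ``pair`` is None
    for dropped pairs and ``reason`` counts why (``kept``, ``mate_not_full``
    or ``ambiguous_placement``).
    """
    picks = []
    for alns in (alns1, alns2):
        fulls = [
            a for a in alns
            if a.ref_name == ref.name and is_full(a, read_len, max_mismatch_full)
        ]
        if not fulls:
            return None, "mate_not_full"
        folded = set()
        for a in fulls:
            s, e = a.ref_start, a.ref_end
            if e <= ref.length:
                folded.add(ref.fold_interval(s, e, a.strand))
            else:  # wraps the origin; cannot lie inside an IR copy
                folded.add((s, e, a.strand))
        # placements in the two IR copies fold to the same spot; a copy
        # end-trimmed at an IR boundary may be off by up to the mismatch
        # slack and still be the same placement
        distinct: list[tuple[int, int, str]] = []
        for s, e, st in sorted(folded):
            if not any(
                st == st2 and abs(s - s2) <= max_mismatch_full and abs(e - e2) <= max_mismatch_full
                for s2, e2, st2 in distinct
            ):
                distinct.append((s, e, st))
        if len(distinct) > 1:
            return None, "ambiguous_placement"
        # prefer the placement already in the first IR (or unique placement)
        pick = min(fulls, key=lambda a: (ref.fold_position(a.ref_start) != a.ref_start, -a.score, a.ref_start))
        picks.append(pick)
    return (picks[0], picks[1]), "kept"
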
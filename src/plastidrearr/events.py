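"""Classification of split-read candidates into junction events.

The homology at a junction is the *overlap statistic*: the sum of the two
split-alignment lengths minus the read length.  A positive value is a
shared direct repeat (microhomology) used by the join, zero is a blunt
join, and a negative value means inserted bases.  Junctions with an
overlap of at least 5 bp are classed as microhomology-mediated (+MH), the
rest as -MH (the NHEJ-like class), the convention used to separate
microhomology-mediated recombination from end-joining at 5 bp.

Breakpoints are inter-base boundary coordinates: ``pos_a`` is the first
reference base after segment A's end in read direction (the homologous
bases are assigned to segment A), ``pos_b`` the boundary where segment B
begins.  Events are canonicalized so that the same physical junction read
from either strand yields one key, folded out of the second inverted
repeat, and deduplicated into unique events with read support counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace

import pandas as pd

from .align import LocalAln
from .reference import PlastomeRef
from .split import SplitReadCandidate

__all__ = [
    "JunctionEvent",
    "compute_overlap",
    "classify_mh",
    "classify_event_type",
    "candidate_event",
    "fold_event",
    "deduplicate",
    "MH_CUTOFF",
    "write_events_tsv",
    "read_events_tsv",
    "write_events_bedpe",
]

#: minimum homology length for the +MH (microhomology-mediated) class
MH_CUTOFF = 5

EVENT_TYPES = ("deletion", "duplication", "inversion")


@dataclass(frozen=True)
class JunctionEvent:
    """A (possibly deduplicated) rearrangement junction.

    ``homology_len`` is the signed overlap statistic (negative = inserted
    bases); ``support`` is the number of reads backing the event.
    """

    pos_a: int
    pos_b: int
    strand_a: str
    strand_b: str
    homology_len: int
    mh_class: str
    event_type: str
    support: int = 1

    @property
    def key(self) -> tuple:
        return (self.pos_a, self.pos_b, self.strand_a, self.strand_b, self.homology_len)


def compute_overlap(aln_a: LocalAln, aln_b: LocalAln, read_len: int) -> int:
    """Overlap statistic: (len_a + len_b) - read_len, read-frame lengths.

    Positive = shared homology, zero = blunt, negative = inserted bases.
    """
    if aln_a.read_id != aln_b.read_id:
        raise ValueError(
            f"alignments from different reads: {aln_a.read_id!r} vs {aln_b.read_id!r}"
        )
    return aln_a.read_span + aln_b.read_span - read_len


def classify_mh(overlap: int) -> str:
    """+MH iff the overlap is at least 5 bp; everything below (including
    blunt joins and insertions) is -MH."""
    return "+MH" if overlap >= MH_CUTOFF else "-MH"


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _canonicalize(
    pos_a: int, strand_a: str, pos_b: int, strand_b: str
) -> tuple[int, str, int, str]:
    """One key per physical junction: reading the molecule from the other
    strand swaps the two sides and flips both strands, so pick the
    lexicographically smaller of the two representations."""
    rep = ((pos_a, strand_a), (pos_b, strand_b))
    alt = ((pos_b, _flip(strand_b)), (pos_a, _flip(strand_a)))
    (pa, sa), (pb, sb) = min(rep, alt)
    return pa, sa, pb, sb


def _breakpoints(cand: SplitReadCandidate, L: int) -> tuple[int, str, int, str]:
    a, b = cand.aln_a, cand.aln_b
    pos_a = (a.ref_end if a.strand == "+" else a.ref_start) % L
    pos_b = (b.ref_start if b.strand == "+" else b.ref_end) % L
    return pos_a, a.strand, pos_b, b.strand


def classify_event_type(cand: SplitReadCandidate, ref: PlastomeRef) -> str:
    """Type a junction from its (pre-folding) geometry.

    Differing strands mean an inversion.  Otherwise, on the plus-strand
    representation, a forward skip shorter than half the circle is a
    deletion; a junction looping backwards (or skipping more than half the
    circular genome) is a duplication/circularization.
    """
    L = ref.length
    pos_a, sa, pos_b, sb = _breakpoints(cand, L)
    if sa != sb:
        return "inversion"
    if sa == "+":
        d = (pos_b - pos_a) % L
    else:  # both minus: equivalent plus-strand junction runs b -> a
        d = (pos_a - pos_b) % L
    if d == 0:
        raise ValueError("junction collapses onto the reference (zero-length adjacency)")
    return "deletion" if d < L / 2 else "duplication"


def candidate_event(
    cand: SplitReadCandidate, ref: PlastomeRef, mh_cutoff: int = MH_CUTOFF
) -> JunctionEvent:
    """Turn one split-read candidate into a folded, classified single-read
    event (support 1)."""
    event_type = classify_event_type(cand, ref)
    overlap = compute_overlap(cand.aln_a, cand.aln_b, cand.read_len)
    pos_a, sa, pos_b, sb = _breakpoints(cand, ref.length)
    pa, sa, pb, sb = _canonicalize(pos_a, sa, pos_b, sb)
    ev = JunctionEvent(
        pos_a=pa, pos_b=pb, strand_a=sa, strand_b=sb,
        homology_len=overlap,
        mh_class="+MH" if overlap >= mh_cutoff else "-MH",
        event_type=event_type,
        support=1,
    )
    return fold_event(ev, ref)


def fold_event(ev: JunctionEvent, ref: PlastomeRef) -> JunctionEvent:
    """Fold breakpoints out of the second IR (mirroring flips the strand),
    then re-canonicalize.  Idempotent; homology, type and support are
    untouched."""
    ib_s, ib_e = ref.irb
    ia_s, _ = ref.ira

    def fold_side(pos: int, strand: str) -> tuple[int, str]:
        if ib_s < pos <= ib_e:
            return ia_s + (ib_e - pos), _flip(strand)
        return pos, strand

    pa, sa = fold_side(ev.pos_a, ev.strand_a)
    pb, sb = fold_side(ev.pos_b, ev.strand_b)
    pa, sa, pb, sb = _canonicalize(pa, sa, pb, sb)
    return replace(ev, pos_a=pa, strand_a=sa, pos_b=pb, strand_b=sb)


def deduplicate(
    events: list[JunctionEvent], ref: PlastomeRef, merge_tol: int = 0
) -> list[JunctionEvent]:
    """Collapse per-read events into unique junctions with support counts.

    Events group by (pos_a, pos_b, strand_a, strand_b, homology_len); with
    ``merge_tol > 0`` breakpoints and homology within the group may differ
    by up to that many bases from the group seed (absorbing error-shifted
    reads), and the representative coordinates/homology are the group
    majority (ties to the smallest).  Output is sorted by (pos_a, pos_b);
    total support always equals the number of input events.
    """
    if merge_tol == 0:
        groups: dict[tuple, list[JunctionEvent]] = {}
        for ev in events:
            groups.setdefault(ev.key, []).append(ev)
        merged = [replace(g[0], support=len(g)) for g in groups.values()]
        return sorted(merged, key=lambda e: (e.pos_a, e.pos_b, e.homology_len))

    ordered = sorted(events, key=lambda e: (e.strand_a, e.strand_b, e.pos_a, e.pos_b, e.homology_len))
    clusters: list[list[JunctionEvent]] = []
    for ev in ordered:
        placed = False
        for cl in clusters:
            seed = cl[0]
            if (
                ev.strand_a == seed.strand_a
                and ev.strand_b == seed.strand_b
                and abs(ev.pos_a - seed.pos_a) <= merge_tol
                and abs(ev.pos_b - seed.pos_b) <= merge_tol
                and abs(ev.homology_len - seed.homology_len) <= merge_tol
            ):
                cl.append(ev)
                placed = True
                break
        if not placed:
            clusters.append([ev])
    merged = []
    for cl in clusters:
        counts = Counter((e.pos_a, e.pos_b, e.homology_len) for e in cl)
        top = max(counts.items(), key=lambda kv: (kv[1], [-x for x in kv[0]]))
        pa, pb, hom = top[0]
        etype = Counter(e.event_type for e in cl).most_common(1)[0][0]
        merged.append(
            JunctionEvent(
                pos_a=pa, pos_b=pb,
                strand_a=cl[0].strand_a, strand_b=cl[0].strand_b,
                homology_len=hom, mh_class=classify_mh(hom),
                event_type=etype, support=len(cl),
            )
        )
    return sorted(merged, key=lambda e: (e.pos_a, e.pos_b, e.homology_len))


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

_EVENT_COLS = [
    "pos_a", "pos_b", "strand_a", "strand_b",
    "homology_len", "mh_class", "event_type", "support",
]


def write_events_tsv(events: list[JunctionEvent], path) -> None:
    """Junction table; breakpoint coordinates are written 1-based for
    human-readable (GenBank-style) reporting."""
    df = pd.DataFrame(
        [
            {
                "pos_a": e.pos_a + 1, "pos_b": e.pos_b + 1,
                "strand_a": e.strand_a, "strand_b": e.strand_b,
                "homology_len": e.homology_len, "mh_class": e.mh_class,
                "event_type": e.event_type, "support": e.support,
            }
            for e in events
        ],
        columns=_EVENT_COLS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> list[JunctionEvent]:
    df = pd.read_csv(path, sep="\t")
    return [
        JunctionEvent(
            pos_a=int(r["pos_a"]) - 1, pos_b=int(r["pos_b"]) - 1,
            strand_a=r["strand_a"], strand_b=r["strand_b"],
            homology_len=int(r["homology_len"]), mh_class=r["mh_class"],
            event_type=r["event_type"], support=int(r["support"]),
        )
        for _, r in df.iterrows()
    ]


def write_events_bedpe(events: list[JunctionEvent], ref_name: str, path) -> None:
    """BEDPE-like pairwise track (0-based half-open) for genome browsers."""
    with open(path, "w") as fh:
        for i, e in enumerate(events):
            fh.write(
                f"{ref_name}\t{e.pos_a}\t{e.pos_a + 1}"
                f"\t{ref_name}\t{e.pos_b}\t{e.pos_b + 1}"
                f"\tjunction_{i + 1}\t{e.support}\t{e.strand_a}\t{e.strand_b}\n"
            )
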
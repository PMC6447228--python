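"""Nucleotide-level annotation of recombinant junctions.

Given the two parental sequences flanking a rearrangement junction and the
recombinant (e.g. a sequenced PCR product spanning the new join), find the
short direct repeat shared by both parents at the junction — the
microhomology that mediated the join.  The recombinant must decompose into
a 5' part matching the first parent and a 3' part matching the second; the
repeat is the block that simultaneously ends the first part and begins the
second and occurs in both parents.

With ``max_mismatch > 0`` the repeat may extend beyond the exactly shared
core by positions where the two *parental* copies differ by a substitution
(the recombinant still matches one parent there); mismatches are counted
between the parental copies, never against the recombinant.
"""

from __future__ import annotations

from dataclasses import dataclass

from .events import JunctionEvent

__all__ = [
    "RepeatAnnotation",
    "HomologyHistogram",
    "find_direct_repeat",
    "homology_histogram",
]


@dataclass(frozen=True)
class RepeatAnnotation:
    """The short direct repeat at a recombinant junction.

    ``repeat_seq`` is taken from the recombinant; the parental intervals
    are 0-based half-open positions of the two copies.
    """

    repeat_seq: str
    length: int
    mismatches: int
    pos_in_parent_a: tuple[int, int]
    pos_in_parent_b: tuple[int, int]
    pos_in_recombinant: tuple[int, int]


def _check_dna(name: str, seq: str) -> None:
    if not seq or set(seq) - set("ACGT"):
        raise ValueError(f"{name} must be a non-empty uppercase ACGT string")


def find_direct_repeat(
    parent_a: str, parent_b: str, recombinant: str, max_mismatch: int = 0
) -> RepeatAnnotation:
    """Longest direct repeat shared by the parents at the junction.

    Considers every anchoring of the recombinant's 5' part in ``parent_a``
    and of its 3' part in ``parent_b``; for each, the exactly shared core
    block may be extended by up to ``max_mismatch`` parental substitutions.
    Ties break to the longest repeat, then fewest mismatches, then the
    leftmost copy in ``parent_a``.  Returns a length-0 annotation when the
    junction is blunt; raises ValueError when the recombinant cannot be
    split into a parent_a part followed by a parent_b part.
    """
    _check_dna("parent_a", parent_a)
    _check_dna("parent_b", parent_b)
    _check_dna("recombinant", recombinant)
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    n = len(recombinant)

    # prefix anchors in parent_a: (start in parent_a, exact prefix length)
    pref = []
    for a in range(len(parent_a)):
        la = 0
        while a + la < len(parent_a) and la < n and parent_a[a + la] == recombinant[la]:
            la += 1
        if la > 0:
            pref.append((a, la))
    # suffix anchors in parent_b: alignment offset o maps rec[j] -> parent_b[o+j]
    suf = []
    for o in range(-n + 1, len(parent_b) - n + 1):
        m = 0
        while (
            m < n
            and o + n - 1 - m >= 0
            and parent_b[o + n - 1 - m] == recombinant[n - 1 - m]
        ):
            m += 1
        if m > 0:
            suf.append((o, m))

    best = None
    best_key = None
    for a, la in pref:
        for o, lb in suf:
            if la + lb < n:
                continue  # no valid split with this anchoring
            j0, i0 = n - lb, la  # exact shared core on the recombinant
            # mismatch positions available for extension on either side
            right_mm = []
            t = i0
            while t < n and a + t < len(parent_a):
                if parent_a[a + t] != recombinant[t]:
                    right_mm.append(1)
                else:
                    right_mm.append(0)
                t += 1
            left_mm = []
            t = j0 - 1
            while t >= 0 and o + t >= 0:
                if parent_b[o + t] != recombinant[t]:
                    left_mm.append(1)
                else:
                    left_mm.append(0)
                t -= 1
            max_r = len(right_mm)
            max_l = len(left_mm)
            # enumerate extensions within the mismatch budget
            for r in range(max_r + 1):
                mm_r = sum(right_mm[:r])
                if mm_r > max_mismatch:
                    break
                for l in range(max_l + 1):
                    mm = mm_r + sum(left_mm[:l])
                    if mm > max_mismatch:
                        break
                    length = (i0 - j0) + r + l
                    start_a = a + j0 - l
                    key = (-length, mm, start_a, o + j0 - l)
                    if best_key is None or key < best_key:
                        best_key = key
                        best = (j0 - l, i0 + r, a, o, mm)
    if best is None:
        raise ValueError(
            "recombinant cannot be decomposed into a parent_a part followed "
            "by a parent_b part; no valid junction"
        )
    j, i, a, o, mm = best
    return RepeatAnnotation(
        repeat_seq=recombinant[j:i],
        length=i - j,
        mismatches=mm,
        pos_in_parent_a=(a + j, a + i),
        pos_in_parent_b=(o + j, o + i),
        pos_in_recombinant=(j, i),
    )


@dataclass
class HomologyHistogram:
    """Coverage-normalized unique-event counts per signed homology length.

    Negative keys are base insertions at the junction; values are unique
    events per 10,000 genome copies.
    """

    bins: dict[int, float]
    coverage: float

    def total_events(self) -> float:
        """Back-transformed unique event count (conservation check)."""
        return sum(self.bins.values()) * self.coverage / 10_000


def homology_histogram(
    events: list[JunctionEvent], coverage: float
) -> HomologyHistogram:
    """Histogram of junction homology lengths over unique events, scaled
    per 10,000 genome copies."""
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    bins: dict[int, float] = {}
    for e in events:
        bins[e.homology_len] = bins.get(e.homology_len, 0.0) + 1.0
    return HomologyHistogram(
        bins={h: c / coverage * 10_000 for h, c in sorted(bins.items())},
        coverage=coverage,
    )
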
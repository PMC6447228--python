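"""Synthetic rearranged plastome molecules and paired-end reads.

The generator emulates the sequencing side of a plastid genome-instability
experiment: a circular quadripartite plastome, a set of rearranged molecules
whose junctions carry shared direct repeats (microhomology) of 0-25 bp or
short insertions, and Illumina-style 2x150 bp read pairs at configurable
fold-coverage with i.i.d. substitution errors.

Junction chemistry
------------------
A rearranged molecule is a linear amplicon-like construct: ``flank_len``
bases ending at breakpoint ``pos_a`` followed by ``flank_len`` bases taken
at breakpoint ``pos_b`` (reverse-complemented for inversions), optionally
separated by inserted random bases.  A shared direct repeat of ``mh_len``
bases is planted by overwriting reference bases on the ``pos_b`` flank so
that both parental loci carry the identical repeat; the repeat appears once
in the molecule.  Overwrites inside an inverted repeat are mirrored into the
other IR copy so the reference stays self-consistent.

So that the homology length recovered from split-read alignments equals the
planted ``mh_len`` *exactly*, a few single-base "guard" edits adjacent to
each junction locus force the bases just beyond the shared repeat to
mismatch their counterparts on the partner locus.  Without them, a chance
match of the next base would lengthen the maximal local alignment and shift
the detected homology by one or more bases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import PlastomeRef, revcomp, _COMP

__all__ = [
    "JunctionSpec",
    "TruthJunction",
    "Molecule",
    "ReadPair",
    "plant_rearrangement",
    "plant_cohort",
    "intact_molecule",
    "simulate_read_pairs",
    "write_fastq_pair",
    "read_fastq_pair",
    "write_truth_table",
    "read_truth_table",
]

logger = logging.getLogger(__name__)

_BASES = "ACGT"
KINDS = ("deletion", "duplication", "inversion")

#: number of forced-mismatch bases beyond each junction locus; with the
#: +1/-2 alignment scoring, recovering from 3 consecutive mismatches needs
#: >6 net score of chance matches, so accidental extension is negligible.
GUARD_BASES = 3


@dataclass(frozen=True)
class JunctionSpec:
    """One engineered rearrangement junction.

    ``pos_a`` and ``pos_b`` are 0-based boundary coordinates on the
    reference: the molecule carries the bases *ending at* ``pos_a`` joined
    to the bases *starting at* ``pos_b`` (for inversions, to the minus
    strand *ending at* ``pos_b``).  ``mh_len`` bases of shared direct repeat
    or ``ins_len`` inserted bases (mutually exclusive) sit at the junction.
    """

    kind: str
    pos_a: int
    pos_b: int
    mh_len: int = 0
    ins_len: int = 0

    def validate(self, ref: PlastomeRef) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown junction kind {self.kind!r}")
        if self.mh_len < 0 or self.ins_len < 0:
            raise ValueError("mh_len and ins_len must be >= 0")
        if self.mh_len > 0 and self.ins_len > 0:
            raise ValueError("mh_len and ins_len are mutually exclusive")
        L = ref.length
        if not (0 <= self.pos_a < L and 0 <= self.pos_b < L):
            raise ValueError("breakpoints outside the reference")
        if self.kind != "inversion":
            d = (self.pos_b - self.pos_a) % L
            if d == 0:
                raise ValueError("zero-length adjacency is not a rearrangement")
            if self.kind == "deletion" and not (0 < d < L / 2):
                raise ValueError(
                    f"deletion geometry requires a forward skip < L/2 (got {d})"
                )
            if self.kind == "duplication" and d < L / 2:
                raise ValueError(
                    f"duplication geometry requires a backward junction (got {d})"
                )

    @property
    def expected_homology(self) -> int:
        return self.mh_len if self.ins_len == 0 else -self.ins_len


@dataclass(frozen=True)
class TruthJunction:
    """Simulator ground truth for one planted junction."""

    molecule_id: str
    spec: JunctionSpec
    junction_offset: int  # molecule position of the first base after the left flank
    expected_homology: int


@dataclass
class Molecule:
    """A sequence reads can be sampled from, with a mixture weight."""

    id: str
    seq: str
    weight: float = 1.0
    circular: bool = False


@dataclass
class ReadPair:
    id: str
    mate1_seq: str
    mate2_seq: str
    qual1: str
    qual2: str
    source_molecule: str
    source_pos: int


# ---------------------------------------------------------------------------
# junction planting
# ---------------------------------------------------------------------------


class _EditPlan:
    """Accumulates single-base reference edits, erroring on conflicts."""

    def __init__(self, ref: PlastomeRef):
        self.ref = ref
        self.edits: dict[int, str] = {}

    def base(self, pos: int) -> str:
        pos %= self.ref.length
        return self.edits.get(pos, self.ref.seq[pos])

    def set(self, pos: int, base: str) -> None:
        pos %= self.ref.length
        if pos in self.edits and self.edits[pos] != base:
            raise ValueError(
                f"conflicting planted edits at reference position {pos}; "
                "space the junctions further apart"
            )
        self.edits[pos] = base

    def force_mismatch(self, pos: int, avoid: str, rng: np.random.Generator) -> None:
        """Ensure base at ``pos`` differs from ``avoid`` (editing if needed)."""
        if self.base(pos) != avoid:
            return
        choices = [b for b in _BASES if b != avoid]
        self.set(pos, choices[rng.integers(0, len(choices))])


def _comp(b: str) -> str:
    return b.translate(_COMP)


def _plan_junction(plan: _EditPlan, spec: JunctionSpec, rng: np.random.Generator) -> None:
    """Plant the shared repeat and guard bases for one junction.

    The guard pairings account for inserted bases: the molecule bases
    beyond an insert sit ``ins_len`` positions further along the partner
    locus, so the forced mismatches are offset accordingly (the insert's
    own flanking bases are guarded in :func:`_insert_bases`).
    """
    h = spec.mh_len
    i = spec.ins_len
    a, b = spec.pos_a, spec.pos_b
    if spec.kind != "inversion":
        # repeat: ref[b : b+h] := ref[a-h : a]
        for t in range(h):
            plan.set(b + t, plan.base(a - h + t))
        # guards: block rightward extension of the A segment past the
        # junction (and past the insert, if any)
        for u in range(GUARD_BASES):
            plan.force_mismatch(b + h + u, plan.base(a + i + u), rng)
        # block leftward extension of the B segment before the junction
        for u in range(1, GUARD_BASES + 1):
            plan.force_mismatch(b - i - u, plan.base(a - h - u), rng)
    else:
        # repeat: ref[b-h : b] := revcomp(ref[a-h : a])
        src = "".join(plan.base(a - h + t) for t in range(h))
        rc = revcomp(src)
        for t in range(h):
            plan.set(b - h + t, rc[t])
        # block rightward extension of A: the molecule bases beyond the
        # junction are complement(ref[b-h-1-u]); they must mismatch the
        # A-locus continuation ref[a+i+u]
        for u in range(GUARD_BASES):
            plan.force_mismatch(b - h - 1 - u, _comp(plan.base(a + i + u)), rng)
        # block leftward extension of B on the minus strand: continuation
        # bases are complement(ref[b+i+u-1]); they must mismatch ref[a-h-u]
        for u in range(1, GUARD_BASES + 1):
            plan.force_mismatch(b + i + u - 1, _comp(plan.base(a - h - u)), rng)


def _insert_bases(
    plan: _EditPlan, spec: JunctionSpec, rng: np.random.Generator
) -> str:
    """Random inserted bases whose ends cannot extend either alignment."""
    n = spec.ins_len
    a, b = spec.pos_a, spec.pos_b
    avoid: list[set[str]] = [set() for _ in range(n)]
    # A segment must stop at the junction: the first bases of the insert
    # must mismatch the A-locus continuation ref[a + t]
    for t in range(min(GUARD_BASES, n)):
        avoid[t].add(plan.base(a + t))
    # B segment must not reach back into the insert: the last bases must
    # mismatch the B-locus continuation (minus strand for inversions)
    for t in range(1, min(GUARD_BASES, n) + 1):
        if spec.kind != "inversion":
            avoid[n - t].add(plan.base(b - t))
        else:
            avoid[n - t].add(_comp(plan.base(b + t - 1)))
    ins = []
    for t in range(n):
        allowed = [c for c in _BASES if c not in avoid[t]]
        ins.append(allowed[rng.integers(0, len(allowed))])
    return "".join(ins)


def _flank_intervals(spec: JunctionSpec, flank_len: int) -> tuple[tuple[int, int], tuple[int, int]]:
    g = GUARD_BASES + spec.ins_len  # guard edits sit beyond any insert
    left = (spec.pos_a - flank_len, spec.pos_a + g)
    if spec.kind != "inversion":
        right = (spec.pos_b - g, spec.pos_b + flank_len)
    else:
        right = (spec.pos_b - flank_len, spec.pos_b + g)
    return left, right


def _intervals_overlap_circ(iv1: tuple[int, int], iv2: tuple[int, int], L: int) -> bool:
    def spans(iv):
        s, e = iv
        s %= L
        e2 = s + (iv[1] - iv[0])
        if e2 <= L:
            return [(s, e2)]
        return [(s, L), (0, e2 - L)]

    for s1, e1 in spans(iv1):
        for s2, e2 in spans(iv2):
            if s1 < e2 and s2 < e1:
                return True
    return False


def plant_cohort(
    ref: PlastomeRef,
    specs: list[JunctionSpec],
    flank_len: int,
    seed: int,
    read_len: int = 150,
) -> tuple[list[Molecule], list[TruthJunction]]:
    """Plant a set of junctions and build one molecule per junction.

    All reference edits (shared repeats, guard bases) are planned and applied
    *before* any molecule sequence is extracted, so every molecule is exactly
    consistent with the final reference.  ``ref.seq`` is modified in place.

    Returns the derived molecules (ids ``mol_0001`` ...) and their ground
    truth.  Raises ValueError for ill-defined junctions (overlapping flanks)
    or for cohorts whose planted edits collide.
    """
    if flank_len < 2 * read_len:
        raise ValueError(f"flank_len must be >= 2*read_len ({2 * read_len})")
    rng = np.random.default_rng(seed)
    for spec in specs:
        spec.validate(ref)
        left, right = _flank_intervals(spec, flank_len)
        if _intervals_overlap_circ(left, right, ref.length):
            raise ValueError(
                f"flanks of junction ({spec.pos_a},{spec.pos_b}) overlap; "
                "the junction is ill-defined"
            )

    plan = _EditPlan(ref)
    inserts: list[str] = []
    for spec in specs:
        _plan_junction(plan, spec, rng)
        inserts.append(_insert_bases(plan, spec, rng) if spec.ins_len else "")
    ref.apply_edits(plan.edits)
    ref.validate()

    molecules: list[Molecule] = []
    truths: list[TruthJunction] = []
    for i, spec in enumerate(specs):
        left = ref.circ_slice(spec.pos_a - flank_len, spec.pos_a)
        if spec.kind != "inversion":
            right = ref.circ_slice(spec.pos_b + spec.mh_len, spec.pos_b + flank_len)
        else:
            right = revcomp(ref.circ_slice(spec.pos_b - flank_len, spec.pos_b - spec.mh_len))
        mol_id = f"mol_{i + 1:04d}"
        seq = left + inserts[i] + right
        molecules.append(Molecule(id=mol_id, seq=seq, weight=float(len(seq))))
        truths.append(
            TruthJunction(
                molecule_id=mol_id,
                spec=spec,
                junction_offset=flank_len,
                expected_homology=spec.expected_homology,
            )
        )
    return molecules, truths


def plant_rearrangement(
    ref: PlastomeRef, spec: JunctionSpec, flank_len: int, seed: int, read_len: int = 150
) -> tuple[str, TruthJunction]:
    """Plant a single junction (see :func:`plant_cohort`); returns the
    derived molecule sequence and its ground truth."""
    mols, truths = plant_cohort(ref, [spec], flank_len, seed, read_len=read_len)
    return mols[0].seq, truths[0]


def intact_molecule(ref: PlastomeRef, weight: float | None = None) -> Molecule:
    """The un-rearranged circular genome as a sampling molecule."""
    return Molecule(
        id=ref.name,
        seq=ref.seq,
        weight=float(ref.length) if weight is None else weight,
        circular=True,
    )


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def _as_molecules(molecules) -> list[Molecule]:
    out = []
    for i, m in enumerate(molecules):
        if isinstance(m, Molecule):
            out.append(m)
        else:
            seq, weight = m
            out.append(Molecule(id=f"molecule_{i}", seq=seq, weight=float(weight)))
    return out


def simulate_read_pairs(
    molecules,
    n_pairs: int,
    read_len: int = 150,
    insert_mean: float = 320.0,
    insert_sd: float = 50.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Sample paired-end reads from a weighted mixture of molecules.

    Fragments are drawn from molecules proportionally to their weights, with
    uniform start positions and insert lengths from a Normal(insert_mean,
    insert_sd) truncated to [read_len, molecule length].  Mates are read
    from opposite ends of the fragment on opposite strands; per-base
    substitution errors are i.i.d. at ``error_rate``.  Qualities are a
    constant Q37.  Deterministic for a fixed seed.

    Returns the read pairs and a per-pair truth table (read id, source
    molecule, fragment start on the molecule, insert length, strand).
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    if not 0 <= error_rate < 0.25:
        raise ValueError("error_rate must be in [0, 0.25)")
    if insert_mean < read_len:
        raise ValueError("insert_mean must be >= read_len")
    mols = _as_molecules(molecules)
    usable: list[Molecule] = []
    for m in mols:
        if m.weight < 0:
            raise ValueError(f"negative weight for molecule {m.id}")
        if len(m.seq) < read_len:
            logger.warning(
                "molecule %s shorter than read length (%d < %d); excluded",
                m.id, len(m.seq), read_len,
            )
            continue
        if m.weight > 0:
            usable.append(m)
    if not usable:
        raise ValueError("no usable molecule with positive weight")

    rng = np.random.default_rng(seed)
    weights = np.array([m.weight for m in usable], dtype=float)
    probs = weights / weights.sum()
    qual = chr(37 + 33) * read_len  # constant Q37

    # circular molecules are read through the origin by doubling the window
    pad = int(insert_mean + 6 * insert_sd)
    ext_seqs = [
        (m.seq + m.seq[: min(pad, len(m.seq))]) if m.circular else m.seq
        for m in usable
    ]

    mol_idx = rng.choice(len(usable), size=n_pairs, p=probs)
    ins_draw = rng.normal(insert_mean, insert_sd, size=n_pairs)
    strands = rng.integers(0, 2, size=n_pairs)
    starts_u = rng.random(n_pairs)

    pairs: list[ReadPair] = []
    rows = []
    for k in range(n_pairs):
        m = usable[mol_idx[k]]
        mol_len = len(m.seq)
        ins = int(round(ins_draw[k]))
        ins = max(read_len, min(ins, mol_len))
        if m.circular:
            start = int(starts_u[k] * mol_len)
        else:
            start = int(starts_u[k] * (mol_len - ins + 1))
        frag = ext_seqs[mol_idx[k]][start : start + ins]
        fwd, rev = frag[:read_len], revcomp(frag[-read_len:])
        if strands[k] == 0:
            m1, m2 = fwd, rev
        else:
            m1, m2 = rev, fwd
        if error_rate > 0:
            m1 = _add_errors(m1, error_rate, rng)
            m2 = _add_errors(m2, error_rate, rng)
        rid = f"read_{k + 1:06d}"
        pairs.append(
            ReadPair(
                id=rid, mate1_seq=m1, mate2_seq=m2, qual1=qual, qual2=qual,
                source_molecule=m.id, source_pos=start,
            )
        )
        rows.append((rid, m.id, start, ins, "+" if strands[k] == 0 else "-"))
    truth = pd.DataFrame(
        rows, columns=["read_id", "molecule_id", "start", "insert_len", "strand"]
    )
    return pairs, truth


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    s = list(seq)
    for p in pos:
        alts = [b for b in _BASES if b != s[p]]
        s[p] = alts[rng.integers(0, 3)]
    return "".join(s)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def write_fastq_pair(pairs: list[ReadPair], out_prefix) -> tuple[str, str]:
    """Write mates as ``<prefix>_R1.fastq`` / ``<prefix>_R2.fastq``."""
    p1, p2 = f"{out_prefix}_R1.fastq", f"{out_prefix}_R2.fastq"
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for rp in pairs:
            f1.write(f"@{rp.id}/1\n{rp.mate1_seq}\n+\n{rp.qual1}\n")
            f2.write(f"@{rp.id}/2\n{rp.mate2_seq}\n+\n{rp.qual2}\n")
    return p1, p2


def read_fastq_pair(r1_path, r2_path) -> list[ReadPair]:
    """Read paired FASTQ files back into :class:`ReadPair` records."""
    from Bio import SeqIO

    out = []
    for rec1, rec2 in zip(
        SeqIO.parse(str(r1_path), "fastq"), SeqIO.parse(str(r2_path), "fastq")
    ):
        rid = rec1.id.rsplit("/", 1)[0]
        q1 = "".join(chr(q + 33) for q in rec1.letter_annotations["phred_quality"])
        q2 = "".join(chr(q + 33) for q in rec2.letter_annotations["phred_quality"])
        out.append(
            ReadPair(
                id=rid,
                mate1_seq=str(rec1.seq).upper(),
                mate2_seq=str(rec2.seq).upper(),
                qual1=q1,
                qual2=q2,
                source_molecule="",
                source_pos=-1,
            )
        )
    return out


def write_truth_table(truths: list[TruthJunction], path) -> None:
    df = pd.DataFrame(
        [
            {
                "molecule_id": t.molecule_id,
                "kind": t.spec.kind,
                "pos_a": t.spec.pos_a,
                "pos_b": t.spec.pos_b,
                "mh_len": t.spec.mh_len,
                "ins_len": t.spec.ins_len,
                "expected_homology": t.expected_homology,
            }
            for t in truths
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_truth_table(path) -> list[TruthJunction]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        spec = JunctionSpec(
            kind=r["kind"], pos_a=int(r["pos_a"]), pos_b=int(r["pos_b"]),
            mh_len=int(r["mh_len"]), ins_len=int(r["ins_len"]),
        )
        out.append(
            TruthJunction(
                molecule_id=r["molecule_id"],
                spec=spec,
                junction_offset=-1,
                expected_homology=int(r["expected_homology"]),
            )
        )
    return out
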
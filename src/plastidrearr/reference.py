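"""Quadripartite plastome reference: construction, IR folding, FASTA IO.

A land-plant plastome is a small circular genome organised as four blocks:
a large single-copy region (LSC), one copy of the inverted repeat (IRa),
a small single-copy region (SSC) and the second inverted-repeat copy (IRb),
which is the reverse complement of IRa.  Because the two IR copies are
indistinguishable by sequence, positions in IRb are conventionally "folded"
onto IRa for counting and reporting.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "PlastomeRef",
    "make_reference",
    "revcomp",
    "fold_ir",
    "write_reference_fasta",
    "read_reference_fasta",
]

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")
_BASES = np.array(list("ACGT"))

REGION_ORDER = ("LSC", "IRa", "SSC", "IRb")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGT, case-preserving)."""
    return seq.translate(_COMP)[::-1]


@dataclass
class PlastomeRef:
    """Circular quadripartite plastome reference.

    Attributes
    ----------
    name : str
        Sequence name (FASTA header).
    seq : str
        Uppercase ACGT sequence of length L.  Mutable: the simulator may
        plant short direct repeats by overwriting bases (see
        :meth:`apply_edits`).
    regions : dict[str, tuple[int, int]]
        Half-open intervals for LSC, IRa, SSC, IRb tiling ``[0, L)`` in
        that order.
    circular : bool
        Always True for a plastome; kept explicit for clarity.
    """

    name: str
    seq: str
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)
    circular: bool = True

    # -- basic geometry ------------------------------------------------
    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)

    def region(self, name: str) -> tuple[int, int]:
        return self.regions[name]

    @property
    def ira(self) -> tuple[int, int]:
        return self.regions["IRa"]

    @property
    def irb(self) -> tuple[int, int]:
        return self.regions["IRb"]

    @property
    def folded_length(self) -> int:
        """Genome length with the second IR counted once."""
        s, e = self.irb
        return self.length - (e - s)

    def validate(self) -> None:
        """Check the quadripartite invariants; raise ValueError on failure."""
        if set(self.seq) - set("ACGT"):
            raise ValueError("reference sequence contains non-ACGT characters")
        pos = 0
        for rn in REGION_ORDER:
            if rn not in self.regions:
                raise ValueError(f"missing region {rn}")
            s, e = self.regions[rn]
            if s != pos or e <= s:
                raise ValueError(f"region {rn}=({s},{e}) does not tile the genome")
            pos = e
        if pos != self.length:
            raise ValueError("regions do not cover the full sequence")
        ia_s, ia_e = self.ira
        ib_s, ib_e = self.irb
        if (ia_e - ia_s) != (ib_e - ib_s):
            raise ValueError("IRa and IRb lengths differ")
        if revcomp(self.seq[ia_s:ia_e]) != self.seq[ib_s:ib_e]:
            raise ValueError("IRb is not the reverse complement of IRa")

    # -- circular access ----------------------------------------------
    def circ_slice(self, start: int, end: int) -> str:
        """Sequence of ``[start, end)`` with circular wrap-around.

        ``start`` may be negative or beyond L; the extent ``end - start``
        must not exceed L.
        """
        return _circ_slice(self.seq, start, end)

    def circ_base(self, pos: int) -> str:
        """Single base at ``pos`` modulo L."""
        return self.seq[pos % self.length]

    # -- IR folding ----------------------------------------------------
    def fold_position(self, pos: int) -> int:
        """Map a base position in IRb to its mirror in IRa; identity elsewhere.

        The mirror is ``IRa_start + (IRb_end - 1 - pos)``, i.e. the base in
        IRa whose reverse complement is the IRb base at ``pos``.  Idempotent.
        """
        if not 0 <= pos < self.length:
            raise ValueError(f"position {pos} outside [0, {self.length})")
        ib_s, ib_e = self.irb
        if ib_s <= pos < ib_e:
            ia_s, _ = self.ira
            return ia_s + (ib_e - 1 - pos)
        return pos

    def fold_boundary(self, pos: int) -> int:
        """Fold an inter-base boundary coordinate (0..L) out of IRb.

        Boundaries strictly inside IRb, and the origin boundary L (which
        closes IRb against the LSC), mirror to ``IRa_start + (IRb_end - pos)``.
        The SSC|IRb boundary itself is left in place (it is also an SSC
        boundary).
        """
        if not 0 <= pos <= self.length:
            raise ValueError(f"boundary {pos} outside [0, {self.length}]")
        ib_s, ib_e = self.irb
        if ib_s < pos <= ib_e:
            ia_s, _ = self.ira
            return ia_s + (ib_e - pos)
        return pos

    def fold_interval(self, start: int, end: int, strand: str) -> tuple[int, int, str]:
        """Fold a sub-interval of IRb onto IRa, flipping the strand.

        Intervals not fully inside IRb are returned unchanged.
        """
        ib_s, ib_e = self.irb
        if ib_s <= start and end <= ib_e:
            ia_s, _ = self.ira
            return (ia_s + (ib_e - end), ia_s + (ib_e - start), "-" if strand == "+" else "+")
        return (start, end, strand)

    def in_irb(self, pos: int) -> bool:
        ib_s, ib_e = self.irb
        return ib_s <= pos < ib_e

    # -- edits ----------------------------------------------------------
    def apply_edits(self, edits: dict[int, str]) -> None:
        """Overwrite single bases, mirroring edits inside either IR copy.

        Editing a base in IRa rewrites the complementary base at the mirror
        position in IRb (and vice versa) so the quadripartite invariant is
        preserved.  Conflicting mirrored edits raise ValueError.
        """
        full: dict[int, str] = {}

        def _put(p: int, b: str) -> None:
            if p in full and full[p] != b:
                raise ValueError(f"conflicting edits at position {p}")
            full[p] = b

        ia_s, ia_e = self.ira
        ib_s, ib_e = self.irb
        for pos, base in edits.items():
            if base not in "ACGT":
                raise ValueError(f"invalid base {base!r}")
            if not 0 <= pos < self.length:
                raise ValueError(f"edit position {pos} out of range")
            _put(pos, base)
            if ia_s <= pos < ia_e:
                _put(ib_s + (ia_e - 1 - pos), base.translate(_COMP))
            elif ib_s <= pos < ib_e:
                _put(ia_s + (ib_e - 1 - pos), base.translate(_COMP))
        s = list(self.seq)
        for pos, base in full.items():
            s[pos] = base
        self.seq = "".join(s)


def _circ_slice(seq: str, start: int, end: int) -> str:
    """Substring of a circular sequence; start/end may run past either end."""
    L = len(seq)
    n = end - start
    if n > L:
        raise ValueError("slice longer than the genome")
    if n < 0:
        raise ValueError("negative slice")
    start %= L
    return (seq + seq)[start : start + n]


def make_reference(lsc_len: int, ira_len: int, ssc_len: int, seed: int) -> PlastomeRef:
    """Generate a random quadripartite plastome.

    Base composition is i.i.d. uniform over ACGT in LSC, IRa and SSC; IRb is
    the reverse complement of IRa.  Deterministic for a fixed seed.

    Parameters are the region lengths in bp; each must be >= 1000 so that
    reads and decoys fit inside a single region.
    """
    for nm, v in (("lsc_len", lsc_len), ("ira_len", ira_len), ("ssc_len", ssc_len)):
        if v < 1000:
            raise ValueError(f"{nm}={v} below the 1000 bp minimum")
    rng = np.random.default_rng(seed)
    core = "".join(_BASES[rng.integers(0, 4, size=lsc_len + ira_len + ssc_len)])
    lsc = core[:lsc_len]
    ira = core[lsc_len : lsc_len + ira_len]
    ssc = core[lsc_len + ira_len :]
    seq = lsc + ira + ssc + revcomp(ira)
    L = len(seq)
    ref = PlastomeRef(
        name=f"synthetic_plastome_{lsc_len}_{ira_len}_{ssc_len}",
        seq=seq,
        regions={
            "LSC": (0, lsc_len),
            "IRa": (lsc_len, lsc_len + ira_len),
            "SSC": (lsc_len + ira_len, lsc_len + ira_len + ssc_len),
            "IRb": (lsc_len + ira_len + ssc_len, L),
        },
    )
    ref.validate()
    return ref


def fold_ir(pos: int, ref: PlastomeRef) -> int:
    """Assign a position in the second IR to the first IR (see
    :meth:`PlastomeRef.fold_position`)."""
    return ref.fold_position(pos)


def write_reference_fasta(ref: PlastomeRef, path) -> None:
    """Write the reference as FASTA, recording region intervals in the
    description (1-based inclusive, GenBank style)."""
    desc = " ".join(
        f"{rn}={s + 1}..{e}" for rn, (s, e) in ((r, ref.regions[r]) for r in REGION_ORDER)
    )
    rec = SeqRecord(Seq(ref.seq), id=ref.name, description=desc)
    SeqIO.write([rec], str(path), "fasta")


def read_reference_fasta(path) -> PlastomeRef:
    """Read a reference written by :func:`write_reference_fasta`.

    The FASTA description must carry the four region intervals
    (``LSC=1..10000 IRa=10001..12000 ...``) — IR folding and decoy
    construction are undefined without them.
    """
    rec = next(SeqIO.parse(str(path), "fasta"))
    regions: dict[str, tuple[int, int]] = {}
    for tok in rec.description.split():
        if "=" in tok and ".." in tok:
            rn, iv = tok.split("=")
            a, b = iv.split("..")
            regions[rn] = (int(a) - 1, int(b))
    if set(REGION_ORDER) - set(regions):
        raise ValueError(
            "reference FASTA header lacks LSC/IRa/SSC/IRb intervals "
            "(expected e.g. 'LSC=1..10000 IRa=10001..12000 ...')"
        )
    ref = PlastomeRef(name=rec.id, seq=str(rec.seq).upper(), regions=regions)
    ref.validate()
    return ref
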
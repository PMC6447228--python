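"""Per-kb coverage profiles, coverage normalization and rearrangement tracks.

A plastome is present in thousands of copies per cell, so raw junction
counts are meaningless across samples; everything is expressed per genome
copy.  Mean fold-coverage (genome copies sequenced) is computed from fully
aligned plastid reads over the IR-folded genome length (the second IR is
counted once, because junction positions are folded the same way), and
rearrangement counts are reported per 1x genome coverage or per 10,000
genomes.  Tracks: a per-kb read-count profile, a sliding-window junction
density (per 100 nt window, 50 nt step, per million plastid reads) and a
2-D breakpoint heat-map matrix in 1 kb tiles per 10,000 genomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import JunctionEvent
from .reference import PlastomeRef

__all__ = [
    "CoverageProfile",
    "per_kb_profile",
    "normalize_events",
    "window_density",
    "breakpoint_heatmap",
    "write_bedgraph",
    "write_heatmap_tsv",
]


@dataclass
class CoverageProfile:
    """IR-folded per-bin read counts plus mean fold-coverage.

    ``counts[i]`` is the number of plastid reads whose folded start lies in
    ``[i * bin_size, (i+1) * bin_size)``; bins only span the folded genome
    (LSC + IRa + SSC).
    """

    bin_size: int
    counts: np.ndarray
    total_plastid_reads: int
    read_len: int
    folded_genome_length: int

    @property
    def mean_fold_coverage(self) -> float:
        """Sequenced genome copies: read bases over folded genome length."""
        return self.total_plastid_reads * self.read_len / self.folded_genome_length

    @property
    def mean_read_coverage(self) -> float:
        """Read-count alternative: reads per folded genome length in kb-bins."""
        return self.total_plastid_reads / (self.folded_genome_length / self.bin_size)

    def per_million(self) -> np.ndarray:
        """Counts rescaled to reads per 1,000,000 total plastid reads."""
        if self.total_plastid_reads == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts * 1e6 / self.total_plastid_reads

    def dose_corrected(self, ref: PlastomeRef) -> np.ndarray:
        """Counts divided by per-bin genome copy number.

        Folding assigns reads from both IR copies to the first IR, so IRa
        bins carry twice the read dose of single-copy bins; dividing by the
        copy number yields the profile expected to be flat on an intact
        genome.
        """
        return self.counts / bin_copy_number(ref, self.bin_size)


def bin_copy_number(ref: PlastomeRef, bin_size: int = 1000) -> np.ndarray:
    """Mean genome copy number per folded bin (2 inside IRa, else 1)."""
    folded_len = ref.folded_length
    n_bins = int(np.ceil(folded_len / bin_size))
    ia_s, ia_e = ref.ira
    copy = np.ones(folded_len)
    copy[ia_s:ia_e] = 2.0
    out = np.empty(n_bins)
    for i in range(n_bins):
        out[i] = copy[i * bin_size : (i + 1) * bin_size].mean()
    return out


def per_kb_profile(
    read_starts: list[int],
    ref: PlastomeRef,
    read_len: int = 150,
    bin_size: int = 1000,
) -> CoverageProfile:
    """Bin fully aligned plastid reads by folded start position.

    Each read contributes 1 to bin ``floor(fold_ir(ref_start) / bin_size)``
    — positions rounded down to the nearest kb, reads in the second IR
    assigned to the first.  An empty input yields a valid zero profile.
    """
    folded_len = ref.folded_length
    n_bins = int(np.ceil(folded_len / bin_size))
    counts = np.zeros(n_bins, dtype=np.int64)
    for s in read_starts:
        counts[ref.fold_position(s) // bin_size] += 1
    return CoverageProfile(
        bin_size=bin_size,
        counts=counts,
        total_plastid_reads=len(read_starts),
        read_len=read_len,
        folded_genome_length=folded_len,
    )


def normalize_events(count: float, coverage: float, scale: str = "per_1x") -> float:
    """Express a junction count per genome copy.

    ``per_1x``: count / coverage (rearrangements per genome).
    ``per_10k_genomes``: count / coverage * 10,000.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if scale == "per_1x":
        return count / coverage
    if scale == "per_10k_genomes":
        return count / coverage * 10_000
    raise ValueError(f"unknown scale {scale!r}")


def window_density(
    events: list[JunctionEvent],
    total_plastid_reads: int,
    folded_genome_length: int,
    window: int = 100,
    step: int = 50,
    weight_by_support: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window junction density along the folded genome.

    Each event contributes at both of its breakpoint positions to every
    window containing them; values are scaled to events per 1,000,000 total
    plastid reads.  Returns ``(window_starts, values)``.
    """
    if window <= 0 or step <= 0 or step > window:
        raise ValueError("require window > 0 and 0 < step <= window")
    starts = np.arange(0, folded_genome_length, step)
    values = np.zeros(len(starts), dtype=float)
    for e in events:
        w = e.support if weight_by_support else 1
        for pos in (e.pos_a, e.pos_b):
            first = max(0, (pos - window) // step + 1)
            last = min(len(starts) - 1, pos // step)
            for i in range(first, last + 1):
                values[i] += w
    if total_plastid_reads > 0:
        values *= 1e6 / total_plastid_reads
    return starts, values


def breakpoint_heatmap(
    events: list[JunctionEvent],
    coverage: float,
    folded_genome_length: int,
    tile: int = 1000,
    normalize: bool = True,
) -> np.ndarray:
    """2-D breakpoint intersection matrix in ``tile`` bp tiles.

    ``M[i, j]`` accumulates the read support of junctions whose two folded
    breakpoints fall in tiles ``i <= j`` (coordinates canonicalized so
    pos_a <= pos_b); with ``normalize`` the matrix is scaled per 10,000
    genome copies.
    """
    n = int(np.ceil(folded_genome_length / tile))
    mat = np.zeros((n, n), dtype=float)
    for e in events:
        lo, hi = sorted((e.pos_a, e.pos_b))
        mat[min(lo // tile, n - 1), min(hi // tile, n - 1)] += e.support
    if normalize:
        if coverage <= 0:
            raise ValueError("coverage must be positive")
        mat = mat / coverage * 10_000
    return mat


def write_bedgraph(
    chrom: str, starts, values, span: int, path, decimals: int = 6
) -> None:
    """Write a (start, value) track as BedGraph with fixed span."""
    with open(path, "w") as fh:
        for s, v in zip(starts, values):
            fh.write(f"{chrom}\t{int(s)}\t{int(s) + span}\t{round(float(v), decimals)}\n")


def write_heatmap_tsv(mat: np.ndarray, path, decimals: int = 6) -> None:
    with open(path, "w") as fh:
        for row in mat:
            fh.write("\t".join(str(round(float(v), decimals)) for v in row) + "\n")
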
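# Methods

## Overview

`plastidrearr` detects and quantifies structural rearrangement junctions in
a circular quadripartite plastome from paired-end short reads. The
procedure is: (1) align each mate against a reference set (the plastome
plus two decoy junction sequences) with a gap-free local aligner; (2) keep
pairs in which both mates align full length to the plastome for coverage;
(3) for the remaining reads, select the best pair of end-anchored split
alignments that implies a non-reference adjacency; (4) compute the signed
homology at the junction, classify it, type the event, fold inverted-repeat
coordinates, and deduplicate into unique events with read support; (5)
normalize counts and tracks by sequenced genome copies.

## Model and assumptions

**Junction model.** A rearranged molecule joins the sequence ending at
boundary `pos_a` (read on the plus strand) to the sequence at boundary
`pos_b` — on the plus strand for deletions and duplications, on the minus
strand (ending at `pos_b`) for inversions. The join may use a shared
direct repeat of `h` bases (present once in the molecule, present in both
parental loci) or carry `k` inserted bases; the two are mutually
exclusive. All coordinates are 0-based boundaries internally; TSV reports
are 1-based.

**Overlap statistic.** For a junction-spanning read of length `r` with
split alignments of read-frame lengths `l_a`, `l_b`, the homology is
`l_a + l_b − r`: the shared repeat is covered by both alignments (counted
twice), inserted bases by neither (counted negatively). In gap-free mode
read-frame and reference-frame lengths coincide, which is why the aligner
is gap-free by design. Junctions with homology ≥ 5 bp are `+MH`
(microhomology-mediated recombination–like), all others — blunt joins and
insertions included — are `−MH` (end-joining–like). The signed value is
retained for histograms, where `−k` bins represent `k`-base insertions.

**Event typing.** Differing segment strands mean an inversion. Otherwise,
on the plus-strand representation with `d = (pos_b − pos_a) mod L` on the
circle of length `L`: a forward skip `0 < d < L/2` is a deletion; anything
longer loops backwards and is a duplication/circularization (the geometry
an outward-facing primer pair detects). `d = 0` is reference-consistent
and rejected. A junction read from the opposite strand swaps the two sides
and flips both strands; events are canonicalized to the lexicographically
smaller of the two representations, so each physical junction has one key.

**IR folding.** Positions in the second inverted repeat are assigned to
the first by the mirror `p ↦ IRa_start + (IRb_end − 1 − p)` (boundaries by
`p ↦ IRa_start + IRb_end − p`); mirroring flips the strand of an event
breakpoint. Folding is idempotent and applied to junction breakpoints,
coverage positions and all tracks, so every reported coordinate lies in
the folded genome (LSC + IRa + SSC).

## Alignment engine

Seed-and-extend, gap-free, both strands: exact k-mers (default 12) nominate
diagonals; on each diagonal every maximal-scoring segment is reported by
recursive best-subarray decomposition of the +1/−2 match/mismatch profile,
with a reporting threshold of 20 (a perfect 20 bp segment) and a minimum
segment length of 20 bp. The circular genome is handled by appending the
first `read_len + max_gap` bases before indexing and reducing coordinates
modulo `L` afterwards, so origin-spanning alignments are first-class.
An `exhaustive` mode scans every diagonal instead of seeded ones; it is
guaranteed complete and is what the dynamic-programming cross-checks in
the test suite exercise. The seeded mode can in principle miss a
threshold-scoring segment whose longest exact stretch is shorter than the
seed; for junction segments ≥ 20 bp at the error rates simulated here this
is negligible, and the tests verify seeded ≡ exhaustive on junction-style
reads. External aligners can be substituted via 12-column tabular
import/export (1-based inclusive subject coordinates, minus strand as
sstart > send).

**Split selection.** A candidate pair must anchor both read ends (the
interval from the 5′ segment's start to the 3′ segment's end spans ≥ 90%
of the read), have an unaligned middle ≤ 50 bp (capping detectable
insertions at 50 bp), imply a non-collinear adjacency (diagonal difference
> 3 bp, modulo `L`), and sit on the plastome rather than a decoy. Reads
with any (near-)full-length alignment — including to a decoy — are never
split candidates. Among valid pairs the highest combined score wins, then
smallest |homology|, then lexicographic reference position; the chain is
total, so results are deterministic. Decoy alignments disqualify a segment
only when they score *strictly* better: the decoys are verbatim plastome
subsequences, so equal-scoring decoy hits are expected for any segment
near an IR boundary and carry no information. (With the built-in
circular-aware aligner the decoys are therefore belt-and-braces; they do
real work when alignments come from an external tool with no circular
awareness, which is the setting they were designed for.)

**Full pairs.** A mate is "full" when trimmed bases plus mismatches are at
most 5; a pair enters the coverage profile only if both mates have a full
plastid placement unique up to IR ambiguity (placements folding to the
same interval within the mismatch slack).

## Coverage and normalization

Mean fold-coverage (sequenced genome copies) is plastid read bases divided
by the IR-folded genome length; read-count coverage is provided as an
alternative. The per-kb profile bins each fully aligned read at
`floor(fold(ref_start)/1000)`. Because folding assigns reads from both IR
copies to IRa, IRa bins carry exactly twice the dose of single-copy bins;
`CoverageProfile.dose_corrected` divides by the per-bin copy number and is
the profile expected to be flat on an intact genome (observed CV ≈ 0.07 at
50×; the raw folded profile has CV ≈ 0.30 by construction of the
architecture, not by noise). Rearrangement rates are `count / coverage`
(per genome copy) or `× 10,000` (per 10k genomes). The windowed junction
track (100 nt windows, 50 nt step) counts both breakpoints of each unique
event in every covering window, scaled per million plastid reads; the
breakpoint heat map accumulates read support in 1 kb × 1 kb tiles with
`pos_a ≤ pos_b` canonicalization, per 10k genomes. Conservation holds
exactly: raw heat-map total = summed support; window-track total =
2 windows/breakpoint × 2 breakpoints/event (away from the first
half-window of the genome, where a position is covered once).

## Direct-repeat annotation

Given the two parental sequences and the recombinant across a junction,
the finder considers every anchoring of the recombinant's 5′ part in
parent A and 3′ part in parent B; the exactly shared core block may be
extended by positions where the parental copies differ by a substitution,
up to `max_mismatch` (default 0). Mismatches are counted between the
parental copies, never against the recombinant. Ties break longest →
fewest mismatches → leftmost in parent A. A recombinant that cannot be
split into an A-part followed by a B-part raises an error; a blunt
junction returns length 0. Repeats interrupted by indels between the
parental copies are out of scope of the default model (no gap scoring is
defined for them). The implementation is checked against an exhaustive
scan over all anchorings and repeat extents on small instances.

## Statistics

Two samples are compared on raw +MH/−MH unique-event counts with Pearson's
χ² on the 2×2 table, df = 1, no continuity correction by default
(selectable); raw counts rather than normalized rates carry the sampling
model. A zero row or column raises (test undefined). Coverage-normalized
rates are compared as fold changes. No multiple-testing adjustment is
applied; comparisons are reported per contrast.

## The synthetic-data generator

The generator emulates the study conditions the pipeline targets: a
circular LSC–IRa–SSC–IRb genome (i.i.d. uniform base composition; IRb the
reverse complement of IRa), rearranged molecules as linear amplicon-like
constructs with `flank_len` (default 400 bp ≥ 2 read lengths) on each side
of one junction, and 2×150 bp read pairs with insert lengths from a
Normal(320, 50) truncated to [read length, molecule length], uniform
fragment starts (the intact genome sampled circularly through the origin),
opposite-strand mates, i.i.d. substitution errors, and constant Q37
qualities. Insert mean 320 bp and read length 150 match the library
design the pipeline is meant for; the 50 bp insert SD is a conventional
short-insert spread, chosen once.

**Exactness guards.** Shared repeats are planted by overwriting the
`pos_b`-side reference bases so both loci carry the identical repeat
(edits inside an IR are mirrored into the other copy, preserving the IR
invariant). So that the *detected* homology equals the planted `mh_len`
exactly, three guard bases beyond each junction locus are forced to
mismatch their counterparts on the partner locus (offset by the insert
length when bases are inserted, whose flanking bases are constrained the
same way). Without guards, a chance match of the next base extends the
maximal local alignment and shifts the measured homology — with the +1/−2
scoring, recovering from three consecutive forced mismatches requires a
net +7 of chance matches, making accidental extension negligible. All
edits for a cohort are planned and applied before any molecule sequence is
extracted; colliding edits (junctions too close) raise an error rather
than silently corrupting truth.

**What the generator does not emulate.** GC-biased or otherwise nonuniform
coverage, indel sequencing errors, quality-value structure, optical/PCR
duplicates, chimeric library artifacts, heteroplasmy gradients, and
multi-junction molecules. Passing the recovery tests therefore
demonstrates correctness of the detection arithmetic and bookkeeping under
clean library conditions, not robustness to every artifact of real
libraries; the error-rate path is exercised separately (binomial error
recovery, merge-tolerance deduplication).

**Inversion convention.** The minus-strand flank of an inversion is taken
as the reverse complement of the sequence *ending at* `pos_b`, so the
junction joins boundary `pos_a` to boundary `pos_b` and the planted
coordinate round-trips exactly through detection (a "starting at pos_b"
convention would make the recovered partner coordinate depend on the flank
length, which no detector could know).

## Tunable parameters

| parameter | default | units | role |
|---|---|---|---|
| `mh_cutoff` | 5 | bp | +MH/−MH classification boundary |
| `min_seg` | 20 | bp | smallest usable split segment |
| `score_threshold` | 20 | score | alignment reporting threshold (+1/−2) |
| `seed_len` | 12 | bp | exact seed k-mer |
| `min_covered_fraction` | 0.9 | — | end-anchoring requirement for splits |
| `max_gap` | 50 | bp | unaligned middle cap (max insertion) |
| `collinear_tol` | 3 | bp | diagonal tolerance for reference-consistency |
| `max_mismatch_full` | 5 | bases | trim+mismatch budget for "full" mates |
| `merge_tol` | 0 | bp | dedup coordinate/homology tolerance (2 for noisy data) |
| `decoy_width` | 400 | bp | decoy span across each IRb join |
| `bin_size` / `tile` | 1000 | bp | coverage bins / heat-map tiles |
| `window` / `step` | 100 / 50 | nt | junction density track |

## Numerical and degenerate-input choices

Deduplication with `merge_tol = 0` groups on exact keys; with a positive
tolerance, clusters take the majority (mode) coordinates and homology,
ties to the smallest. Empty read sets yield a valid zero-coverage profile;
zero events yield empty histograms and zero tracks; normalization by
non-positive coverage raises. All randomness flows through a single
`numpy` generator per operation, seeded explicitly; the full pipeline is
byte-deterministic for fixed seeds.

## Known limitations

- A junction with exactly one breakpoint inside an inverted repeat is
  *inherently* type-ambiguous: joining `x(+)` to an IRb position on (+) is
  sequence-identical to joining `x(+)` to its IRa mirror on (−), so
  duplication vs inversion cannot be decided from reads. The pipeline
  deterministically reports the type implied by the canonical (first-IR)
  placement; breakpoint coordinates and homology are unaffected.
- Homology measurement assumes the two split segments reach the read ends;
  sequencing errors within a few bases of a segment end shift individual
  reads' measured homology (absorbed by majority-vote deduplication with
  `merge_tol = 2`).
- Insertions longer than `max_gap` (50 bp) are not detectable at 150 bp
  reads; segments shorter than `min_seg` (20 bp) are not usable, so
  junctions within 20 bp of a read end go unseen by that read.
- Junctions between the plastome and other compartments (nuclear,
  mitochondrial contigs supplied as extra references) are recorded but
  excluded from plastid statistics.

## Problem sizes in the test suite

The recovery and contrast checks run on an 18 kb miniature plastome
(LSC 10 kb, IRs 2 kb, SSC 4 kb) — the quadripartite architecture at 1/8
scale — with cohorts of up to 20 junctions at 50× coverage (~5,600 read
pairs) and genotype-style cohorts at 30×. These sizes give every junction
dozens of spanning reads while keeping the whole suite fast enough to run
on every change.
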
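"""End-to-end junction detection pipeline and recovery evaluation.

``run_pipeline`` ties the stages together: align every mate of every pair
against the reference set (plastome + decoy junction sequences), route
fully aligned plastid pairs into the coverage profile, route split reads
through junction classification, fold and deduplicate events, and report
coverage-normalized statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import pandas as pd

from .align import ReferenceIndex, align_read, make_reference_set
from .annotate import homology_histogram
from .coverage import (
    CoverageProfile,
    breakpoint_heatmap,
    normalize_events,
    per_kb_profile,
    window_density,
)
from .events import JunctionEvent, MH_CUTOFF, candidate_event, deduplicate
from .reference import PlastomeRef
from .simulate import ReadPair, TruthJunction
from .split import detect_split, filter_full_pairs
from .stats import MHCounts

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "evaluate_recovery", "expected_event"]

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """All tunable thresholds, with their conventional defaults.

    ``mh_cutoff`` 5 bp separates microhomology-mediated from end-joining
    junctions; ``min_seg`` 20 bp is the smallest usable split segment at
    150 bp reads; ``decoy_width`` 400 bp covers the two natural IRb joins;
    tracks use 100/50 nt windows and 1 kb tiles/bins.
    """

    read_len: int = 150
    seed_len: int = 12
    score_threshold: int = 20
    min_seg: int = 20
    min_covered_fraction: float = 0.9
    max_gap: int = 50
    collinear_tol: int = 3
    max_mismatch_full: int = 5
    merge_tol: int = 0
    mh_cutoff: int = MH_CUTOFF
    decoy_width: int = 400
    bin_size: int = 1000
    window: int = 100
    step: int = 50
    tile: int = 1000
    exhaustive: bool = False


@dataclass
class PipelineResult:
    """Detected events plus the coverage context needed to normalize them."""

    ref: PlastomeRef
    config: PipelineConfig
    events: list[JunctionEvent]
    profile: CoverageProfile
    read_counts: dict[str, int] = field(default_factory=dict)

    @property
    def coverage(self) -> float:
        return self.profile.mean_fold_coverage

    def mh_counts(self, sample: str = "sample") -> MHCounts:
        return MHCounts.from_events(
            sample, self.events, self.coverage, self.config.mh_cutoff
        )

    def homology_histogram(self):
        return homology_histogram(self.events, self.coverage)

    def window_track(self):
        return window_density(
            self.events,
            self.profile.total_plastid_reads,
            self.ref.folded_length,
            window=self.config.window,
            step=self.config.step,
        )

    def heatmap(self, normalize: bool = True):
        return breakpoint_heatmap(
            self.events, self.coverage, self.ref.folded_length,
            tile=self.config.tile, normalize=normalize,
        )

    def summary(self) -> dict:
        """Versioned JSON-ready report of counts, coverage and rates."""
        mh = self.mh_counts()
        by_type = {t: 0 for t in ("deletion", "duplication", "inversion")}
        support = 0
        for e in self.events:
            by_type[e.event_type] += 1
            support += e.support
        cov = self.coverage
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "config": asdict(self.config),
            "total_read_pairs": self.read_counts.get("pairs", 0),
            "read_counts": dict(self.read_counts),
            "total_plastid_reads": self.profile.total_plastid_reads,
            "mean_fold_coverage": cov,
            "unique_events": len(self.events),
            "junction_read_support": support,
            "events_by_type": by_type,
            "n_plus_mh": mh.n_plus_mh,
            "n_minus_mh": mh.n_minus_mh,
            "rate_plus_mh_per_genome": mh.rate_plus if cov > 0 else None,
            "rate_minus_mh_per_genome": mh.rate_minus if cov > 0 else None,
            "events_per_10k_genomes": (
                normalize_events(len(self.events), cov, "per_10k_genomes")
                if cov > 0 else None
            ),
        }


def run_pipeline(
    ref: PlastomeRef,
    pairs: list[ReadPair],
    config: PipelineConfig | None = None,
    extra_refs: dict[str, str] | None = None,
) -> PipelineResult:
    """Detect, classify and normalize rearrangement junctions in read pairs.

    Every read is assigned to exactly one of {full, split-candidate,
    unassigned}; the per-class counts are reported in ``read_counts`` and
    always sum to the number of reads.
    """
    cfg = config or PipelineConfig()
    seqs, circular, decoys = make_reference_set(ref, cfg.decoy_width, extra_refs)
    index = ReferenceIndex(seqs, circular=circular, seed_len=cfg.seed_len,
                           pad=cfg.read_len + cfg.max_gap)
    counts = {
        "pairs": len(pairs), "reads": 2 * len(pairs),
        "full_reads": 0, "split_reads": 0, "unassigned_reads": 0,
        "full_pairs": 0, "pairs_dropped_mate_not_full": 0,
        "pairs_dropped_ambiguous_placement": 0,
    }
    coverage_starts: list[int] = []
    raw_events: list[JunctionEvent] = []

    for rp in pairs:
        alns = [
            align_read(
                seq, index, min_seg=cfg.min_seg,
                score_threshold=cfg.score_threshold,
                exhaustive=cfg.exhaustive, read_id=rp.id, mate=mate,
            )
            for mate, seq in ((1, rp.mate1_seq), (2, rp.mate2_seq))
        ]
        pair, reason = filter_full_pairs(
            alns[0], alns[1], ref, cfg.read_len, cfg.max_mismatch_full
        )
        if pair is not None:
            counts["full_pairs"] += 1
            counts["full_reads"] += 2
            coverage_starts.extend(a.ref_start for a in pair)
            continue
        counts[f"pairs_dropped_{reason}"] += 1
        for mate_alns in alns:
            cand = detect_split(
                mate_alns, cfg.read_len, ref.name, decoys,
                circular_len=ref.length,
                min_covered_fraction=cfg.min_covered_fraction,
                max_gap=cfg.max_gap, collinear_tol=cfg.collinear_tol,
            )
            if cand is not None:
                try:
                    raw_events.append(candidate_event(cand, ref, cfg.mh_cutoff))
                    counts["split_reads"] += 1
                    continue
                except ValueError:
                    pass  # reference-consistent adjacency slipped through
            counts["unassigned_reads"] += 1

    events = deduplicate(raw_events, ref, merge_tol=cfg.merge_tol)
    profile = per_kb_profile(coverage_starts, ref, cfg.read_len, cfg.bin_size)
    logger.info(
        "pipeline: %d pairs -> %d full reads, %d split reads, %d unassigned; "
        "%d unique events at %.1fx coverage",
        len(pairs), counts["full_reads"], counts["split_reads"],
        counts["unassigned_reads"], len(events), profile.mean_fold_coverage,
    )
    return PipelineResult(
        ref=ref, config=cfg, events=events, profile=profile, read_counts=counts
    )


# ---------------------------------------------------------------------------
# ground-truth evaluation
# ---------------------------------------------------------------------------


def expected_event(truth: TruthJunction, ref: PlastomeRef) -> JunctionEvent:
    """The folded canonical event a planted junction should produce."""
    from .events import _canonicalize, fold_event  # shared canonical form

    spec = truth.spec
    if spec.kind == "inversion":
        sa, sb = "+", "-"
    else:
        sa, sb = "+", "+"
    pa, sa, pb, sb = _canonicalize(spec.pos_a, sa, spec.pos_b, sb)
    ev = JunctionEvent(
        pos_a=pa, pos_b=pb, strand_a=sa, strand_b=sb,
        homology_len=truth.expected_homology,
        mh_class="+MH" if truth.expected_homology >= MH_CUTOFF else "-MH",
        event_type=spec.kind, support=0,
    )
    return fold_event(ev, ref)


def evaluate_recovery(
    events: list[JunctionEvent],
    truths: list[TruthJunction],
    ref: PlastomeRef,
    pos_tol: int = 0,
) -> pd.DataFrame:
    """Match detected events against planted junctions.

    One row per truth junction: whether it was recovered (breakpoints within
    ``pos_tol``), whether homology and event type are exact, and the read
    support.  False positives (events matching no truth) are reported in
    ``df.attrs['false_positives']``.
    """
    rows = []
    matched_events: set[int] = set()
    for t in truths:
        exp = expected_event(t, ref)
        hit = None
        for i, e in enumerate(events):
            if (
                e.strand_a == exp.strand_a and e.strand_b == exp.strand_b
                and abs(e.pos_a - exp.pos_a) <= pos_tol
                and abs(e.pos_b - exp.pos_b) <= pos_tol
            ):
                hit = (i, e)
                break
        rows.append(
            {
                "molecule_id": t.molecule_id,
                "kind": t.spec.kind,
                "expected_pos_a": exp.pos_a,
                "expected_pos_b": exp.pos_b,
                "expected_homology": t.expected_homology,
                "recovered": hit is not None,
                "homology_exact": hit is not None and hit[1].homology_len == t.expected_homology,
                "type_exact": hit is not None and hit[1].event_type == t.spec.kind,
                "support": hit[1].support if hit else 0,
            }
        )
        if hit:
            matched_events.add(hit[0])
    df = pd.DataFrame(rows)
    df.attrs["false_positives"] = [
        e for i, e in enumerate(events) if i not in matched_events
    ]
    return df
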
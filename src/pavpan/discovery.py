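"""Filter cascade turning candidate structural variants into PAV calls.

A presence/absence variant (PAV) is a sequence that is present in one
inbred genome (the *donor*) and entirely absent from the other (the
*acceptor*).  Candidate deletion calls produced by external SV callers
are noisy: they include assembly artifacts (also detected when the
donor's own reads are mapped back onto its assembly), small indels,
copy-number variants (the sequence is missing at the called locus but
present elsewhere in the acceptor), poorly assembled regions, and very
large calls that are in practice misclassified duplications.

The cascade applies, in order:

1. self-consistency   — drop calls also seen in the self-mapping control;
2. minimum size       — keep calls >= 1 kb (configurable);
3. genotype specificity — keep calls whose footprint has opposite-genotype
   read depth below 5x over at least 70% of its length (rejects CNVs);
4. assembly support   — keep calls whose own properly-paired read pairs
   cover more than 90% of the length (rejects assembly errors);
5. oversize flag      — calls above 200 kb are flagged as suspected
   misclassified duplications and excluded from the PAV output;
6. anchoring          — place the remaining calls on the acceptor genome
   via exact flank matching; a unique placement yields a breakpoint.

Scaffolds too short to expose shared flanks are handled separately: if
they are almost uncovered by acceptor reads they become *incomplete*
PAVs without a breakpoint.

All coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "CandidateSV",
    "CoverageProfile",
    "PavRecord",
    "FilterReport",
    "DiscoveryParams",
    "filter_self_consistency",
    "filter_min_size",
    "filter_specificity",
    "filter_assembly_support",
    "classify_incomplete_scaffolds",
    "flag_oversize",
    "count_anchor_hits",
    "assign_anchor_category",
    "run_discovery_pipeline",
]


@dataclass
class CandidateSV:
    """One candidate deletion interval on the donor genome."""

    id: str
    contig: str
    start: int
    end: int
    caller_support: int = 0
    detected_in_self_mapping: bool = False
    anchor_hit_count: int | None = None
    anchor_position: tuple[str, int, int] | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.id}: end ({self.end}) must exceed start ({self.start})")
        if self.caller_support < 0:
            raise ValueError(f"{self.id}: caller_support must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CoverageProfile:
    """Per-base read depth over one interval of one contig.

    ``depth`` is total mapped-read depth; ``properly_paired_depth`` counts
    only read pairs mapped with correct orientation and insert size and
    may be absent when not needed.
    """

    contig: str
    start: int
    end: int
    depth: np.ndarray
    properly_paired_depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if len(self.depth) != self.end - self.start:
            raise ValueError("depth vector length must equal interval length")
        if self.properly_paired_depth is not None:
            self.properly_paired_depth = np.asarray(self.properly_paired_depth)
            if len(self.properly_paired_depth) != self.end - self.start:
                raise ValueError("properly_paired_depth length must equal interval length")
        if (self.depth < 0).any():
            raise ValueError("negative depth")

    def slice_depth(self, start: int, end: int) -> np.ndarray:
        if start < self.start or end > self.end:
            raise ValueError(
                f"profile [{self.start},{self.end}) does not span requested [{start},{end})"
            )
        return self.depth[start - self.start : end - self.start]

    def slice_proper(self, start: int, end: int) -> np.ndarray:
        if self.properly_paired_depth is None:
            raise ValueError("profile carries no properly-paired depth")
        if start < self.start or end > self.end:
            raise ValueError(
                f"profile [{self.start},{self.end}) does not span requested [{start},{end})"
            )
        return self.properly_paired_depth[start - self.start : end - self.start]


@dataclass
class PavRecord:
    """One genotype-specific region after filtering and anchoring."""

    id: str
    contig: str
    start: int
    end: int
    category: str  # anchored_unique | anchored_ambiguous | incomplete | unanchored
    sequence: str | None = None
    breakpoint: tuple[str, int] | None = None  # (acceptor contig, position)
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.category == "incomplete" and self.breakpoint is not None:
            raise ValueError("incomplete PAVs carry no breakpoint")

    @property
    def length(self) -> int:
        return self.end - self.start


class FilterReport:
    """Per-stage bookkeeping of the cascade: counts telescope exactly."""

    def __init__(self) -> None:
        self.stages: list[tuple[str, int, int]] = []  # (name, n_in, n_out)
        self.rejections: dict[str, tuple[str, str]] = {}  # id -> (stage, reason)

    def record_stage(self, name: str, n_in: int, n_out: int) -> None:
        self.stages.append((name, n_in, n_out))

    def reject(self, candidate_id: str, stage: str, reason: str) -> None:
        self.rejections[candidate_id] = (stage, reason)

    def telescopes(self) -> bool:
        return all(
            self.stages[i][2] == self.stages[i + 1][1] for i in range(len(self.stages) - 1)
        )


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def filter_self_consistency(
    candidates: Sequence[CandidateSV],
    self_detections: Sequence[CandidateSV] | None = None,
    mode: str = "any_overlap",
    report: FilterReport | None = None,
) -> list[CandidateSV]:
    """Drop candidates also detected in the donor self-mapping control.

    A candidate is removed if it is flagged ``detected_in_self_mapping``,
    or if it overlaps an interval in ``self_detections``.  ``mode`` is
    either ``any_overlap`` (a single shared base suffices) or
    ``reciprocal_50`` (the overlap must cover >= 50% of both intervals).
    """
    if mode not in ("any_overlap", "reciprocal_50"):
        raise ValueError(f"unknown overlap mode {mode!r}")
    self_detections = self_detections or []
    kept = []
    for cand in candidates:
        hit = cand.detected_in_self_mapping
        if not hit:
            for det in self_detections:
                if det.contig != cand.contig:
                    continue
                ov = _overlaps(cand.start, cand.end, det.start, det.end)
                if ov == 0:
                    continue
                if mode == "any_overlap" or (
                    ov >= 0.5 * cand.length and ov >= 0.5 * det.length
                ):
                    hit = True
                    break
        if hit:
            if report is not None:
                report.reject(cand.id, "self_consistency", "detected in self-mapping")
        else:
            kept.append(cand)
    if report is not None:
        report.record_stage("self_consistency", len(candidates), len(kept))
    return kept


def filter_min_size(
    candidates: Sequence[CandidateSV],
    min_bp: int = 1000,
    report: FilterReport | None = None,
) -> list[CandidateSV]:
    """Keep candidates of length >= ``min_bp`` (inclusive; default 1 kb)."""
    if min_bp <= 0:
        raise ValueError("min_bp must be positive")
    kept = []
    for cand in candidates:
        if cand.length >= min_bp:
            kept.append(cand)
        elif report is not None:
            report.reject(cand.id, "min_size", f"length {cand.length} < {min_bp}")
    if report is not None:
        report.record_stage("min_size", len(candidates), len(kept))
    return kept


def filter_specificity(
    candidate: CandidateSV,
    opposite_profile: CoverageProfile,
    depth_cutoff: int = 5,
    frac: float = 0.70,
) -> tuple[bool, float]:
    """Genotype-specificity test against opposite-genotype read depth.

    Keep iff the fraction of bases with depth strictly below
    ``depth_cutoff`` is at least ``frac``.  Returns (keep, fraction).
    A CNV — deleted at the locus but present elsewhere — attracts
    opposite-genotype reads and fails this test.
    """
    depth = opposite_profile.slice_depth(candidate.start, candidate.end)
    low_frac = float(np.mean(depth < depth_cutoff))
    return low_frac >= frac, low_frac


def filter_assembly_support(
    candidate: CandidateSV,
    own_profile: CoverageProfile,
    frac: float = 0.90,
) -> tuple[bool, float]:
    """Keep iff properly-paired own-read pairs cover > ``frac`` of bases (strict)."""
    proper = own_profile.slice_proper(candidate.start, candidate.end)
    covered = float(np.mean(proper >= 1))
    return covered > frac, covered


def classify_incomplete_scaffolds(
    scaffolds: Mapping[str, str],
    opposite_profiles: Mapping[str, CoverageProfile],
    covered_frac_max: float = 0.20,
    depth_cutoff: int = 5,
    low_frac: float = 0.70,
) -> list[PavRecord]:
    """Classify whole scaffolds as incomplete PAVs.

    A scaffold too short to expose flanks shared with the acceptor becomes
    an incomplete PAV iff (i) fewer than ``covered_frac_max`` of its bases
    have any opposite-genotype coverage AND (ii) the specificity criterion
    (depth < cutoff over >= ``low_frac``) holds over its whole length.
    """
    records = []
    for name, seq in scaffolds.items():
        prof = opposite_profiles[name]
        depth = prof.slice_depth(0, len(seq))
        covered = float(np.mean(depth >= 1))
        low = float(np.mean(depth < depth_cutoff))
        if covered < covered_frac_max and low >= low_frac:
            records.append(
                PavRecord(id=name, contig=name, start=0, end=len(seq),
                          category="incomplete", sequence=seq)
            )
    return records


def flag_oversize(
    candidates: Sequence[CandidateSV],
    max_bp: int = 200_000,
    report: FilterReport | None = None,
) -> tuple[list[CandidateSV], list[CandidateSV]]:
    """Split candidates at ``max_bp``: (kept, oversize-flagged).

    Deletion calls strictly larger than ``max_bp`` are, on manual
    inspection, misclassified genome duplications; they are flagged and
    excluded from PAV output rather than silently dropped.
    """
    kept, flagged = [], []
    for cand in candidates:
        if cand.length > max_bp:
            flagged.append(cand)
            if report is not None:
                report.reject(cand.id, "oversize", f"length {cand.length} > {max_bp}")
        else:
            kept.append(cand)
    if report is not None:
        report.record_stage("oversize", len(candidates), len(kept))
    return kept, flagged


def count_anchor_hits(
    donor_seq: str,
    candidate: CandidateSV,
    acceptor_seq: str,
    flank: int = 100,
) -> tuple[int, int | None]:
    """Toy anchoring by exact flank matching.

    The junction a deletion leaves in the acceptor is the ``flank`` bases
    preceding the deletion joined to the ``flank`` bases following it.
    Count (possibly overlapping) exact occurrences of that junction in
    the acceptor; return (hit count, position of first hit breakpoint).
    """
    left = donor_seq[max(0, candidate.start - flank) : candidate.start]
    right = donor_seq[candidate.end : candidate.end + flank]
    junction = left + right
    if not junction:
        return 0, None
    hits = []
    pos = acceptor_seq.find(junction)
    while pos != -1:
        hits.append(pos + len(left))  # breakpoint = junction point in acceptor
        pos = acceptor_seq.find(junction, pos + 1)
    return len(hits), (hits[0] if hits else None)


def assign_anchor_category(hit_count: int) -> str:
    """Map an anchor placement count to a PAV category."""
    if hit_count < 0:
        raise ValueError("anchor hit count must be >= 0")
    if hit_count == 0:
        return "unanchored"
    if hit_count == 1:
        return "anchored_unique"
    return "anchored_ambiguous"


@dataclass(frozen=True)
class DiscoveryParams:
    min_bp: int = 1000
    depth_cutoff: int = 5
    specificity_frac: float = 0.70
    assembly_frac: float = 0.90
    scaffold_covered_max: float = 0.20
    oversize_bp: int = 200_000
    flank: int = 100
    overlap_mode: str = "any_overlap"


def run_discovery_pipeline(
    candidates: Sequence[CandidateSV],
    scaffolds: Mapping[str, str],
    opposite_profiles: Mapping[str, CoverageProfile],
    self_profiles: Mapping[str, CoverageProfile],
    donor_seqs: Mapping[str, str],
    acceptor_seq: str,
    params: DiscoveryParams = DiscoveryParams(),
    self_detections: Sequence[CandidateSV] | None = None,
) -> tuple[list[PavRecord], FilterReport]:
    """Run the full cascade and append incomplete-scaffold PAVs.

    ``opposite_profiles`` / ``self_profiles`` map contig (and scaffold)
    names to full-length coverage profiles.  Raises KeyError listing the
    offending candidate if a contig lacks a profile or sequence.
    """
    report = FilterReport()
    missing = [c.id for c in candidates
               if c.contig not in opposite_profiles or c.contig not in donor_seqs]
    if missing:
        raise KeyError(f"candidates on contigs without profile/sequence: {missing}")

    stage1 = filter_self_consistency(candidates, self_detections,
                                     mode=params.overlap_mode, report=report)
    stage2 = filter_min_size(stage1, min_bp=params.min_bp, report=report)

    stage3 = []
    for cand in stage2:
        keep, frac = filter_specificity(
            cand, opposite_profiles[cand.contig],
            depth_cutoff=params.depth_cutoff, frac=params.specificity_frac)
        if keep:
            stage3.append(cand)
        else:
            report.reject(cand.id, "specificity",
                          f"only {frac:.2f} of bases below {params.depth_cutoff}x")
    report.record_stage("specificity", len(stage2), len(stage3))

    stage4 = []
    for cand in stage3:
        keep, frac = filter_assembly_support(
            cand, self_profiles[cand.contig], frac=params.assembly_frac)
        if keep:
            stage4.append(cand)
        else:
            report.reject(cand.id, "assembly_support",
                          f"properly-paired coverage {frac:.2f} <= {params.assembly_frac}")
    report.record_stage("assembly_support", len(stage3), len(stage4))

    stage5, oversize = flag_oversize(stage4, max_bp=params.oversize_bp, report=report)

    records = []
    for cand in stage5:
        donor_seq = donor_seqs[cand.contig]
        hits, bp_pos = count_anchor_hits(donor_seq, cand, acceptor_seq, flank=params.flank)
        category = assign_anchor_category(hits)
        records.append(PavRecord(
            id=cand.id, contig=cand.contig, start=cand.start, end=cand.end,
            category=category,
            sequence=donor_seq[cand.start : cand.end],
            breakpoint=("acceptor", bp_pos) if category == "anchored_unique" else None,
        ))
    report.record_stage("anchoring", len(stage5), len(records))

    records.extend(
        classify_incomplete_scaffolds(
            scaffolds, opposite_profiles,
            covered_frac_max=params.scaffold_covered_max,
            depth_cutoff=params.depth_cutoff, low_frac=params.specificity_frac)
    )
    return records, report
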
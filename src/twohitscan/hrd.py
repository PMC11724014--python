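"""Genomic-scar HRD scoring from allele-specific copy-number segments.

The score is the unweighted sum of three counters over a smoothed segment
profile (no ploidy adjustment):

* HRD-LOH: segments with minor copy number 0 longer than 15 Mb that do not
  span an entire chromosome;
* TAI: allelically imbalanced segments reaching a chromosome end (within a
  small tolerance) without crossing the centromere, at least 11 Mb long;
* LST: breakpoints between two segments of at least 10 Mb separated by at
  most 3 Mb, counted per chromosome arm after 3 Mb smoothing.

A total of >= 63 classifies the tumour as HRD-high.  Sex chromosomes are
excluded by default.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

from .io_formats import ChromosomeArms, Segment, SegmentProfile

__all__ = [
    "HRDResult",
    "smooth_segments",
    "count_hrd_loh",
    "count_tai",
    "count_lst",
    "hrd_score",
    "HRD_THRESHOLD",
]

HRD_THRESHOLD = 63
SEX_CHROMS = frozenset({"X", "Y", "chrX", "chrY"})


@dataclass
class HRDResult:
    loh_count: int
    tai_count: int
    lst_count: int
    threshold_used: int = HRD_THRESHOLD

    @property
    def total(self) -> int:
        return self.loh_count + self.tai_count + self.lst_count

    @property
    def hrd_high(self) -> bool:
        return self.total >= self.threshold_used

    def as_dict(self) -> dict:
        return {
            "loh": self.loh_count,
            "tai": self.tai_count,
            "lst": self.lst_count,
            "total": self.total,
            "threshold": self.threshold_used,
            "hrd_high": self.hrd_high,
        }


def _coalesce(segments: list[Segment]) -> list[Segment]:
    """Merge contiguous equal-state neighbours (summary stats dropped)."""
    out: list[Segment] = []
    for seg in segments:
        if (
            out
            and out[-1].chrom == seg.chrom
            and out[-1].state == seg.state
            and seg.start == out[-1].end + 1
        ):
            out[-1] = replace(out[-1], end=seg.end, baf=None, log2=None)
        else:
            out.append(replace(seg))
    return out


def smooth_segments(profile: SegmentProfile, min_len_bp: float = 3e6) -> SegmentProfile:
    """Iteratively absorb sub-threshold segments into their longer neighbour.

    The shortest segment under ``min_len_bp`` is merged into whichever
    adjacent same-chromosome neighbour is longer (adopting that neighbour's
    copy-number state); contiguous equal-state segments are then coalesced.
    Idempotent: a second pass is a no-op.
    """
    by_chrom: dict[str, list[Segment]] = {}
    for seg in profile:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    smoothed: list[Segment] = []
    for chrom, segs in by_chrom.items():
        segs = [replace(s) for s in segs]
        while len(segs) > 1:
            lengths = [s.length for s in segs]
            idx = min(range(len(segs)), key=lambda i: lengths[i])
            if lengths[idx] >= min_len_bp:
                break
            left = segs[idx - 1] if idx > 0 else None
            right = segs[idx + 1] if idx < len(segs) - 1 else None
            if left is not None and (right is None or left.length >= right.length):
                segs[idx - 1] = replace(left, end=segs[idx].end, baf=None, log2=None)
            else:
                segs[idx + 1] = replace(right, start=segs[idx].start, baf=None, log2=None)
            del segs[idx]
            segs = _coalesce(segs)
        smoothed.extend(_coalesce(segs))
    return SegmentProfile(
        sample_id=profile.sample_id, segments=smoothed, genome_build=profile.genome_build
    )


def _autosomal(profile: SegmentProfile, include_sex: bool) -> list[Segment]:
    return [s for s in profile if include_sex or s.chrom not in SEX_CHROMS]


def count_hrd_loh(
    profile: SegmentProfile,
    arms: ChromosomeArms,
    min_len_bp: float = 15e6,
    telomere_tol_bp: float = 1e4,
    include_sex: bool = False,
) -> int:
    """Count LOH segments strictly longer than ``min_len_bp`` that do not
    span the whole chromosome (expects a smoothed profile)."""
    n = 0
    for seg in _autosomal(profile, include_sex):
        if not seg.is_loh or seg.length <= min_len_bp:
            continue
        bounds = arms[seg.chrom]
        whole = (
            seg.start <= bounds.chrom_start + telomere_tol_bp
            and seg.end >= bounds.chrom_end - telomere_tol_bp
        )
        if not whole:
            n += 1
    return n


def count_tai(
    profile: SegmentProfile,
    arms: ChromosomeArms,
    min_len_bp: float = 11e6,
    telomere_tol_bp: float = 1e4,
    include_sex: bool = False,
) -> int:
    """Count telomeric allelic imbalances: imbalanced segments reaching a
    chromosome end without crossing the centromere."""
    n = 0
    for seg in _autosomal(profile, include_sex):
        if not seg.is_imbalanced or seg.length < min_len_bp:
            continue
        bounds = arms[seg.chrom]
        telomeric = (
            seg.start <= bounds.chrom_start + telomere_tol_bp
            or seg.end >= bounds.chrom_end - telomere_tol_bp
        )
        crosses_cen = (
            seg.start < bounds.centromere_start and seg.end > bounds.centromere_end
        )
        if telomeric and not crosses_cen:
            n += 1
    return n


def count_lst(
    profile: SegmentProfile,
    arms: ChromosomeArms,
    min_seg_bp: float = 10e6,
    max_gap_bp: float = 3e6,
    include_sex: bool = False,
) -> int:
    """Count large-scale state transitions on a profile smoothed at 3 Mb.

    A transition is a breakpoint between consecutive segments of at least
    ``min_seg_bp`` each with an inter-segment gap of at most ``max_gap_bp``;
    breakpoints falling inside the centromere are per-arm boundaries, not
    transitions.
    """
    by_chrom: dict[str, list[Segment]] = {}
    for seg in _autosomal(profile, include_sex):
        by_chrom.setdefault(seg.chrom, []).append(seg)
    n = 0
    for chrom, segs in by_chrom.items():
        bounds = arms[chrom]
        for prev, nxt in zip(segs, segs[1:]):
            if prev.state == nxt.state:
                continue
            gap = nxt.start - prev.end - 1
            if gap > max_gap_bp:
                continue
            if prev.length < min_seg_bp or nxt.length < min_seg_bp:
                continue
            breakpoint_pos = (prev.end + nxt.start) / 2.0
            if bounds.centromere_start <= breakpoint_pos <= bounds.centromere_end:
                continue
            n += 1
    return n


def hrd_score(
    profile: SegmentProfile,
    arms: ChromosomeArms,
    threshold: int = HRD_THRESHOLD,
    smooth_min_len_bp: float = 3e6,
    loh_min_len_bp: float = 15e6,
    tai_min_len_bp: float = 11e6,
    lst_min_seg_bp: float = 10e6,
    lst_max_gap_bp: float = 3e6,
    telomere_tol_bp: float = 1e4,
    include_sex: bool = False,
) -> HRDResult:
    """Unweighted HRD scar score: LOH + TAI + LST, HRD-high at >= threshold."""
    smoothed = smooth_segments(profile, smooth_min_len_bp)
    return HRDResult(
        loh_count=count_hrd_loh(
            smoothed, arms, loh_min_len_bp, telomere_tol_bp, include_sex
        ),
        tai_count=count_tai(smoothed, arms, tai_min_len_bp, telomere_tol_bp, include_sex),
        lst_count=count_lst(smoothed, arms, lst_min_seg_bp, lst_max_gap_bp, include_sex),
        threshold_used=threshold,
    )
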
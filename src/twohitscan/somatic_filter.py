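"""Final-stage somatic variant filtering and SBS pooling.

A somatic call survives when it is rare in the population (gnomAD AF at most
1e-4; missing AF counts as 0), falls inside an extended capture target, has
adequate depth and alt-read support, and its VAF clears a purity-adjusted
cut-off max(vaf_floor, vaf_purity_factor * p/2) — i.e. a configurable
fraction of the expected clonal heterozygous VAF at purity p.  Removals are
attributed to the first failing rule in a fixed order so the audit counts
partition the removed set.
"""
from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, replace
from pathlib import Path

from .io_formats import VariantRecord, to_one_based

__all__ = [
    "FilterConfig",
    "TargetIntervals",
    "filter_somatic",
    "pool_unique_sbs",
    "RULE_ORDER",
]

RULE_ORDER = ("gnomad_af", "target", "depth", "alt_reads", "vaf")


@dataclass
class FilterConfig:
    max_gnomad_af: float = 1e-4
    target_extension_bp: int = 150
    min_depth: int = 10
    min_alt_reads: int = 4
    vaf_floor: float = 0.03
    vaf_purity_factor: float = 0.2
    stringent: bool = False

    def __post_init__(self) -> None:
        for name in (
            "max_gnomad_af",
            "target_extension_bp",
            "min_depth",
            "min_alt_reads",
            "vaf_floor",
            "vaf_purity_factor",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def stringent_profile(cls) -> "FilterConfig":
        """Harsher settings for tumours without a paired germline sample."""
        return cls(
            max_gnomad_af=0.0, min_alt_reads=8, vaf_floor=0.10, stringent=True
        )


class TargetIntervals:
    """Capture-target intervals, held 1-based inclusive, queried with extension."""

    def __init__(self, intervals: list[tuple[str, int, int]]):
        self._by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start > end:
                raise ValueError(f"interval {chrom}:{start}-{end} has start > end")
            self._by_chrom.setdefault(chrom, []).append((start, end))
        self._starts: dict[str, list[int]] = {}
        for chrom, ivals in self._by_chrom.items():
            ivals.sort()
            self._by_chrom[chrom] = ivals
            self._starts[chrom] = [s for s, _ in ivals]

    @classmethod
    def from_bed(cls, path: str | Path) -> "TargetIntervals":
        """Read BED (0-based half-open per the standard) into 1-based intervals."""
        intervals = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            start, end = to_one_based(int(fields[1]), int(fields[2]))
            intervals.append((fields[0], start, end))
        return cls(intervals)

    def contains(self, chrom: str, pos: int, extension_bp: int = 0) -> bool:
        """True when ``pos`` is within ``extension_bp`` of a target (inclusive)."""
        ivals = self._by_chrom.get(chrom)
        if not ivals:
            return False
        i = bisect_right(self._starts[chrom], pos + extension_bp)
        for start, end in ivals[max(i - 3, 0) : i][::-1]:
            if start - extension_bp <= pos <= end + extension_bp:
                return True
        return False


def _first_failing_rule(
    v: VariantRecord,
    targets: TargetIntervals | None,
    cfg: FilterConfig,
    vaf_cutoff: float,
) -> str | None:
    if (v.gnomad_af or 0.0) > cfg.max_gnomad_af:
        return "gnomad_af"
    if targets is not None and not targets.contains(v.chrom, v.pos, cfg.target_extension_bp):
        return "target"
    if v.depth < cfg.min_depth:
        return "depth"
    if v.alt_reads < cfg.min_alt_reads:
        return "alt_reads"
    if v.vaf is None or v.vaf < vaf_cutoff:
        return "vaf"
    return None


def filter_somatic(
    variants: list[VariantRecord],
    purity: float,
    targets: TargetIntervals | None,
    cfg: FilterConfig | None = None,
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Apply the purity-adjusted somatic filter; returns (kept, audit counts).

    The audit attributes each removed variant to the first failing rule in
    ``RULE_ORDER``, so ``len(variants) == len(kept) + sum(audit.values())``.
    Input order is preserved.  Passing ``targets=None`` disables the
    target-region rule.
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    cfg = cfg or FilterConfig()
    vaf_cutoff = max(cfg.vaf_floor, cfg.vaf_purity_factor * purity / 2.0)
    kept: list[VariantRecord] = []
    audit = {rule: 0 for rule in RULE_ORDER}
    for v in variants:
        rule = _first_failing_rule(v, targets, cfg, vaf_cutoff)
        if rule is None:
            kept.append(v)
        else:
            audit[rule] += 1
    return kept, audit


def pool_unique_sbs(
    samples: list[tuple[str, list[VariantRecord]]],
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Pool single-base substitutions across tumours, deduplicated on
    (chrom, pos, ref, alt); non-SBS records are dropped and audited.

    The pooled record for a duplicated site is the first occurrence; pooled
    output is sorted by genomic position.
    """
    seen: dict[tuple[str, int, str, str], VariantRecord] = {}
    audit = {"non_sbs": 0}
    for sample_id, variants in samples:
        for v in variants:
            if not v.is_snv:
                audit["non_sbs"] += 1
                continue
            if v.key not in seen:
                rec = replace(v, annotations=dict(v.annotations), filter_flags=set(v.filter_flags))
                rec.annotations.setdefault("pooled_from", sample_id)
                seen[v.key] = rec
    pooled = sorted(seen.values(), key=lambda r: r.key)
    return pooled, audit
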
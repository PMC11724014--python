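"""Forward model linking tumour purity, local copy number and observed VAF.

For a tumour of purity ``p``, a locus with tumour total copy number ``n_t``
carrying ``m_v`` variant copies, and normal cells that are diploid at the
locus, the expected variant allele fraction is

    germline heterozygous variant:  v = (p*m_v + (1-p)*1) / (p*n_t + (1-p)*2)
    somatic variant:                v = (p*m_v)           / (p*n_t + (1-p)*2)

The named hypotheses enumerate the allelic fates of a germline heterozygous
variant of interest: balanced retention (m_v=1, n_t=2), loss of the wildtype
allele by deletion (1, 1) or copy-neutral LOH (2, 2), and loss of the variant
allele (0, n_t).  Inverting the somatic case on a single-copy LOH segment
(m_v = n_t = 1) gives the purity estimator p = 2v / (1 + v).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import Segment, VariantRecord

__all__ = [
    "PurityEstimate",
    "VafHypothesis",
    "GERMLINE_HYPOTHESES",
    "hypotheses_for_segment",
    "expected_vaf",
    "purity_from_somatic_vaf",
    "consensus_purity",
    "PURITY_FLOOR",
]

#: Minimum purity accepted for downstream allelic-status work (tumours were
#: dissected to >= 30% tumour-cell content).
PURITY_FLOOR = 0.3

ESTIMATOR_METHODS = frozenset({"cn_fit", "visual_cn", "somatic_vaf", "consensus"})


@dataclass(frozen=True)
class VafHypothesis:
    """A candidate allelic state: ``m_v`` variant copies of ``n_t`` total."""

    label: str
    m_v: int
    n_t: int
    germline: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.m_v <= self.n_t:
            raise ValueError(f"require 0 <= m_v <= n_t, got ({self.m_v}, {self.n_t})")


def germline_hypotheses(variant_lost_total_cn: int = 1) -> tuple[VafHypothesis, ...]:
    return (
        VafHypothesis("balanced_het", 1, 2),
        VafHypothesis("wt_lost_deletion", 1, 1),
        VafHypothesis("wt_lost_cnloh", 2, 2),
        VafHypothesis("variant_lost", 0, max(variant_lost_total_cn, 0) or 1),
    )


GERMLINE_HYPOTHESES = germline_hypotheses()


def hypotheses_for_segment(segment: Segment) -> dict[str, tuple[VafHypothesis, bool]]:
    """The four germline hypotheses plus a copy-number compatibility flag.

    ``variant_lost`` adopts the segment's total copy number when the segment
    shows LOH; hypotheses whose implied (total, minor) state contradicts the
    segment are flagged incompatible but still returned for scoring.
    """
    total, minor = segment.total_cn, segment.minor_cn
    out: dict[str, tuple[VafHypothesis, bool]] = {}
    out["balanced_het"] = (VafHypothesis("balanced_het", 1, 2), total == 2 and minor == 1)
    out["wt_lost_deletion"] = (VafHypothesis("wt_lost_deletion", 1, 1), total == 1 and minor == 0)
    out["wt_lost_cnloh"] = (VafHypothesis("wt_lost_cnloh", 2, 2), total == 2 and minor == 0)
    vl_total = total if (minor == 0 and total >= 1) else 2
    out["variant_lost"] = (VafHypothesis("variant_lost", 0, vl_total), minor == 0 and total >= 1)
    return out


def expected_vaf(hypothesis: VafHypothesis, purity: float) -> float:
    """Expected VAF of a variant under ``hypothesis`` at tumour purity ``purity``."""
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    p, m, n = purity, hypothesis.m_v, hypothesis.n_t
    denom = p * n + (1.0 - p) * 2.0
    num = p * m + ((1.0 - p) * 1.0 if hypothesis.germline else 0.0)
    return num / denom


@dataclass
class PurityEstimate:
    value: float
    method: str
    n_support: int = 1
    detail: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.value <= 1.0:
            raise ValueError(f"purity estimate must be in (0, 1], got {self.value}")
        if self.method not in ESTIMATOR_METHODS:
            raise ValueError(f"unknown purity method {self.method!r}")


def purity_from_somatic_vaf(
    observations: list[VariantRecord],
    profile=None,
) -> PurityEstimate:
    """Purity from somatic variants sitting on single-copy LOH segments.

    Each observation inverts the somatic forward model at m_v = n_t = 1,
    p_i = 2 v_i / (1 + v_i); the estimate is their depth-weighted mean,
    clipped into (0, 1].  When a segment ``profile`` is supplied, every
    observation is checked to lie on a (total_cn=1, minor_cn=0) segment.
    """
    informative = [v for v in observations if v.depth > 0]
    if not informative:
        raise ValueError("no informative variants")
    if profile is not None:
        for v in informative:
            seg = profile.segment_at(v.chrom, v.pos)
            if seg is None or seg.total_cn != 1 or seg.minor_cn != 0:
                raise ValueError(
                    f"variant {v.chrom}:{v.pos} is not on a single-copy LOH segment"
                )
    vafs = np.array([v.vaf for v in informative])
    depths = np.array([v.depth for v in informative], dtype=float)
    per_variant = 2.0 * vafs / (1.0 + vafs)
    value = float(np.average(per_variant, weights=depths))
    value = float(np.clip(value, 1e-9, 1.0))
    return PurityEstimate(
        value=value,
        method="somatic_vaf",
        n_support=len(informative),
        detail=f"depth-weighted mean over {len(informative)} variants",
    )


def consensus_purity(estimates: list[PurityEstimate]) -> PurityEstimate:
    """Unweighted arithmetic mean of the available estimator values."""
    if not estimates:
        raise ValueError("no purity estimates to combine")
    value = float(np.mean([e.value for e in estimates]))
    return PurityEstimate(
        value=value,
        method="consensus",
        n_support=len(estimates),
        detail="; ".join(f"{e.method}={e.value:.3f}" for e in estimates),
    )
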
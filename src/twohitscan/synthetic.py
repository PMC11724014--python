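"""Synthetic cohorts, tumours and catalogues with known ground truth.

The tumour generator emulates the study regime this pipeline targets:
exome-like mean depth 90x, tumour purity down to 0.3 (the dissection floor),
a germline heterozygous variant of interest with a planted allelic fate, and
a few dozen clonal somatic SNVs.  Tumour genomes are miniature: three 100 Mb
autosomes with a 40-42 Mb centromere — large enough to host the >15 Mb and
>=10 Mb scar events the HRD counters look for, small enough for fast tests.

Scar events are planted in fixed, well-separated slots so each planted event
is counted exactly once and never bleeds into another counter: interstitial
20 Mb single-copy LOH blocks, telomeric 20 Mb (3,1) imbalances, and chains of
12 Mb alternating-state segments for LSTs, each insulated by 5 Mb buffer
segments too short to trigger the >=10 Mb flank rule.  Capacity per tumour:
loh <= 2, tai <= 2, lst <= 3.

Read counts are binomial given the purity-adjusted expected VAF (no
overdispersion); site depths are Poisson around the mean except for the
purity-informative variants, which use the exact nominal depth.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import (
    ArmDefinition,
    ChromosomeArms,
    MethylationCall,
    MutationalCatalog,
    Segment,
    SegmentProfile,
    SignatureSet,
    TumorSample,
    VariantRecord,
)
from .purity import VafHypothesis, expected_vaf

__all__ = [
    "TruthRecord",
    "default_arms",
    "gen_cohort",
    "gen_tumor",
    "gen_catalog",
    "GENE_OF_INTEREST",
    "MAX_SCARS",
]

GENE_OF_INTEREST = "GENE1"
MAX_SCARS = (2, 2, 3)  # (loh, tai, lst) slot capacity per tumour

_MB = 1_000_000
_CHROMS = ("chr1", "chr2", "chr3")
_BG = (2, 1)  # diploid balanced background state


@dataclass
class TruthRecord:
    """Planted ground truth accompanying a generated object."""

    purity: float | None = None
    gene_fate: str | None = None
    scar_counts: tuple[int, int, int] | None = None
    exposures_true: tuple[float, ...] | None = None
    cohort_or_true: dict | None = None


def default_arms() -> ChromosomeArms:
    """Arm definitions for the miniature 3 x 100 Mb genome."""
    arm = ArmDefinition(
        chrom_start=1,
        centromere_start=40 * _MB,
        centromere_end=42 * _MB,
        chrom_end=100 * _MB,
    )
    return ChromosomeArms({c: arm for c in _CHROMS})


# --------------------------------------------------------------------------
# cohorts


def gen_cohort(
    n_cases: int,
    n_controls: int,
    genes: list[str],
    base_carrier_freq: float,
    or_per_gene: dict[str, float] | float,
    seed: int | None = None,
) -> tuple[dict[str, int], dict[str, int], TruthRecord]:
    """Simulate per-gene LoF allele counts for a case and a control cohort.

    Control alleles carry the variant with probability ``base_carrier_freq``;
    case alleles with the frequency whose odds are multiplied by the gene's
    odds ratio.  Returns (case counts, control counts, truth).
    """
    if not 0.0 <= base_carrier_freq < 1.0:
        raise ValueError("base_carrier_freq must be in [0, 1)")
    rng = np.random.default_rng(seed)
    ors = (
        {g: float(or_per_gene) for g in genes}
        if np.isscalar(or_per_gene)
        else dict(or_per_gene)
    )
    case_counts: dict[str, int] = {}
    control_counts: dict[str, int] = {}
    for gene in genes:
        odds_ratio = ors[gene]
        if odds_ratio <= 0:
            raise ValueError(f"odds ratio for {gene} must be > 0")
        if base_carrier_freq * odds_ratio >= 1.0:
            raise ValueError(f"case frequency for {gene} would exceed 1")
        odds = base_carrier_freq / (1.0 - base_carrier_freq) * odds_ratio
        f_case = odds / (1.0 + odds)
        control_counts[gene] = int(rng.binomial(2 * n_controls, base_carrier_freq))
        case_counts[gene] = int(rng.binomial(2 * n_cases, f_case))
    truth = TruthRecord(cohort_or_true=ors)
    return case_counts, control_counts, truth


# --------------------------------------------------------------------------
# tumours

_FATE_STATES = {
    # fate -> (gene segment (total, minor), variant copies m_v)
    ("WT_LOST", "deletion"): ((1, 0), 1),
    ("WT_LOST", "cnloh"): ((2, 0), 2),
    ("VARIANT_LOST", "deletion"): ((1, 0), 0),
    ("HETEROZYGOUS", "none"): ((2, 1), 1),
}


def _fate_plan(gene_fate: str, mechanism: str | None) -> tuple[tuple[int, int], int]:
    if gene_fate == "HETEROZYGOUS":
        return _FATE_STATES[("HETEROZYGOUS", "none")]
    if gene_fate == "WT_LOST":
        return _FATE_STATES[("WT_LOST", mechanism or "deletion")]
    if gene_fate == "VARIANT_LOST":
        return _FATE_STATES[("VARIANT_LOST", "deletion")]
    raise ValueError(
        f"unknown gene fate {gene_fate!r}; "
        "expected WT_LOST, VARIANT_LOST or HETEROZYGOUS"
    )


def _seg(chrom: str, start_mb: float, end_mb: float, state: tuple[int, int]) -> Segment:
    # slots are expressed in Mb; adjacent slots share a boundary (start = prev end + 1)
    return Segment(
        chrom=chrom,
        start=int(start_mb * _MB) + 1,
        end=int(end_mb * _MB),
        total_cn=state[0],
        minor_cn=state[1],
    )


def _build_profile(
    gene_state: tuple[int, int], scar_spec: tuple[int, int, int]
) -> list[Segment]:
    n_loh, n_tai, n_lst = scar_spec
    segs: list[Segment] = []

    # chr1 p arm: insulated gene-of-interest segment
    segs += [
        _seg("chr1", 0, 5, _BG),
        _seg("chr1", 5, 10, (3, 1)),
        _seg("chr1", 10, 20, gene_state),
        _seg("chr1", 20, 25, (3, 1)),
        _seg("chr1", 25, 40, _BG),
    ]
    # chr1 q arm: LST chain of n_lst + 1 alternating 12 Mb segments
    if n_lst > 0:
        segs.append(_seg("chr1", 42, 47, (5, 2)))
        pos = 47
        states = [_BG, (4, 2)]
        for i in range(n_lst + 1):
            segs.append(_seg("chr1", pos, pos + 12, states[i % 2]))
            pos += 12
        segs.append(_seg("chr1", pos, pos + 5, (5, 2)))
        pos += 5
        if pos < 100:
            segs.append(_seg("chr1", pos, 100, _BG))
    else:
        segs.append(_seg("chr1", 42, 100, _BG))

    # chr2 p arm: TAI slot 1; q arm: LOH slot 1
    if n_tai >= 1:
        segs += [
            _seg("chr2", 0, 20, (3, 1)),
            _seg("chr2", 20, 25, (2, 0)),
            _seg("chr2", 25, 40, _BG),
        ]
    else:
        segs.append(_seg("chr2", 0, 40, _BG))
    if n_loh >= 1:
        segs += [
            _seg("chr2", 42, 55, _BG),
            _seg("chr2", 55, 60, (3, 1)),
            _seg("chr2", 60, 80, (1, 0)),
            _seg("chr2", 80, 85, (3, 1)),
            _seg("chr2", 85, 100, _BG),
        ]
    else:
        segs.append(_seg("chr2", 42, 100, _BG))

    # chr3 p arm: TAI slot 2 + the purity-informative single-copy LOH segment
    if n_tai >= 2:
        segs += [_seg("chr3", 0, 20, (3, 1)), _seg("chr3", 20, 25, (2, 0))]
    else:
        segs += [_seg("chr3", 0, 20, _BG), _seg("chr3", 20, 25, (3, 1))]
    segs += [_seg("chr3", 25, 35, (1, 0)), _seg("chr3", 35, 40, (3, 1))]
    # chr3 q arm: LOH slot 2
    if n_loh >= 2:
        segs += [
            _seg("chr3", 42, 55, _BG),
            _seg("chr3", 55, 60, (3, 1)),
            _seg("chr3", 60, 80, (1, 0)),
            _seg("chr3", 80, 85, (3, 1)),
            _seg("chr3", 85, 100, _BG),
        ]
    else:
        segs.append(_seg("chr3", 42, 100, _BG))
    return segs


_PURITY_SEGMENT = ("chr3", 25 * _MB + 1, 35 * _MB)
_BASES = "ACGT"


def _random_snv(rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[rng.integers(4)]
    alt = ref
    while alt == ref:
        alt = _BASES[rng.integers(4)]
    return ref, alt


def gen_tumor(
    purity: float,
    depth_mean: float = 90.0,
    gene_fate: str = "WT_LOST",
    scar_spec: tuple[int, int, int] = (0, 0, 0),
    n_somatic: int = 68,
    seed: int | None = None,
    mechanism: str | None = None,
    gene_state: tuple[int, int] | None = None,
    n_purity_informative: int = 5,
    somatic_second_hit: bool = False,
    methylation_status: tuple[str, str] | None = None,
    sample_id: str | None = None,
) -> tuple[TumorSample, TruthRecord]:
    """Generate one tumour with a planted allelic fate and scar counts.

    Returns a :class:`TumorSample` (segment profile, germline variant of
    interest, somatic variants, optional methylation call) and the matching
    :class:`TruthRecord`.  Deterministic for a fixed ``seed``.
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if any(s < 0 for s in scar_spec) or any(
        s > cap for s, cap in zip(scar_spec, MAX_SCARS)
    ):
        raise ValueError(f"scar_spec {scar_spec} outside slot capacity {MAX_SCARS}")
    planned_state, m_v = _fate_plan(gene_fate, mechanism)
    if gene_state is not None and gene_state != planned_state:
        raise ValueError(
            f"gene fate {gene_fate} is inconsistent with forced segment state "
            f"{gene_state} (expected {planned_state})"
        )
    rng = np.random.default_rng(seed)
    sample_id = sample_id or f"SIM-{seed if seed is not None else 'X'}"

    segments = _build_profile(planned_state, scar_spec)
    profile = SegmentProfile(sample_id=sample_id, segments=segments, genome_build="mini3")

    # germline heterozygous variant of interest
    gene_hyp = VafHypothesis("planted", m_v, planned_state[0], germline=True)
    v_exp = expected_vaf(gene_hyp, purity)
    g_depth = max(int(rng.poisson(depth_mean)), 1)
    g_alt = int(rng.binomial(g_depth, v_exp))
    germline_variant = VariantRecord(
        chrom="chr1",
        pos=15 * _MB,
        ref="C",
        alt="T",
        gene=GENE_OF_INTEREST,
        consequence="stop_gain",
        origin="germline",
        alt_reads=g_alt,
        ref_reads=g_depth - g_alt,
        annotations={"genotype": "het"},
    )

    somatic: list[VariantRecord] = []
    # purity-informative somatic variants on the (1,0) segment (TP53-like)
    chrom_p, start_p, end_p = _PURITY_SEGMENT
    v_inf = expected_vaf(VafHypothesis("clonal_loh", 1, 1, germline=False), purity)
    depth_inf = max(int(round(depth_mean)), 1)
    positions = np.linspace(start_p + _MB, end_p - _MB, max(n_purity_informative, 1)).astype(int)
    for i in range(n_purity_informative):
        ref, alt = _random_snv(rng)
        alt_reads = int(rng.binomial(depth_inf, v_inf))
        somatic.append(
            VariantRecord(
                chrom=chrom_p,
                pos=int(positions[i]),
                ref=ref,
                alt=alt,
                gene="TP53",
                consequence="missense",
                origin="somatic",
                alt_reads=alt_reads,
                ref_reads=depth_inf - alt_reads,
            )
        )

    # clonal somatic passengers on balanced background segments
    bg_segments = [s for s in segments if s.state == _BG]
    v_clonal = expected_vaf(VafHypothesis("clonal_het", 1, 2, germline=False), purity)
    lengths = np.array([s.length for s in bg_segments], dtype=float)
    seg_choice = rng.choice(len(bg_segments), size=n_somatic, p=lengths / lengths.sum())
    for si in seg_choice:
        seg = bg_segments[si]
        pos = int(rng.integers(seg.start, seg.end + 1))
        ref, alt = _random_snv(rng)
        depth = max(int(rng.poisson(depth_mean)), 1)
        alt_reads = int(rng.binomial(depth, v_clonal))
        somatic.append(
            VariantRecord(
                chrom=seg.chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                consequence="other",
                origin="somatic",
                alt_reads=alt_reads,
                ref_reads=depth - alt_reads,
            )
        )

    if somatic_second_hit:
        # somatic truncating hit in the remaining allele of the gene of interest
        hit_exp = expected_vaf(
            VafHypothesis("hit", 1, planned_state[0], germline=False), purity
        )
        depth = max(int(rng.poisson(depth_mean)), 1)
        alt_reads = int(rng.binomial(depth, hit_exp))
        somatic.append(
            VariantRecord(
                chrom="chr1",
                pos=15 * _MB + 500_000,
                ref="G",
                alt="T",
                gene=GENE_OF_INTEREST,
                consequence="stop_gain",
                origin="somatic",
                alt_reads=alt_reads,
                ref_reads=depth - alt_reads,
            )
        )

    methylation = []
    if methylation_status is not None:
        status, allele = methylation_status
        methylation.append(
            MethylationCall(
                sample_id=sample_id,
                gene=GENE_OF_INTEREST,
                status=status,
                methylated_allele=allele,
            )
        )

    sample = TumorSample(
        sample_id=sample_id,
        profile=profile,
        germline_variant=germline_variant,
        somatic_variants=somatic,
        methylation=methylation,
        purity=purity,
    )
    truth = TruthRecord(purity=purity, gene_fate=gene_fate, scar_counts=tuple(scar_spec))
    return sample, truth


# --------------------------------------------------------------------------
# catalogues


def gen_catalog(
    signatures: SignatureSet,
    proportions,
    n_mutations: int,
    seed: int | None = None,
    label: str = "synthetic",
) -> tuple[MutationalCatalog, TruthRecord]:
    """Multinomial SBS96 catalogue from a known signature mixture."""
    proportions = np.asarray(proportions, dtype=float)
    if proportions.shape != (signatures.n_signatures,):
        raise ValueError("one proportion per signature required")
    if (proportions < 0).any() or abs(proportions.sum() - 1.0) > 1e-6:
        raise ValueError("proportions must be non-negative and sum to 1")
    if n_mutations < 0:
        raise ValueError("n_mutations must be >= 0")
    rng = np.random.default_rng(seed)
    probs = signatures.matrix @ proportions
    probs = probs / probs.sum()
    counts = (
        rng.multinomial(n_mutations, probs) if n_mutations > 0 else np.zeros(96, dtype=int)
    )
    return (
        MutationalCatalog(counts=counts, label=label),
        TruthRecord(exposures_true=tuple(proportions)),
    )
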
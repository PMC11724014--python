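"""Two-hit (biallelic inactivation) classification for a gene of interest.

The germline variant's tumour VAF is compared against the purity-adjusted
expectation under each allelic hypothesis with a binomial read-count
likelihood.  The winning hypothesis must (i) be compatible with the local
allele-specific copy-number state and (ii) beat the runner-up by a Bayes
factor of at least ``bf_min``; otherwise the call is AMBIGUOUS (such cases
were resolved orthogonally in practice, modelled here as an override input).
Somatic second hits and promoter-methylation calls then refine the verdict
into the full call vocabulary.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from scipy.stats import binom

from .io_formats import (
    LOF_CONSEQUENCES,
    MethylationCall,
    Segment,
    VariantRecord,
)
from .purity import expected_vaf, hypotheses_for_segment

__all__ = [
    "CATEGORIES",
    "CATEGORY_STRINGS",
    "StatusConfig",
    "AllelicStatusCall",
    "GeneSummary",
    "score_hypotheses",
    "classify_allelic_status",
    "summarize_gene",
    "is_biallelic",
]

CATEGORIES = (
    "WT_LOST",
    "VARIANT_LOST",
    "HETEROZYGOUS",
    "HET_WITH_SOMATIC_HIT_PHASE_UNKNOWN",
    "WT_LOST_BY_SOMATIC_HIT",
    "VARIANT_LOST_WT_METHYLATED",
    "HET_WT_METHYLATED",
    "HET_ONE_ALLELE_METHYLATED",
    "AMBIGUOUS",
)

#: Human-readable call vocabulary used in reports.
CATEGORY_STRINGS = {
    "WT_LOST": "WT lost",
    "VARIANT_LOST": "Variant lost",
    "HETEROZYGOUS": "Heterozygous",
    "HET_WITH_SOMATIC_HIT_PHASE_UNKNOWN": "Heterozygous with 2nd hit (phase unknown)",
    "WT_LOST_BY_SOMATIC_HIT": "Variant lost with 2nd hit in WT allele",
    "VARIANT_LOST_WT_METHYLATED": "Variant lost with promoter methylation of WT allele",
    "HET_WT_METHYLATED": "Heterozygous with promoter methylation of WT allele",
    "HET_ONE_ALLELE_METHYLATED": "Heterozygous with promoter methylation of one allele",
    "AMBIGUOUS": "Ambiguous",
}

_BIALLELIC_ALWAYS = {
    "WT_LOST",
    "WT_LOST_BY_SOMATIC_HIT",
    "VARIANT_LOST_WT_METHYLATED",
    "HET_WT_METHYLATED",
}


@dataclass
class StatusConfig:
    """Decision thresholds for the allelic-status classifier.

    ``log_bf_min`` is the natural-log Bayes-factor margin the best hypothesis
    must hold over the runner-up (default 2, i.e. BF >= e^2 ~ 7.4).  A somatic
    missense counts as a second hit only when predicted deleterious by both
    CADD (phred >= ``cadd_min``) and REVEL (>= ``revel_min``).
    """

    log_bf_min: float = 2.0
    cadd_min: float = 20.0
    revel_min: float = 0.5
    phase_unknown_biallelic: bool = True


def is_biallelic(category: str, cfg: StatusConfig | None = None) -> bool:
    cfg = cfg or StatusConfig()
    if category in _BIALLELIC_ALWAYS:
        return True
    if category == "HET_WITH_SOMATIC_HIT_PHASE_UNKNOWN":
        return cfg.phase_unknown_biallelic
    return False


@dataclass
class AllelicStatusCall:
    sample_id: str
    gene: str
    category: str
    biallelic: bool
    loglik: dict = field(default_factory=dict)
    expected_vafs: dict = field(default_factory=dict)
    segment_used: Segment | None = None
    somatic_hits: list = field(default_factory=list)
    methylation: MethylationCall | None = None

    def as_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "gene": self.gene,
            "category": self.category,
            "call": CATEGORY_STRINGS[self.category],
            "biallelic": self.biallelic,
            "loglik": self.loglik,
            "expected_vafs": self.expected_vafs,
            "n_somatic_hits": len(self.somatic_hits),
        }


def score_hypotheses(
    germline_obs: VariantRecord, segment: Segment, purity: float
) -> tuple[dict[str, float], dict[str, float], dict[str, bool]]:
    """Binomial log-likelihood and expected VAF per allelic hypothesis.

    Returns (loglik, expected_vafs, cn_compatible).  Hypotheses whose implied
    copy-number state contradicts the segment are flagged incompatible but
    still scored.
    """
    depth = germline_obs.depth
    if depth == 0:
        raise ValueError(
            f"zero depth for germline variant {germline_obs.chrom}:{germline_obs.pos}"
        )
    hypotheses = hypotheses_for_segment(segment)
    loglik: dict[str, float] = {}
    expected: dict[str, float] = {}
    compatible: dict[str, bool] = {}
    for label, (hyp, compat) in hypotheses.items():
        v = expected_vaf(hyp, purity)
        v = min(max(v, 1e-9), 1.0 - 1e-9)
        expected[label] = expected_vaf(hyp, purity)
        loglik[label] = float(binom.logpmf(germline_obs.alt_reads, depth, v))
        compatible[label] = compat
    return loglik, expected, compatible


_HYPOTHESIS_CATEGORY = {
    "balanced_het": "HETEROZYGOUS",
    "wt_lost_deletion": "WT_LOST",
    "wt_lost_cnloh": "WT_LOST",
    "variant_lost": "VARIANT_LOST",
}


def _qualifies_as_hit(v: VariantRecord, cfg: StatusConfig) -> bool:
    if v.origin != "somatic":
        return False
    if v.consequence in LOF_CONSEQUENCES:
        return True
    if v.consequence == "missense":
        cadd = v.annotations.get("cadd_phred")
        revel = v.annotations.get("revel")
        return (
            cadd is not None
            and revel is not None
            and float(cadd) >= cfg.cadd_min
            and float(revel) >= cfg.revel_min
        )
    return False


def _wt_allele_methylated(m: MethylationCall) -> bool:
    return m.status == "homozygous_methylated" or (
        m.status == "heterozygous_methylated" and m.methylated_allele == "wildtype"
    )


def classify_allelic_status(
    germline_obs: VariantRecord,
    segment: Segment,
    purity: float,
    somatic_hits: list[VariantRecord] | None = None,
    methylation: MethylationCall | None = None,
    cfg: StatusConfig | None = None,
    sample_id: str = "",
    override_category: str | None = None,
) -> AllelicStatusCall:
    """Classify the two-hit status of the gene of interest in one tumour.

    ``override_category`` models an orthogonal adjudication (e.g. targeted
    re-sequencing) and replaces an AMBIGUOUS verdict only.
    """
    cfg = cfg or StatusConfig()
    loglik, expected, compatible = score_hypotheses(germline_obs, segment, purity)
    hits = [v for v in (somatic_hits or []) if _qualifies_as_hit(v, cfg)]

    candidates = [h for h in loglik if compatible[h]]
    if not candidates:
        category = "AMBIGUOUS"
    else:
        ordered = sorted(candidates, key=lambda h: loglik[h], reverse=True)
        best = ordered[0]
        if len(ordered) > 1 and loglik[best] - loglik[ordered[1]] < cfg.log_bf_min:
            category = "AMBIGUOUS"
        else:
            category = _HYPOTHESIS_CATEGORY[best]

    # LOH verdicts additionally need the segment itself to corroborate LOH.
    if category in {"WT_LOST", "VARIANT_LOST"} and segment.minor_cn != 0:
        category = "AMBIGUOUS"

    if category == "AMBIGUOUS" and override_category is not None:
        if override_category not in CATEGORIES:
            raise ValueError(f"unknown override category {override_category!r}")
        category = override_category

    if category == "VARIANT_LOST":
        if methylation is not None and _wt_allele_methylated(methylation):
            category = "VARIANT_LOST_WT_METHYLATED"
        elif hits:
            category = "WT_LOST_BY_SOMATIC_HIT"
    elif category == "HETEROZYGOUS":
        if hits:
            category = "HET_WITH_SOMATIC_HIT_PHASE_UNKNOWN"
        elif methylation is not None:
            if _wt_allele_methylated(methylation):
                category = "HET_WT_METHYLATED"
            elif methylation.status == "heterozygous_methylated":
                category = "HET_ONE_ALLELE_METHYLATED"

    return AllelicStatusCall(
        sample_id=sample_id,
        gene=germline_obs.gene,
        category=category,
        biallelic=is_biallelic(category, cfg),
        loglik=loglik,
        expected_vafs=expected,
        segment_used=segment,
        somatic_hits=hits,
        methylation=methylation,
    )


_WT_LOST_BUCKET = {"WT_LOST", "WT_LOST_BY_SOMATIC_HIT"}
_VARIANT_LOST_BUCKET = {"VARIANT_LOST", "VARIANT_LOST_WT_METHYLATED"}


@dataclass
class GeneSummary:
    gene: str
    n_tumours: int
    n_biallelic: int
    n_wt_lost: int
    n_variant_lost: int
    n_het: int
    pattern: str


def summarize_gene(calls: list[AllelicStatusCall]) -> GeneSummary:
    """Aggregate per-tumour calls for one gene into its inactivation pattern.

    ``consistent_biallelic`` requires biallelic inactivation in every tumour;
    ``variant_loss_observed`` flags any unrescued loss of the variant allele
    (evidence against a two-hit role); ``heterozygous_only`` means no tumour
    shows either; anything else is ``partial``.
    """
    if not calls:
        raise ValueError("no calls to summarise")
    genes = {c.gene for c in calls}
    if len(genes) > 1:
        raise ValueError(f"calls span multiple genes {sorted(genes)}")
    n = len(calls)
    n_biallelic = sum(c.biallelic for c in calls)
    n_wt = sum(c.category in _WT_LOST_BUCKET for c in calls)
    n_vl = sum(c.category in _VARIANT_LOST_BUCKET for c in calls)
    n_het = n - n_wt - n_vl

    if n_biallelic == n:
        pattern = "consistent_biallelic"
    elif any(c.category == "VARIANT_LOST" for c in calls):
        pattern = "variant_loss_observed"
    elif n_biallelic == 0 and n_wt == 0 and n_vl == 0:
        pattern = "heterozygous_only"
    else:
        pattern = "partial"
    return GeneSummary(
        gene=calls[0].gene,
        n_tumours=n,
        n_biallelic=n_biallelic,
        n_wt_lost=n_wt,
        n_variant_lost=n_vl,
        n_het=n_het,
        pattern=pattern,
    )
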
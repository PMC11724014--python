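"""Per-gene rare-LoF allele counting and case-control enrichment statistics.

The test is the one-sided Fisher exact test in the enrichment direction: the
p-value is the upper tail of the central hypergeometric distribution,
P(X >= a_case) with the table margins fixed.  The point estimate is the
unconditional cross-product odds ratio

    OR = a_case * (N_ctrl - a_ctrl) / ((N_case - a_case) * a_ctrl)

and the confidence interval is the conditional exact interval obtained by
inverting the Fisher noncentral hypergeometric tail probabilities (the
interval R's ``fisher.test`` reports).  Allele denominators are 2 per
individual for autosomes in female cohorts.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import hypergeom, nchypergeom_fisher

from .io_formats import CONSEQUENCES, LOF_CONSEQUENCES, VariantRecord

__all__ = [
    "GeneBurdenRecord",
    "EnrichmentResult",
    "count_lof_alleles",
    "fisher_enrichment",
    "combine_cohorts",
    "rank_genes",
    "load_packaged_counts",
    "enrichment_table",
]


@dataclass
class GeneBurdenRecord:
    """LoF allele count ``a`` out of ``N`` total alleles for one gene/cohort."""

    gene: str
    cohort: str
    lof_alleles: int
    total_alleles: int

    def __post_init__(self) -> None:
        if self.total_alleles <= 0:
            raise ValueError("total_alleles must be positive")
        if not 0 <= self.lof_alleles <= self.total_alleles:
            raise ValueError("lof_alleles must lie in [0, total_alleles]")

    @property
    def af_percent(self) -> float:
        return 100.0 * self.lof_alleles / self.total_alleles


@dataclass
class EnrichmentResult:
    gene: str
    case_record: GeneBurdenRecord
    control_record: GeneBurdenRecord
    odds_ratio: float | None
    ci_low: float
    ci_high: float
    p_one_sided: float
    rank: int | None = None


def count_lof_alleles(
    variants: list[VariantRecord],
    gene: str,
    cohort: str,
    n_individuals: int | None,
    af_threshold: float = 0.005,
    lof_classes: frozenset = LOF_CONSEQUENCES,
    alleles_per_individual: int = 2,
) -> GeneBurdenRecord:
    """Count rare LoF alleles for one gene in one cohort.

    Each qualifying heterozygous carrier contributes one allele; a carrier
    annotated ``genotype == "hom"`` contributes two.  A variant qualifies when
    its gene matches, its consequence is in ``lof_classes`` and its population
    AF is at or below ``af_threshold`` (a missing AF counts as rare).
    """
    if n_individuals is None or n_individuals <= 0:
        raise ValueError("cohort size (n_individuals) is required")
    unknown = {v.consequence for v in variants} - CONSEQUENCES
    if unknown:
        raise ValueError(
            f"unknown consequence classes {sorted(unknown)}; "
            f"legal values: {sorted(CONSEQUENCES)}"
        )
    a = 0
    for v in variants:
        if v.gene != gene or v.consequence not in lof_classes:
            continue
        if v.gnomad_af is not None and v.gnomad_af > af_threshold:
            continue
        a += 2 if v.annotations.get("genotype") == "hom" else 1
    return GeneBurdenRecord(
        gene=gene,
        cohort=cohort,
        lof_alleles=a,
        total_alleles=alleles_per_individual * n_individuals,
    )


def one_sided_p(a_case, n_case: int, a_ctrl: int, n_ctrl: int):
    """Exact hypergeometric upper-tail P(X >= a_case) with margins fixed.

    ``a_case`` may be an array (vectorised over the observed case count).
    """
    total = n_case + n_ctrl
    k = np.asarray(a_case) + a_ctrl
    return hypergeom.sf(np.asarray(a_case) - 1, total, k, n_case)


def _conditional_exact_ci(
    a: int, n_case: int, b: int, n_ctrl: int, alpha: float
) -> tuple[float, float]:
    total, k, draws = n_case + n_ctrl, a + b, n_case
    lo_support = max(0, k - n_ctrl)
    hi_support = min(k, n_case)

    def sf_at(log_odds: float) -> float:  # P(X >= a | odds)
        return nchypergeom_fisher.sf(a - 1, total, k, draws, np.exp(log_odds))

    def cdf_at(log_odds: float) -> float:  # P(X <= a | odds)
        return nchypergeom_fisher.cdf(a, total, k, draws, np.exp(log_odds))

    if a == lo_support:
        lo = 0.0
    else:
        lo = float(np.exp(brentq(lambda lg: sf_at(lg) - alpha / 2, -50.0, 50.0)))
    if a == hi_support:
        hi = float("inf")
    else:
        hi = float(np.exp(brentq(lambda lg: cdf_at(lg) - alpha / 2, -50.0, 50.0)))
    return lo, hi


def fisher_enrichment(
    a_case: int,
    n_case: int,
    a_ctrl: int,
    n_ctrl: int,
    gene: str = "",
    case_cohort: str = "case",
    control_cohort: str = "control",
    alternative: str = "greater",
    compute_ci: bool = True,
    alpha: float = 0.05,
    haldane: bool = False,
) -> EnrichmentResult:
    """Fisher exact enrichment of LoF alleles in cases versus controls.

    A zero cell leaves the odds ratio undefined (``None``) unless ``haldane``
    adds 0.5 to every cell of the 2x2 table for the point estimate.
    """
    if min(a_case, n_case, a_ctrl, n_ctrl) < 0:
        raise ValueError("counts must be non-negative")
    if a_case > n_case or a_ctrl > n_ctrl:
        raise ValueError("allele count exceeds allele total")

    if alternative == "greater":
        p = float(one_sided_p(a_case, n_case, a_ctrl, n_ctrl))
    elif alternative == "two-sided":
        total, k = n_case + n_ctrl, a_case + a_ctrl
        support = np.arange(max(0, k - n_ctrl), min(k, n_case) + 1)
        pmf = hypergeom.pmf(support, total, k, n_case)
        obs = hypergeom.pmf(a_case, total, k, n_case)
        p = float(pmf[pmf <= obs * (1 + 1e-9)].sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = min(p, 1.0)

    num = a_case * (n_ctrl - a_ctrl)
    den = (n_case - a_case) * a_ctrl
    if den > 0 and num >= 0:
        odds_ratio: float | None = num / den
    elif haldane:
        odds_ratio = ((a_case + 0.5) * (n_ctrl - a_ctrl + 0.5)) / (
            (n_case - a_case + 0.5) * (a_ctrl + 0.5)
        )
    else:
        odds_ratio = None

    if compute_ci and (a_case + a_ctrl) > 0:
        ci_low, ci_high = _conditional_exact_ci(a_case, n_case, a_ctrl, n_ctrl, alpha)
    else:
        ci_low, ci_high = 0.0, float("inf")

    return EnrichmentResult(
        gene=gene,
        case_record=GeneBurdenRecord(gene, case_cohort, a_case, n_case),
        control_record=GeneBurdenRecord(gene, control_cohort, a_ctrl, n_ctrl),
        odds_ratio=odds_ratio,
        ci_low=ci_low,
        ci_high=ci_high,
        p_one_sided=p,
    )


def combine_cohorts(records: list[GeneBurdenRecord]) -> GeneBurdenRecord:
    """Pool disjoint control cohorts for one gene by summing counts."""
    if not records:
        raise ValueError("no records to combine")
    genes = {r.gene for r in records}
    if len(genes) > 1:
        raise ValueError(f"cannot combine records across genes {sorted(genes)}")
    cohorts = [r.cohort for r in records]
    if len(set(cohorts)) != len(cohorts):
        raise ValueError("cohorts must be disjoint (duplicate cohort name)")
    return GeneBurdenRecord(
        gene=records[0].gene,
        cohort="+".join(cohorts),
        lof_alleles=sum(r.lof_alleles for r in records),
        total_alleles=sum(r.total_alleles for r in records),
    )


def rank_genes(
    results: list[EnrichmentResult],
    group_labels: dict[str, str] | None = None,
) -> list[EnrichmentResult]:
    """Assign ranks within each group: 1 = smallest p-value.

    Ties are broken by descending odds ratio (undefined sorting last) and then
    gene symbol, so the ranking is a deterministic permutation of 1..n per
    group regardless of input order.
    """
    genes = [r.gene for r in results]
    if len(set(genes)) != len(genes):
        raise ValueError("one result per gene required")
    groups: dict[str, list[EnrichmentResult]] = {}
    for r in results:
        label = group_labels.get(r.gene, "") if group_labels else ""
        groups.setdefault(label, []).append(r)
    ranked: list[EnrichmentResult] = []
    for members in groups.values():
        members = sorted(
            members,
            key=lambda r: (
                r.p_one_sided,
                -(r.odds_ratio if r.odds_ratio is not None else -np.inf),
                r.gene,
            ),
        )
        for i, r in enumerate(members, start=1):
            r.rank = i
            ranked.append(r)
    return ranked


# --------------------------------------------------------------------------
# packaged per-gene allele counts (cases n=496 vs gnomAD / MGRB / Lifepool)


def load_packaged_counts() -> pd.DataFrame:
    """Load the packaged per-gene LoF allele-count table.

    Columns: gene, group (proposed/candidate), x_linked, per-cohort allele
    counts and allele totals (cases, gnomAD non-Finnish non-cancer, MGRB,
    Lifepool), and the number of sequenced tumours.
    """
    with resources.files("twohitscan.data").joinpath("gene_lof_counts.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["x_linked"] = df["x_linked"].astype(bool)
    return df


def enrichment_table(
    counts: pd.DataFrame,
    control: str = "gnomad",
    group_by: str | None = None,
    compute_ci: bool = True,
) -> pd.DataFrame:
    """Fisher enrichment of every gene versus one control cohort, ranked.

    ``control`` is ``"gnomad"``, ``"mgrb"``, ``"lifepool"`` or ``"combined"``
    (MGRB + Lifepool pooled).  Returns a tidy frame sorted by rank.
    """
    results = []
    for row in counts.itertuples(index=False):
        case = GeneBurdenRecord(row.gene, "cases", int(row.case_alleles), int(row.case_total))
        if control == "combined":
            ctrl = combine_cohorts(
                [
                    GeneBurdenRecord(row.gene, "mgrb", int(row.mgrb_alleles), int(row.mgrb_total)),
                    GeneBurdenRecord(
                        row.gene, "lifepool", int(row.lifepool_alleles), int(row.lifepool_total)
                    ),
                ]
            )
        else:
            ctrl = GeneBurdenRecord(
                row.gene,
                control,
                int(getattr(row, f"{control}_alleles")),
                int(getattr(row, f"{control}_total")),
            )
        results.append(
            fisher_enrichment(
                case.lof_alleles,
                case.total_alleles,
                ctrl.lof_alleles,
                ctrl.total_alleles,
                gene=row.gene,
                case_cohort="cases",
                control_cohort=ctrl.cohort,
                compute_ci=compute_ci,
            )
        )
    labels = (
        dict(zip(counts["gene"], counts[group_by])) if group_by is not None else None
    )
    ranked = rank_genes(results, labels)
    rows = [
        {
            "gene": r.gene,
            "case_alleles": r.case_record.lof_alleles,
            "case_total": r.case_record.total_alleles,
            "case_af_percent": r.case_record.af_percent,
            "control_alleles": r.control_record.lof_alleles,
            "control_total": r.control_record.total_alleles,
            "control_af_percent": r.control_record.af_percent,
            "odds_ratio": np.nan if r.odds_ratio is None else r.odds_ratio,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "p_one_sided": r.p_one_sided,
            "rank": r.rank,
        }
        for r in ranked
    ]
    return pd.DataFrame(rows).sort_values(["rank", "gene"]).reset_index(drop=True)
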
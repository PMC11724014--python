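import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from twohitscan.burden import (
    GeneBurdenRecord,
    combine_cohorts,
    count_lof_alleles,
    enrichment_table,
    fisher_enrichment,
    load_packaged_counts,
    one_sided_p,
    rank_genes,
)
from twohitscan.io_formats import VariantRecord
from twohitscan.synthetic import gen_cohort


def _lof(gene="PALB2", af=1e-4, genotype="het", consequence="stop_gain"):
    return VariantRecord(
        "chr16", 23640000, "C", "A", gene=gene, consequence=consequence,
        origin="germline", alt_reads=40, ref_reads=60, gnomad_af=af,
        annotations={"genotype": genotype},
    )


def exact_tail_p(a, n1, b, n2):
    """Independent oracle: integer enumeration of the hypergeometric upper tail."""
    total, k = n1 + n2, a + b
    hi = min(k, n1)
    numer = sum(math.comb(k, x) * math.comb(total - k, n1 - x) for x in range(a, hi + 1))
    return numer / math.comb(total, n1)


class TestCountLofAlleles:
    def test_three_het_carriers_in_496_women(self):
        variants = [_lof() for _ in range(3)]
        rec = count_lof_alleles(variants, "PALB2", "cases", n_individuals=496)
        assert (rec.lof_alleles, rec.total_alleles) == (3, 992)
        assert round(rec.af_percent, 2) == 0.30

    def test_af_threshold_is_inclusive(self):
        common = [_lof(af=0.006)]
        boundary = [_lof(af=0.005)]
        assert count_lof_alleles(common, "PALB2", "c", 496).lof_alleles == 0
        assert count_lof_alleles(boundary, "PALB2", "c", 496).lof_alleles == 1

    def test_homozygous_carrier_contributes_two_alleles(self):
        rec = count_lof_alleles([_lof(genotype="hom")], "PALB2", "c", 496)
        assert rec.lof_alleles == 2

    def test_non_lof_and_other_genes_ignored(self):
        variants = [_lof(consequence="missense"), _lof(gene="ATM")]
        assert count_lof_alleles(variants, "PALB2", "c", 496).lof_alleles == 0

    def test_missing_cohort_size_errors(self):
        with pytest.raises(ValueError, match="cohort size"):
            count_lof_alleles([], "PALB2", "c", None)

    def test_unknown_consequence_class_errors(self):
        v = _lof()
        v.consequence = "weird_class"
        with pytest.raises(ValueError, match="legal values"):
            count_lof_alleles([v], "PALB2", "c", 496)


class TestFisherEnrichment:
    def test_reproduces_published_palb2_row(self):
        r = fisher_enrichment(3, 992, 86, 118190)
        assert round(r.odds_ratio, 1) == 4.2
        assert round(r.p_one_sided, 3) == 0.039
        # conditional exact CI prints as 0.8 to 12.6
        assert round(r.ci_low, 1) == pytest.approx(0.8, abs=0.1)
        assert round(r.ci_high, 1) == pytest.approx(12.6, abs=0.1)
        assert r.ci_low <= r.odds_ratio <= r.ci_high

    def test_empty_table_is_null(self):
        r = fisher_enrichment(0, 992, 0, 118190)
        assert r.odds_ratio is None
        assert r.p_one_sided == 1.0

    def test_zero_control_or_undefined_unless_haldane(self):
        assert fisher_enrichment(3, 992, 0, 8550, compute_ci=False).odds_ratio is None
        r = fisher_enrichment(3, 992, 0, 8550, compute_ci=False, haldane=True)
        assert r.odds_ratio > 0

    def test_small_table_matches_enumeration(self):
        r = fisher_enrichment(2, 10, 1, 10, compute_ci=False)
        assert r.p_one_sided == pytest.approx(exact_tail_p(2, 10, 1, 10), abs=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(-1, 10, 1, 10)

    @given(
        st.integers(2, 40).flatmap(
            lambda n1: st.tuples(
                st.just(n1),
                st.integers(1, 40),
                st.integers(0, n1),
            )
        ),
        st.data(),
    )
    def test_one_sided_p_matches_oracle_on_random_tables(self, tns, data):
        n1, n2, a = tns
        b = data.draw(st.integers(0, n2))
        p = float(one_sided_p(a, n1, b, n2))
        assert p == pytest.approx(exact_tail_p(a, n1, b, n2), abs=1e-12)


class TestCombineAndRank:
    def test_combining_control_cohorts_sums_counts(self):
        combined = combine_cohorts(
            [
                GeneBurdenRecord("PALB2", "mgrb", 4, 5144),
                GeneBurdenRecord("PALB2", "lifepool", 3, 3406),
            ]
        )
        assert (combined.lof_alleles, combined.total_alleles) == (7, 8550)
        assert round(combined.af_percent, 3) == 0.082

    def test_single_record_is_identity(self):
        rec = GeneBurdenRecord("G", "c", 3, 100)
        out = combine_cohorts([rec])
        assert (out.lof_alleles, out.total_alleles) == (3, 100)

    def test_combine_then_fisher_equals_fisher_on_summed_counts(self):
        combined = combine_cohorts(
            [GeneBurdenRecord("G", "a", 3, 5144), GeneBurdenRecord("G", "b", 4, 3406)]
        )
        via_combined = fisher_enrichment(
            3, 992, combined.lof_alleles, combined.total_alleles, compute_ci=False
        )
        direct = fisher_enrichment(3, 992, 7, 8550, compute_ci=False)
        assert via_combined.p_one_sided == direct.p_one_sided
        assert via_combined.odds_ratio == direct.odds_ratio

    def test_duplicate_cohort_or_mixed_gene_rejected(self):
        with pytest.raises(ValueError):
            combine_cohorts(
                [GeneBurdenRecord("G", "a", 1, 10), GeneBurdenRecord("H", "b", 1, 10)]
            )
        with pytest.raises(ValueError):
            combine_cohorts(
                [GeneBurdenRecord("G", "a", 1, 10), GeneBurdenRecord("G", "a", 1, 10)]
            )

    def test_rank_is_order_invariant_and_deterministic_under_ties(self):
        results = [
            fisher_enrichment(2, 100, 2, 1000, gene=g, compute_ci=False)
            for g in ("B", "A", "C")
        ]
        ranked = rank_genes(list(results))
        ranks = {r.gene: r.rank for r in ranked}
        assert ranks == {"A": 1, "B": 2, "C": 3}  # equal p -> gene-name tiebreak
        ranked2 = rank_genes(list(reversed(results)))
        assert {r.gene: r.rank for r in ranked2} == ranks

    def test_top_ranked_gene_versus_population_controls(self):
        table = enrichment_table(load_packaged_counts(), control="gnomad", compute_ci=False)
        assert table.iloc[0]["gene"] == "MAP6D1"
        assert table.iloc[0]["rank"] == 1
        assert sorted(table["rank"]) == list(range(1, len(table) + 1))


class TestCohortLevelProperties:
    def test_combined_or_lies_between_per_cohort_ors(self):
        counts = load_packaged_counts()
        for row in counts.itertuples(index=False):
            if row.mgrb_alleles == 0 or row.lifepool_alleles == 0:
                continue
            or_m = fisher_enrichment(
                row.case_alleles, row.case_total, row.mgrb_alleles, row.mgrb_total,
                compute_ci=False,
            ).odds_ratio
            or_l = fisher_enrichment(
                row.case_alleles, row.case_total, row.lifepool_alleles, row.lifepool_total,
                compute_ci=False,
            ).odds_ratio
            or_c = fisher_enrichment(
                row.case_alleles,
                row.case_total,
                row.mgrb_alleles + row.lifepool_alleles,
                row.mgrb_total + row.lifepool_total,
                compute_ci=False,
            ).odds_ratio
            assert min(or_m, or_l) - 1e-9 <= or_c <= max(or_m, or_l) + 1e-9

    def test_type_i_error_control_under_null(self):
        """With true OR = 1 the discrete one-sided test is conservative."""
        n_reps, hits = 500, 0
        for rep in range(n_reps):
            case, ctrl, _ = gen_cohort(
                496, 4275, ["G"], base_carrier_freq=0.002, or_per_gene=1.0,
                seed=10_000 + rep,
            )
            p = float(one_sided_p(case["G"], 992, ctrl["G"], 8550))
            hits += p <= 0.05
        # binomial 99% upper bound around 0.05 for 500 draws
        assert hits / n_reps <= 0.05 + 2.6 * np.sqrt(0.05 * 0.95 / n_reps)
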
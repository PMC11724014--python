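# Methods

This note records the models implemented in `twohitscan`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data does and does not emulate.

## Case-control burden (`twohitscan.burden`)

Allele counting treats each individual as contributing two autosomal
alleles; a heterozygous carrier of a qualifying variant contributes one LoF
allele and a homozygous carrier two. A variant qualifies when its
consequence is truncating (stop-gain, frameshift, essential splice) and its
population allele frequency is at most `af_threshold` (default 0.005,
inclusive; a missing AF counts as rare, since absence from the reference
database is itself evidence of rarity).

The test is the one-sided Fisher exact test in the enrichment direction:
`p = P(X >= a_case)` under the central hypergeometric distribution with all
margins fixed. The reported point estimate is the *unconditional*
cross-product odds ratio, not the conditional MLE — the two differ slightly
for extreme tables, and the cross-product form is what the packaged
reference table prints. The 95% interval is the conditional exact interval
found by root-solving the Fisher noncentral hypergeometric tail
probabilities on the log-odds axis (bisection bracket ±50 log-units); it is
the interval `fisher.test` in R reports and should be treated as one of
several defensible exact intervals. Zero-cell tables leave the odds ratio
undefined rather than infinite; a Haldane correction (+0.5 per cell) is
available behind a flag but off by default because none of the packaged
reference rows need it.

Ranking is by ascending p within a caller-supplied group, with deterministic
tie-breaks (descending OR, then gene symbol); the reference table's own
tie-break rule is unstated, so ranks for tied rows are reproducible but not
guaranteed to match other software.

X-linked genes are a known gap: hemizygote counts are generally unavailable
for mixed-sex reference cohorts, so allele denominators for X genes are
configurable and X rows are excluded from exact-reproduction tests.

## Purity model (`twohitscan.purity`)

The forward model assumes two cell populations — tumour cells at purity `p`
with local copy number `n_t` (of which `m_v` copies carry the variant) and
diploid normal cells (one variant copy for a germline heterozygous variant,
zero for a somatic one). Sub-clonality is ignored: all somatic variants used
for purity are assumed clonal, which is why the estimator is meant to be fed
TP53-like truncal mutations sitting on single-copy LOH segments. There the
inversion is `p = 2v/(1+v)`; the estimate is the depth-weighted mean over
variants, clipped into (0, 1].

Two of the three purity estimators used in practice (copy-number model fit,
visual inspection of the log2 profile) are human-in-the-loop; they enter the
consensus as externally supplied numbers and the consensus is their
unweighted arithmetic mean — deliberately simple, with no trimming rule, so
a discordant estimator is visible in the output rather than silently
down-weighted. Downstream classification assumes purity >= 0.3 (the
`PURITY_FLOOR`), matching the tumour-cell content that dissection protocols
target.

## Somatic filtering (`twohitscan.somatic_filter`)

A somatic call survives when it is (i) rare in the population
(`gnomad_af <= 1e-4`, missing treated as 0), (ii) inside a capture target
extended by 150 bp on either side (inclusive boundary), (iii) covered at
depth >= 10 with >= 4 alt reads, and (iv) above the purity-adjusted VAF
cut-off `max(vaf_floor, vaf_purity_factor * p/2)` — by default 20% of the
expected clonal heterozygous VAF, with an absolute floor of 0.03. The depth
and VAF defaults are this package's own choices for FFPE-grade exomes and
are all config-exposed; the `stringent` profile (alt reads >= 8, VAF >= 0.10,
zero tolerance for any gnomAD presence) is intended for tumours without a
paired germline sample, where residual germline variants must be excluded.
Removals are attributed to the *first* failing rule in the fixed order
gnomad_af → target → depth → alt_reads → vaf, so audit counts partition the
removed set exactly; filtering is idempotent and the kept set shrinks
monotonically as purity rises. FFPE-specific artefact correction is out of
scope; a channel mask can be applied upstream of signature fitting instead.

## Allelic status (`twohitscan.allelic_status`)

Read counts at the germline variant are modelled as binomial with success
probability equal to the hypothesis' expected VAF (clamped to
[1e-9, 1-1e-9]); no overdispersion term is included because FFPE noise is
handled upstream by filtering. All four hypotheses are scored, but the
argmax is restricted to hypotheses whose implied copy-number state matches
the overlapping segment — the VAF alone cannot distinguish, say, hemizygous
loss at high purity from copy-neutral LOH, and the segment data is precisely
the orthogonal evidence that can. The winner must beat the runner-up by a
Bayes factor of e² (two natural-log units, roughly "positive" evidence);
below that margin the call is AMBIGUOUS rather than forced, mirroring how
uncertain cases are resolved by orthogonal assays in practice (modelled as
an `override_category` input).

A somatic missense counts as a second hit only when both in-silico
deleteriousness scores clear thresholds (CADD phred >= 20, REVEL >= 0.5),
calibrated so that a reported pathogenic hit (CADD 26.6 / REVEL 0.558)
qualifies. "Heterozygous with second hit, phase unknown" is counted as
biallelic by default on the argument that a clonal somatic truncating
variant in the same gene is most parsimoniously on the opposite haplotype; a
strict mode counts it as not biallelic. Promoter methylation is consumed as
external calls, never inferred.

Gene-level patterns: `consistent_biallelic` (every tumour biallelic),
`variant_loss_observed` (any unrescued variant-allele loss — evidence
*against* a two-hit role), `heterozygous_only`, else `partial`.

## HRD scars (`twohitscan.hrd`)

Counter conventions are fixed here because the underlying literature leaves
implementation details open: LOH strictly > 15 Mb with minor copy number 0
(and total >= 1 — a homozygous deletion is not LOH), excluding
whole-chromosome events; TAI >= 11 Mb, reaching a chromosome end within a
10 kb tolerance, not crossing the centromere; LST breakpoints between
>= 10 Mb flanks with <= 3 Mb gap after iterative 3 Mb smoothing (shortest
sub-threshold segment absorbed into its longer neighbour, equal-state
neighbours coalesced; the procedure is idempotent). Breakpoints falling
inside the centromere are arm boundaries, not transitions. All thresholds
are config-exposed so alternative conventions can be tested. The total is
the unweighted sum, deliberately not ploidy-adjusted; >= 63 classifies
HRD-high. Sex chromosomes are excluded by default, the usual convention for
scar scores.

## Signature fitting (`twohitscan.signatures`)

Catalogue construction maps each SNV to one of 96 trinucleotide channels in
COSMIC order under the pyrimidine-strand convention, verifying the reference
base against the genome. Fitting is single-tier non-negative least squares;
the two-tier common/rare search used by some hosted platforms is
deliberately simplified away, since that platform's exact rule set is not
public. The sparsity filter draws B multinomial bootstrap catalogues
(n = observed total, channel probabilities from the observed catalogue),
refits each, and calls a signature only when the fraction of replicates with
proportion <= threshold is below alpha (defaults B = 1000, threshold 0.01,
alpha 0.05); the point fit is then recomputed on the called subset, so
uncalled signatures are exactly zero. Channel-opportunity normalisation
(exome vs genome) is off by default. Reference signature sets are inputs;
none are bundled.

## Synthetic data (`twohitscan.synthetic`)

The generator emulates the study regime the pipeline targets: mean depth
90x (Poisson-distributed per site), purity down to 0.3, a germline
heterozygous variant of interest with a planted allelic fate, ~68 clonal
somatic SNVs per tumour, and five purity-informative somatic variants on a
dedicated single-copy LOH segment (at exact nominal depth, so purity
recovery reflects read noise only). The genome is a miniature: three 100 Mb
autosomes with a 40–42 Mb centromere. Scar events occupy fixed, insulated
slots — interstitial 20 Mb LOH blocks, telomeric 20 Mb (3,1) imbalances,
chains of alternating 12 Mb segments for LSTs, each separated by 5 Mb
buffer segments too short to trigger the LST flank rule — so each planted
event is counted exactly once (capacity 2/2/3 per tumour, validated).

What the generator does *not* emulate: subclonal populations,
overdispersed (FFPE-noisy) read counts, segmentation error in the
copy-number input, germline contamination of somatic calls, and realistic
genome-wide scar burdens (the miniature genome cannot host 63 events).
Passing recovery tests therefore demonstrate correctness of the estimators
under their stated assumptions, not robustness to violations of them.

Cohort simulation draws control carrier alleles as Binomial(2N, f) and case
alleles with the odds multiplied by the gene's true odds ratio. Catalogue
simulation draws Multinomial(n, M·proportions). All generators are
deterministic under a fixed seed.

The signature-recovery tests use synthetic signatures with disjoint
32-channel support (per-block Dirichlet weights, fixed seed). This mirrors
the concentrated channel profiles of real SBS signatures and makes the
70/30-at-n=500 recovery tolerance (±0.05) meaningful: with disjoint support
the estimator's error is dominated by multinomial sampling noise
(sd ≈ 0.021 at n = 500), whereas dense overlapping random signatures
inflate it past the tolerance for a material fraction of draws. Dense
random signatures are still used in the structural and limit tests.

## Verification batteries and problem sizes

The test suite and `scripts/acceptance.py` use: exhaustive enumeration of
every 2x2 table with total <= 50 against an integer-arithmetic
hypergeometric oracle (agreement to 1e-12); 50 scar profiles with planted
(LOH, TAI, LST) recovered exactly; purity recovery at p ∈ {0.3, 0.5, 0.7,
0.9} with 5 variants at depth 200 over 100 replicates per level, asserted
as mean |error| <= 0.05 with >= 95% of replicates within ±0.05 (the
per-replicate tail probability at p = 0.3 is ~0.4%, so an every-replicate
bound is not what these conditions guarantee); 200 allelic-status tumours
at purity >= 0.3 and depth >= 80 with >= 95% accuracy plus a noise-free
limit set at 100%; and a B = 200 bootstrap signature fit (a scaled-down
setting of the B = 1000 default, sufficient for the 5% sparsity quantile).
Type-I control of the burden test is checked over 500 null cohort
replicates. The full suite runs in a few seconds on one CPU.

## Known limitations

* The allelic-status thresholds (Bayes margin, hit-qualification scores)
  are declared defaults validated on synthetic truth, not learned from
  labelled real tumours.
* The conditional-exact CI pairs a conditional interval with an
  unconditional point estimate; for extreme tables the point estimate can
  fall near an interval endpoint.
* Deep-intronic or structural second hits are invisible to this analysis by
  construction.
* The HRD counters consume segment calls as given; segmentation quality is
  upstream of this package.
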
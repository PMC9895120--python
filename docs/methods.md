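# Methods

## The problem

ADAR enzymes deaminate adenosines in double-stranded RNA to inosines,
which sequencers and the translation machinery read as guanosines; APOBEC
enzymes deaminate cytidines to uridines; and the 3' ends of mature miRNAs
acquire untemplated adenylation and uridylation. All of these leave the
same footprint in small-RNA sequencing: reads carrying a nucleotide that
differs from the genomic hairpin. mirledit detects such mutation/editing
(M/E) sites from small-RNA reads, separates them from sequencing error,
genomic variation and multi-mapping artifacts, classifies them nine ways,
and tests cohort-level hypotheses (age dependence of editing, case-control
differences) on the resulting site-by-sample editing-level matrix.

A site is named `{precursor}_{position}_{REF}_{alt}` with 1-based hairpin
coordinates, the reference base in upper-case RNA and the alternative in
lower-case RNA: `hsa-mir-376a-1_9_A_g` is an A-to-I site at hairpin
position 9.

## Detection model

**Preprocessing.** 3' adapters are removed at the earliest read position
where the remainder matches the adapter (full adapter with at most one
substitution, or an exact adapter prefix of at least 8 nt when the read
ends inside the adapter). Reads shorter than 18 nt, or with any base
below Phred 30, are discarded; survivors are collapsed into unique reads.
The "low-quality read" filter is deliberately tied to the same Phred-30
threshold the error null uses, so one parameter governs both. Support is
normalised to Reads Per Ten Million sequencing tags (RPTM), with the
denominator the number of reads surviving trimming and filtering.

**Alignment.** The reference space — tens of hairpins plus decoy loci —
is small enough for exhaustive search, so the aligner compares every read
against every window of every locus (vectorised over windows), replacing
heuristic seed-and-extend mappers with an exact, deterministic procedure.
Placements are ungapped with at most 2 substitutions in the read body and
an optional 3' tail of at most 3 nt. The body/tail split minimises
(body mismatches + tail length); ties prefer the longer tail, so a
trailing mismatch is coded as an untemplated 3' addition — the
representation under which 3'-tailing sites such as `..._37_C_u` arise.
Tail bases are compared against the hairpin and, past its 3' end, the
genomic flank; a tail base matching its template is treated as a
templated extension (reference support), not an edit.

**Cross-mapping correction.** Multi-mapped reads are reallocated
iteratively: the weight of read r at locus L is proportional to
(weighted perfect-match read mass at L + 0.5) x eps^(non-templated bases
of the placement), with eps = 10^-3, normalised over r's placements; the
perfect-match masses are recomputed each round until the largest weight
change falls below 10^-6 (at most 100 rounds). The error-likelihood
factor is essential: it sends a variant-carrying read to the locus where
its sequence is templated even when the competing hairpin dominates
expression, which is exactly the artifact the Pseudo category captures.
Weights of one read always sum to 1, so total read mass is conserved (to
10^-9 in the tests).

**Site calling.** Each aligned base contributes read count x weight to a
per-position nucleotide counter. Every position/alternative pair with
non-zero weighted support is a candidate. Under the error null the
alternative count is Binomial(n = coverage, p0 = 10^(-30/10) = 0.001);
the whole per-base error rate is directed at the specific alternative
(conservative; `error_split_three=True` divides it by 3). Fractional
weighted counts are rounded half-up for the test. P-values are BH
corrected across all candidates of one sample — the criteria are applied
per sample, before combination. A candidate is significant iff level >=
5%, support >= 10 RPTM, and q < 0.05.

**Combination and retention.** Sites are unioned across samples (level 0
where absent) and retained when significant in at least
round-half-up(10% x n_samples) samples, floored at 1. Round-half-up is
chosen over strict ceiling because it reproduces the 13-of-131 behaviour
of the cohort size this rule is quoted for (ceiling would give 14); the
rule is exposed as `retention_threshold`.

## Classification

Decision order: (1) SNP — the site's genomic position and alleles
(strand-aware complementation on minus-strand hairpins) match a known
variant and the editing level reaches 100% in at least one sample, i.e.
the variation is at the DNA level; (2) Pseudo — more than half of the
site's alternative read mass is attributed to other loci by cross-mapping
correction (the package's operationalisation of a category that mapping
artifacts produce); (3) 3'-A / 3'-U / 3'-Other — positions past the
mature 3' end (window: mature end + 5, matching the tail tolerance);
(4) 5' — positions at or before the mature 5' start; (5) central —
A-to-I for A->g, C-to-U for C->u, Other for the rest (e.g. U->g).

The seed region is mature positions 2-8 (the standard convention). A
deamination site is conserved when at least one other species reports the
same editing type at the same mature-relative position. Neighbour
context tables count the immediate 5'/3' nucleotides (A-to-I sites
favour 5' U / 3' G; C-to-U sites sit in C_C context); sites lacking a
neighbour are excluded and counted.

Positions between two mature arms resolve to the containing mature first,
then to a mature whose 3' window reaches them, then to the nearest
downstream mature (a 5' site). Sites on decoy loci carry no mature
annotation and are excluded from classification.

## Cohort statistics

Spearman correlation (midranks) between per-site editing levels and age
at death is computed within each group; p-values are exact by permutation
enumeration for n <= 8 and t-approximated beyond, then BH-corrected
across sites within each group. Case-control differences use the
Mann-Whitney U test with midranks; the two-sided p-value is
P(|U - n1n2/2| >= |u - n1n2/2|), enumerated exactly over all labelings
when C(n1+n2, n1) <= 50,000, taken from the exact U distribution when
n1 x n2 <= 400 with untied data, and otherwise normal-approximated with
tie and continuity correction. The significance column follows the raw
p < 0.05 convention for this screen while BH-adjusted q-values are
reported alongside, reflecting the coexistence of both conventions in
this literature; direction (hyper/hypo) compares group medians and is
None on ties. The paediatric subgroup filter keeps samples strictly
younger than the cutoff. Zero-variance sites yield a NaN correlation
sentinel rather than being dropped silently.

## Synthetic data

The generator emulates what the detector assumes, not the full biology
of small-RNA libraries. Hairpins are uniform-random sequences (>= 62 nt
get both a 5p and a 3p arm of 20-24 nt, shorter ones a single arm) with
30-nt genomic flanks. Reads are anchored on mature arms with geometric
5'/3' templated extension (p = 0.7, capped at 3 nt) — an isomiR-like end
distribution chosen because it reproduces arm-shaped pileups without
modelling Drosha/Dicer processivity. Planted events: central and 5'
substitutions carried independently per read with the target
probability; SNPs carried by every read; 3' tails that truncate the read
at the mature end and append a nucleotide disagreeing with the genomic
template (otherwise they would be indistinguishable from templated
extension). Sequencing errors are uniform per base at 10^(-q/10) toward
the three other nucleotides, with a single Phred value per sample —
per-base quality variation is outside the model since one score
threshold governs filtering. An optional fixed 3' adapter
(`TGGAATTCTCGGGTGCCAAGG`, a common kit sequence) gives the trimmer real
work. Decoy loci embed a mature sub-sequence with one substitution near
its 3' end, so they share an exact >= 18-nt substring with a hairpin and
perfectly match reads carrying that substitution — the cross-mapping trap.

Not emulated: realistic expression distributions across miRNA families,
ligation bias, UMIs, platform-specific error profiles, gapped variants.
Passing the validation experiments therefore demonstrates correctness of
the statistical machinery under its stated assumptions, not performance
on any real library. Read-length and platform settings are configuration
rather than fixed constants, since the target study design does not pin
them down.

## Validation experiments and problem sizes

`mirledit.validation` (shared by the test suite and
`scripts/acceptance.py`) runs three experiments, with per-replicate seeds
spawned from one master seed:

* **Specificity**: 20 replicates x 50 hairpins, depth 500/arm, Phred-30
  noise, no edits; the fraction of candidate sites that end up retained
  must stay within twice the nominal 0.05 BH level (in practice it is 0:
  error-derived candidates fail the 5% level criterion at this coverage).
* **Level recovery**: 100 replicates x levels {0.1, 0.3, 0.7} at coverage
  1000, one edit per hairpin so edits never stack on one read; >= 99% of
  estimates fall within 3*sqrt(L(1-L)/1000).
* **End-to-end recovery**: 100 replicates of a 20-case/25-control cohort
  with one A->g site at level 0.35 vs 0.12, coverage 800; the site must
  be retained, classified A-to-I and called significantly hyper-edited in
  >= 95% of replicates.

These sizes keep each experiment in the tens of seconds on one core
while leaving the binomial tolerances meaningful.

## Numerical choices and degenerate inputs

Round-half-up for all count rounding; 1-based inclusive coordinates
everywhere; candidate and output orderings sorted so every stage is
order-invariant and deterministic. Binomial tails via scipy's survival
function (validated against direct PMF summation to n = 2000); BH via
statsmodels (validated against the sorted-minimum definition). Empty
inputs return empty outputs rather than raising, except where a contract
is violated (zero library total, empty comparison group, alpha outside
(0,1), duplicate sample ids). k = 0 alternative reads is not a candidate;
coverage rounding to zero yields p = 1.

## Known limitations

Indel editing, strand-bias filters, per-position error profiles and
genome-wide mapping beyond supplied decoys are out of scope. The Pseudo
threshold (0.5 of alt mass) and the 3' window (mature end + 5) are
package choices where the underlying convention is not standardised.
Exact Mann-Whitney enumeration is bounded by combination count, so large
tied cohorts use the tie-corrected normal approximation.
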
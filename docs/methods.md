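# Methods

## The assay and the scoring model

MSAP digests genomic DNA in two parallel reactions — EcoRI/HpaII and
EcoRI/MspI — and scores each amplified fragment (locus) as present or absent
in each lane for every sample. HpaII and MspI recognise the same 5′-CCGG
site with different methylation sensitivities: both cut the unmethylated
site; HpaII is blocked when either cytosine carries double-strand
methylation; MspI is blocked when the external cytosine is hemi-methylated.
The band-pattern pairs (HpaII, MspI) = (1,1), (1,0), (0,1) therefore map
bijectively onto non-methylated, hemi-methylated and internal-full-methylated
states, and `classify_band_pair` is a total deterministic function of the
two bits. The fourth pattern (0,0) is kept as a distinct UNINF state and is
never imputed: the assay cannot distinguish site absence from methylation
that blocks both enzymes, so downstream percentages are not forced to sum
methylated + non-methylated to 100.

Polymorphism is defined on called states — a locus is polymorphic when its
state differs between at least two samples. Because the informative states
are in bijection with the band patterns, a definition on raw lanes would
coincide; the state-level definition is used for clarity.

## Relative levels and group comparisons

Methylation levels are *relative*: each class percentage uses the full
analysed marker count as denominator (subset analyses, e.g. a candidate-gene
panel, use the subset size), so uninformative loci depress the informative
classes rather than being silently dropped. The four class percentages sum
to 100 per sample by construction; the methylated level is hemi + full.

Group comparisons use Student's two-sample equal-variance two-sided t-test
(the classical default of desktop statistics packages for this design);
Welch's correction is available behind `equal_var=False`. Degenerate
zero-variance inputs are defined by the limit of the statistic: identical
groups give t = 0, p = 1; zero variance with different means gives ±∞, 0.
No multiple-testing correction is applied across level metrics — the three
metrics are reported with raw p-values, and each profile comparison is a
single pre-specified test.

## Tau, specific and shared sites

With M_j = 1 when sample j is methylated (HEMI or FULL; NON and UNINF both
count 0), tau = (Σ_j M_j − 1)/(n − 1). Loci methylated nowhere are reported
NA rather than the formula's −1/(n − 1): a negative "specificity" for an
unmethylated locus is meaningless. With a locus→gene map, loci collapse to
genes by union (a gene is methylated where any of its loci is).

A locus is *specific* to sample j for a class when it carries the class in
j and in no other sample; summed over samples, METHYLATED-specific counts
equal the number of breadth-1 loci. *Shared* counts over a sample subset
require every member to carry the class; for the METHYLATED class each
member may independently be HEMI or FULL — which is why a shared-methylated
count can exceed shared-hemi + shared-full. Shared counts are anti-monotone
in the subset. Venn-style exhaustive region counts are emitted for subsets
of up to five samples (2⁵ regions); larger subsets get shared/specific
counts only, to keep output bounded. Whether a tissue-specificity total
should be computed on the METHYLATED class or per class and unioned is a
genuine ambiguity; the package exposes the class as an argument and the
sharing report emits all three views.

## Transition counting

Queries pair an ordered sample path with an equal-length pattern over
{N, H, F, M}: N matches NON only, H/F the exact methylated class, M either
methylated state. UNINF matches nothing, including M — transition rows
describe determinate states only, one consistent reading of an assay whose
(0,0) pattern is unclassifiable. Counts are exact position-wise matches;
replicate noise is resolved upstream by consensus calling, not by fuzzy
matching. The built-in default query set encodes the ten canonical
developmental patterns: three along leaf maturation (young → mature leaf)
and seven along the vascular stages, written in phloem–cambium–mature-xylem
column order with cambium as the biological reference stage.

## Expression association

Genes are partitioned by their called state in one tissue (UNINF excluded)
and group means compared with pairwise t-tests. Tests run on log2(x + 1)
values by default because qRT-PCR/FPKM noise is multiplicative; means are
reported on the raw scale; a raw-scale mode is available. Groups of fewer
than two genes yield NA p-values with a warning rather than an error, so a
sparse panel still reports the estimable pairs.

The pattern–expression correlation pools (gene, tissue) pairs over a tissue
subset — by default the four vascular tissues, where expression data are
typically available — and computes Pearson's r between an ordinal state
encoding and expression, with the usual t-test p-value. The encoding
NON = 0, FULL = 1, HEMI = 2 increases in expected transcriptional
suppression (hemi-methylation suppresses more strongly than full
methylation in this system). It is an interpretation, not a measurement:
the encoding is configurable and recorded in every result object.

## The synthetic-data generator

The generator operates one level below the assay: each locus × sample draws
a *biochemical* state — UNMETH, INTERNAL_FULL, EXTERNAL_HEMI, or
BLOCKED_BOTH (methylation blocking both enzymes) — and band lanes follow
deterministically from the sensitivity rules. Calling the simulated bands
recovers the truth exactly on the three informative states; BLOCKED_BOTH
surfaces as UNINF, reproducing the assay's real information loss. The
blocked/absent distinction is deliberately a single knob, since the data
cannot separate them.

Default conditions emulate a ten-tissue hardwood survey:

- 12,575 loci from 135 selective primer pairs (group sizes 11–204,
  fragment lengths 55–550 bp);
- per-tissue class frequencies with hemi-methylation 7.9–11.9 % (mean
  9.52), full methylation 9.4–14.2 % (mean 11.90), non-methylated
  32.7–39.3 % (mean 36.17), the remainder blocked/absent;
- 18 % of loci monomorphic (drawn once from the mean class frequencies and
  copied to every tissue), yielding an ~82 % polymorphic fraction;
- stage series: stage one draws from the stage's class frequencies, each
  later stage redraws with probability 0.25 (`stage_change_prob`), chosen
  as a plausible between-stage turnover;
- expression: log-normal, exp(Normal(μ − δ(state), σ)) per gene × tissue
  with μ = 4.6 (median near FPKM ≈ 100), σ = 0.5, δ(HEMI) = 1.0 >
  δ(FULL) = 0.5 > δ(NON) = 0 on the natural-log scale, encoding the
  suppression ordering.

All generators are seed-deterministic (bit-identical output per seed). An
optional replicate layer flips each call with a small error probability and
a consensus step takes the per-cell majority vote, ties → UNINF, modelling
pooled biological replicates whose reconciliation the assay protocol leaves
open.

What the generator does **not** emulate: fragment co-migration and
size-homoplasy on gels, primer-specific amplification bias, partial
digestion, sequence context of CCGG sites, or spatially correlated
methylation along chromosomes. Passing tests therefore demonstrate that the
pipeline's arithmetic and inference are correct under a clean multinomial
model of the assay, not that real gel scoring is error-free.

## Numerical choices and degenerate inputs

- Percentages are stored at full precision and rounded only for display
  (one or two decimals), avoiding cascading rounding error.
- Class-probability vectors must sum to 1 within 1e-9.
- Zero-variance t-tests and correlations are defined by limits or returned
  NA with a warning (see above), never silently dropped.
- Single-sample matrices are rejected by the operations whose definitions
  need ≥ 2 samples (polymorphism, specificity, tau).
- Ties in summaries (argmin/argmax, consensus votes) resolve to the first
  in row order and to UNINF respectively — deterministic in file order.
- TSV dialect is fixed (tab separator, UTF-8, "." decimal, no quoting) so
  roundtrips are bit-exact; parsers never coerce and every rejection names
  the offending row/column.

## Problem sizes used in checks

The test-suite simulations use scaled-down matrices (hundreds to a few
thousand loci; one 10⁵-locus law-of-large-numbers check), 200 seeds for the
suppression-ordering recovery and 1000 seeds for the null rejection-rate
calibration on the 132-gene panel (26 hemi / 35 full / 71 non). The
acceptance script runs the full 12,575-locus default study. These sizes are
the package's reference configuration; every simulation parameter above is
fixed by the study conditions, not tuned per run.

## Known limitations

- MSAP only sees CCGG sites that amplify; levels are relative by design and
  cannot be compared with absolute (bisulfite-derived) methylation levels.
- The UNINF convention makes transition counts conservative: a locus
  uninformative at any stage of a path is excluded from every pattern,
  including M.
- The ordinal state encoding for the correlation imposes equal spacing
  between NON, FULL and HEMI; rank-based alternatives would relax this but
  are not implemented.
- The generator draws tissues independently given the monomorphic block, so
  it underestimates the between-tissue correlation real developmental
  lineages would show; shared-site counts from synthetic data are
  correspondingly lower than in lineage-structured data.
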
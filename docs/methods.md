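# Methods

## Scope and model

`mutscan` implements a single-endpoint, count-based analysis of pooled
saturation mutagenesis screens. The underlying selection model is
multiplicative: a variant's expected frequency after selection is its
baseline (plasmid) frequency times a per-variant effect, renormalised over
the library. Under this model the enrichment score — selection frequency
over baseline frequency, rescaled so the synonymous median is 1 — is an
unbiased estimate of the effect relative to neutral. No growth dynamics,
time courses or regression-based fitness estimation (Enrich2-style) are
modelled: the assay design has one baseline and one post-selection
endpoint per replicate.

## Library design

A domain of `k × 80` codons is cut into contiguous 80-codon tiles
(240 nt), each yielding all `3 × 240 = 720` single-nucleotide
substitutions as 300-nt oligos (30-nt wild-type flanks for Gibson
assembly). Coordinates are 1-based on the CDS; protein positions add a
user-supplied `numbering_offset` so outputs match canonical isoform
numbering. Domains that do not divide into whole tiles are rejected
rather than padded — the intended targets are exact multiples — and
designs touching a reference stop codon are annotated like any other
variant, never specially filtered. Restriction-site screening of oligos
is a wet-lab concern and is out of scope. HGVS protein strings use
three-letter codes with `Ter` for stop gains and `=` for synonymous
changes.

## Read calling

The read-handling parameters mirror a FLASH/Trimmomatic-style pipeline:
the forward read loses its first 10 bases (degenerate PCR-primer prefix);
pairs merge by exhaustive overlap search over lengths 10–200, choosing
the overlap with the minimum mismatch density (mismatches / overlap
length, ties to the longer overlap) and rejecting pairs whose best
density exceeds 0.25. Disagreeing overlap bases resolve to the
higher-quality base, the forward base winning ties. Merged reads are
assigned to tiles by anchored comparison of their first and last 15 nt
against each tile's 260-nt reference (240-nt variable region plus 10-nt
context each side) with a ±5-nt shift search.

A gapped aligner is deliberately not used: amplicons are fixed-locus, so
direct positional comparison against the short reference is exact for
substitution-only reads, removes a heavyweight dependency, and makes
rejection criteria explicit. A read is wild-type at 0 substitutions,
a single-SNV call at exactly 1 substitution inside the variable region,
and rejected otherwise (`multi_mismatch`, `indel` for unexplained length
changes, `ambiguous_base` for N at the variant site). A lone substitution
in the 10-nt flank context is counted as wild-type — it cannot be a
designed variant; this choice (tolerate vs reject) is surfaced in the
accounting so users can audit it. Base qualities are used only for
overlap resolution, never for filtering. Per-sample accounting satisfies
`total = headcrop_dropped + merge_rejected + unassigned + assigned` and
`assigned = wildtype + single_snv + rejected`.

Throughput: merging and calling run through vectorised numpy batch paths
grouped by read length; both are property-tested for exact equality with
the scalar reference implementations.

## Scoring

Counts convert to frequencies with a pseudocount α (default 0.5; α = 0
supported and used wherever exactness is asserted), divide by the median
plasmid-baseline frequency across baseline replicates, then by the median
ratio over assayed synonymous variants. With α = 0 the score is exactly
depth-invariant; with α = 0.5 the deviation under a 10× depth change is
below 1e-3 once coverage reaches ~1e5 reads per variant and is bounded by
the pseudocount's relative weight in general. A variant with a raw
plasmid count of 0 in a strict majority of baseline replicates is flagged
*unassayed*: it is absent from the library, excluded from hit calling and
from the synonymous control pool. Each selection replicate is normalised
against the pooled (median-of-replicates) baseline, not a replicate-
matched one. The median over an even number of replicates is the mean of
the two central values. Wild-type reads are tabulated but excluded from
the frequency denominator by default (flag to include): the score is
defined over library variants.

## Classification

Hit rule: median enrichment ≥ 1.5 *and* ≥ 1.5 in at least
`min_replicates` individual replicates (3 of 4 for activation, 2 of 3 for
resistance). All thresholds are inclusive and tier intervals are
right-closed: [1.5, 2.5] potential, (2.5, 5] weak, (5, 10] moderate,
(10, ∞) strong. Resistance screens reuse the same tier bounds; they are
configuration, not hard-code. The conjunctive replicate rule applies to
every tier, including "potential". Loss of function mirrors the hit rule
at the low end: median ≤ 0.4 with enough replicates at or below 0.4,
tiered as (0.2, 0.4] inactivating and ≤ 0.2 strongly inactivating; the
0.4 threshold and the mirrored replicate rule are both config-exposed.
Unassayed variants receive no call — distinct from a negative. A
convenience `aa_median` column gives the median over nucleotide variants
encoding the same amino acid change.

## Statistics

Log transforms use the natural log; the t statistic is base-invariant so
this is cosmetic. A two-sided F-test on the log-score variances
(cutoff 0.05) selects between the equal-variance and Welch t-tests; the
control group pools all replicates of all assayed synonymous variants.
FDR control uses the two-stage step-up procedure (Benjamini–Krieger–
Yekutieli 2006) at Q = 0.01, delegated to
`statsmodels.stats.multitest.multipletests(method="fdr_tsbky")` and
cross-checked in the test suite against an independently coded two-stage
Benjamini–Hochberg reference.

OddsPath calibration: with P1 the pathogenic fraction among labelled
controls and P2 the pathogenic fraction among controls with a given assay
readout, OddsPath = [P2(1−P1)]/[(1−P2)P1]. Degenerate P2 ∈ {0, 1} gets a
0.5-count continuity correction and a flag. Default evidence tiers
follow the ACMG/AMP functional-evidence framework (pathogenic ≥ 350 very
strong, ≥ 18.7 strong, ≥ 4.3 moderate, ≥ 2.1 supporting; benign ≤ 0.053
strong, ≤ 0.23 moderate, ≤ 0.48 supporting) and are configuration.

Hydropathy association uses the Kyte–Doolittle scale (swappable) with
Δh = h(alt) − h(ref) over missense variants, two-sided Wilcoxon rank-sum
tests of GoF and LoF classes against neutrals (exact enumeration for
small groups), plus a Fisher exact test on the 2×2
increasing/decreasing × class table. Prediction-score concordance is
Spearman rank correlation computed piecewise for enriched (> 1) and
depleted (< 1) variants; strata under 10 variants are reported missing.

## Druggability integration

Group assignment is a pure function of the three hit flags; the seven
groups are the non-empty cells of the 2³ truth table, and
druggable ⟺ activating ∧ ¬(resistant to both). Clinical concordance maps
each administered inhibitor to a screened drug (erdafitinib, a reversible
inhibitor not screened directly, maps to the pemigatinib screen; the
mapping is configuration), takes the observed mutation with the maximum
median resistance enrichment as the case's lead mutation, and counts the
case concordant when that lead is a resistance hit at any tier.
Percentages are reported rounded to the nearest integer. Recurrence
stratification bins somatic counts as {0, 1, 2–4, ≥5} (configurable).
Cross-paralog comparison consumes a user-supplied protein alignment and
reports per-aligned-position amino-acid-level medians with a
conserved-in-k hit count; alignment generation itself is out of scope.

## Synthetic-data generator

The generator encodes the study conditions the analysis assumes:

- plasmid abundances ~ symmetric Dirichlet, concentration 50 — a
  near-equimolar library with realistic inter-variant spread (CV ≈ 14%);
- 3 baseline, 4 activation and 3 resistance replicates;
- depth 300 reads per variant, the assay's sequencing floor;
- per-class effect multipliers drawn log-normally (σ = 0.4 on the log
  scale) around 6-fold for gain-of-function and resistance classes and
  0.2-fold for loss of function; class fractions default to 5% GoF, 5%
  LoF, 3% pemigatinib-only, 2% futibatinib-only and 2% dual resistance
  among missense variants, giving hit rates of the same order as real
  kinase-domain screens;
- synonymous variants are neutral in every screen by construction;
- reads are 210-nt pairs covering the 260-nt reference with a 10-nt
  degenerate forward prefix, i.i.d. substitution errors at a configurable
  rate, constant high quality except at error positions.

All stochastic steps derive from `(seed, config)` alone. The analytic
mode replaces sampling with expected frequencies, making the pipeline
score equal the programmed effect exactly (the closed-form oracle used in
tests). Not modelled — and therefore not validated by passing tests:
PCR jackpots and chimeras, quality-profile-dependent errors, index
hopping, cell-growth dynamics, and selection acting on synonymous
variants. Passing recovery tests show the statistical machinery recovers
multiplicative effects from multinomial data; they do not certify
behaviour under those unmodelled artefacts.

## Numerical choices and problem sizes

Merging compares overlap densities as exact integer ratios (no float
ties); ordering of manifest and catalog rows is lexicographic in
(gene, CDS position, alt base), making all file outputs byte-stable.
The end-to-end recovery runs used by the test suite and by
`scripts/acceptance.py` use one 720-variant tile at 300 reads per variant
with a 0.5% substitution error rate and the full replicate structure
(10 FASTQ sample pairs, ~2.2 M read pairs), a size chosen so a complete
parameter-recovery study runs in minutes on a single CPU while exercising
every pipeline stage at the assay's nominal coverage.

## Known limitations

- Indel-containing reads are rejected, not characterised; the assay
  designs substitutions only.
- The enrichment score is a point estimate; no shrinkage or variance
  model is applied beyond the replicate rule and the t-test.
- OddsPath depends on the composition of the labelled control set;
  with few controls the continuity-corrected values are conservative
  but unstable.
- Cross-paralog comparison trusts the supplied alignment; positions
  misaligned there propagate directly.
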
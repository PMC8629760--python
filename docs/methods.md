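# Methods

## The pipeline model

`tieraudit` models a family-based, panel-driven prioritization pipeline for
genome sequencing in rare disease. Genomes are interrogated as family
units: each variant is assessed for population frequency, protein
consequence and segregation, then intersected with the virtual gene panels
applied to the case. The output is a small number of mandatory-review
candidates (Tier 1/2 for small variants, Tier A for copy-number calls), a
longer discretionary list (Tier 3), and everything else unreported (Tier
null).

### Small-variant tiering

For one variant in one family, in order:

1. **Quality filter (legacy mode only).** Multinucleotide indel calls —
   a length change of ≥ 3 nt, or a combined deletion/insertion — inside a
   flagged low-complexity region are dropped before tiering. This
   reproduces the documented loss of 3- and 14-nt deletions and a
   1-del/6-ins call to "quality settings".
2. **Segregation.** The proband must carry the variant. Patterns: *de
   novo* (absent from both parents, subject to the parental-support rule
   below), *dominant inherited* (every affected member carries it; under
   complete penetrance no unaffected member may), *biallelic* (homozygous,
   or one allele of a compound-heterozygous trans pair detected at the
   gene level), *X-linked* (hemizygous male, carrier mother),
   *parents unavailable*, or *fails segregation*. Under the
   `shared_variant` sibship model a variant absent from any affected
   sibling fails — the mechanism that hides a genuine de novo event in a
   discordant multiplex sibship.
3. **Parental support.** Legacy mode vetoes a de novo call on a single
   parental alternate read; improved mode tolerates an alternate-read
   fraction up to `parental_alt_fraction_max` (default 0.05, chosen so the
   archetypal 1-of-32 artefactual read no longer vetoes the call).
4. **Frequency.** Population AF ceilings of 0.1% for monoallelic/X-linked
   and 1% for biallelic candidates. The source pipeline's exact thresholds
   are not public; these are conventional rare-disease values and are
   exposed on `TierConfig`. A missing AF annotation is treated as 0 so
   novel variants are never frequency-filtered by omission.
5. **Consequence.** Loss-of-function → high impact; missense and in-frame
   indels → moderate; synonymous/non-coding → Tier null.
6. **Panel intersection.** If the gene is Green on at least one applied
   panel (ratings merged by maximum across panels) with a compatible mode
   of inheritance: Tier 1 for high-impact or de novo protein-altering
   variants, Tier 2 for inherited moderate-impact ones. The Tier 1/Tier 2
   boundary is not published; this reconstruction is constrained by the
   audited cases (a biallelic splice + missense pair printing as "Tier 1;
   Tier 2") and is deliberately simple. Otherwise a variant that passed
   every upstream rule is Tier 3.

Compound heterozygotes require both alleles to survive the filters: a
candidate trans pair is two rare protein-altering heterozygotes in one
gene with different parental origins. When one allele is lost upstream,
the survivor is a singleton and is capped at Tier 3 even in a Green
recessive gene — reproducing the audited case where the surviving missense
of a filtered pair printed as Tier 3.

Two operating points bundle these knobs: `LEGACY_CONFIG` (quality filter
on, zero-tolerance parental support, shared-variant sibships) and
`IMPROVED_CONFIG` (filter off, 5% parental fraction, per-individual
sibships). Relaxing any knob can only promote a variant; this monotonicity
is property-tested.

### CNV / SV

The production path considers only DEL/DUP calls with length strictly
greater than 10 kb and call quality strictly greater than 10, and assigns
Tier A on any ≥ 1-base overlap with a Green-gene span, ignoring mode of
inheritance (a heterozygous deletion over a recessive gene is still
tiered). "Pathogenic region in a Green gene" is modelled as the gene's
full coding span since region boundaries are not published, and
any-overlap is used rather than a reciprocal-overlap fraction. Balanced
inversions produce no copy-number change and never enter this path at
all — the miss is mechanical, not annotation-driven.
`sv_breakpoint_review` models researcher-grade analysis instead: it
inspects the full interval between the outermost breakpoints, so it flags
an inversion whose breakpoints flank a Green gene and is a strict superset
of the Tier A detector. Mosaic carriage, which VCF genotypes cannot
express, travels in a dedicated `MOSAIC` FORMAT key.

## Synthetic cohorts

The generator emulates the audited recruitment: 114 families (72
proband-parent trios, 15 multiplex sibships of three affected brothers,
the remainder split evenly into parent-child duos and singletons, a
documented convention since per-family counts of non-trio structures are
not published), with syndromic probands drawn at 72%. Twelve plantable
archetypes cover the documented mechanisms; each is embedded with exactly
the annotations its mechanism requires (low-complexity flags, a
1-of-32-read mother, mosaic flags, panel membership) and recorded in a
truth table together with the tier an ideal implementation must assign
under each operating point. That expected-tier table is a plain lookup,
independent of the engine, and serves as the oracle in the tests.

Background variation defaults to 50 benign variants per proband genome on
filler genes only (never on archetype genes): a half-and-half mixture of
common (AF 2–50%) and rare variants, mostly inherited, with occasional
benign de novo events. Real genomes carry millions of calls, but only
filter-surviving candidates are informative for the audit, so the
generator models candidate-scale variation directly. There is no sequence
realism — no reads, no reference FASTA, no mutation-rate or population
structure model — and gene spans live on toy contigs. Consequently,
passing tests demonstrate the correctness of the *decision logic*, not
calling accuracy on real data.

Determinism: one seeded NumPy generator consumed in a fixed order; the
same configuration and seed give byte-identical files. The "legacy" mode
pairs the legacy configuration with the original panel versions and
"improved" pairs the remediated configuration with the updated versions,
matching how re-analysis would be deployed.

## The embedded fixture

The 36 audited diagnoses are embedded as data: 22 researcher-submitted
cases transcribed field-for-field, 12 pipeline/clinic finds known through
aggregate counts (placeholder gene symbols except the named ZBTB20 case),
and two diagnoses from outside both routes. Fields not printed per-case —
the inheritance of the X-linked deletion case, one phenotype-ranker rank,
and which two diagnoses are non-syndromic — are assigned the unique or a
schematic value consistent with every aggregate count (the two
non-syndromic diagnoses are placed on schematic cases so no transcribed
row carries an invented flag); such cases are marked `schematic=True`.
The `legacy_filter_dropped` flag is set for all five small-variant
calling/filtering losses (the three indel-filter cases, the
parental-read case and the forced-sibship case), which makes the
improved-calling strategy and the loss attribution consistent with the
published arithmetic. Two VUS cases are excluded from every sensitivity
denominator (N = 34).

## Strategies and audit

Strategy found-sets are predicates over case attributes; non-baseline
strategies describe additional routes and exclude baseline finds. The
combined national-guidance strategy is flag-driven because the guidance
document is external; the flag column is itself part of the transcribed
data. Sensitivities use a single rounding rule (nearest integer, halves
away from zero), which reproduces every published percentage and
increment. The missed-diagnosis code joins a reason digit (1 filtering/
calling, 2 gene not Green on the applied panels, 3 untiered SV/CNV, 4
research/novel gene; SV/CNV takes precedence because the calling route,
not the gene, failed) with an inheritance letter (A–E, with E for a de
novo event inside a discordant multiplex sibship — a definition attested
by a single case and therefore a reconstruction). The syndromic contrast
is a one-tailed Fisher exact test (direction fixed as "syndromic diagnosed
more often") via `scipy.stats.fisher_exact`, cross-checked in the tests
against exhaustive fixed-margin enumeration; the 2×2 counts are the
unique integer solution to the published stratum percentages.

## Numerical and interface choices

* Coordinates are 1-based inclusive externally (VCF convention); interval
  arithmetic is 0-based half-open inside the gene index only.
* VCF floats are stored as 32-bit by the format; parsed values are
  normalized to 6 significant figures so write/parse cycles are exact.
* Multi-allelic sites are decomposed to one record per ALT allele;
  allele counts are per-allele, so hemizygous X genotypes in males are
  0/1-valued.
* Test problem sizes: the shared generated cohort uses 30 families with
  light background; the multi-seed recovery property runs five seeds at 16
  families; one full 114-family generation + dual-mode tiering + audit
  runs end to end in a few seconds.

## Known limitations

* No in-silico pathogenicity scores, phasing, mitochondrial logic, or
  ACMG/AMP classification — pathogenicity labels are data.
* The phenotype-driven ranker is treated as an annotation (a rank per
  case), not re-implemented.
* Panel content is a synthetic stand-in reproducing the fixture's
  green/not-green outcomes per gene; it is not a PanelApp snapshot.
* Only two panel versions (original/updated) are modelled — the
  granularity at which re-analysis decisions are reported.
* SV segregation is not modelled beyond carrier sets; the copy-number
  path deliberately ignores inheritance, as the production rule does.
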
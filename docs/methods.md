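# Methods

This note documents the models and estimators implemented in `pacvar`, the
defaults that matter, what the synthetic-data generator does and does not
emulate, and the design choices made where more than one reasonable option
existed.

## Gene models and coordinates

External formats keep their native conventions (GFF3 and VCF are 1-based
inclusive; BED is 0-based half-open and converted on read).  Internally a
gene model stores 1-based inclusive CDS segments ordered 5'→3' along the
mRNA, the spliced sense-strand CDS, and its translation under the standard
nuclear code.  Invariants enforced on load: CDS length divisible by 3, a
single terminal stop, no internal stop, non-overlapping segments.

Split annotations can be merged into one model by concatenating the
constituents' spliced CDS in translation order.  If an upstream constituent
ends in a stop codon, those three bases are dropped so the merged ORF has
exactly one terminal stop — the only rule that yields a translatable single
ORF from two stop-complete fragments.  Merges work for both adjacent and
gapped constituents (the intervening genomic sequence is simply never part
of a CDS segment).  A merge that still contains an internal stop is an
error, not a silent product.

Only one transcript per gene is modelled (the one named in the input);
alternative isoform discovery, selenocysteine, and annotation lift-over are
out of scope.  Codons containing ambiguity bases (N) are excluded from site
counting and make affected variant calls `unclassifiable` rather than
guessed.

## Variant classification

Variants are trimmed (shared suffix, then prefix, preserving VCF
left-anchoring) before classification.  SNPs are substituted into their
codon (minus-strand genes complement the alleles first) and classified by
comparing amino acids: silent, missense, nonsense (alt codon is a stop),
or stop-loss (reference codon is the terminal stop).  Stop-loss is kept as
its own class even though it is rare; it is never folded into missense.

Indels must lie fully inside the CDS; edits spanning a splice junction or
UTR boundary are `unclassifiable`.  A net length change not divisible by 3
is a frameshift, positioned at the codon containing the first changed base;
in-frame indels are re-translated, and an in-frame change that introduces a
premature stop is reported as nonsense.  Notation follows the abbreviated
survey-table dialect (`p.Asn175fs/c.525_526delCA`: no transcript prefix, no
frameshift extension length).  Two SNPs in the same codon in the same
accession are classified independently per SNP; a combined-codon mode is
deliberately not implemented because the upstream per-SNP exports are the
unit of observation.

Carriers are accessions, not alleles: the surveyed populations are inbred
lines, so any genotype containing the alternate allele counts the accession
once.  Population annotation is non-redundant over
(gene, chrom, pos, ref, alt) with carrier sets unioned; multi-allelic VCF
records are split first.  A site-list VCF without genotypes is accepted as
a dialect, taking carrier counts from INFO/AC (accession burdens then
cannot be computed, since they need carrier identities).

## Diversity (π_N/π_S)

Site counting is Nei–Gojobori: each position of each non-stop codon
contributes `f_syn` synonymous and `1 − f_syn` nonsynonymous sites, where
`f_syn` is the fraction of the three single-base neighbours preserving the
amino acid.  Changes that create a stop count as nonsynonymous; the
terminal stop codon is excluded.

Per-site diversity is the sample-size-corrected heterozygosity
`π_site = n/(n−1) · (1 − Σ p_i²)`, which equals the average pairwise
difference over all accession pairs (verified exhaustively for n ≤ 8 in the
tests).  π_N (π_S) is the sum of π_site over nonsynonymous (synonymous)
polymorphic SNP sites divided by the nonsynonymous (synonymous) site count.
Nonsense SNPs count as nonsynonymous; frameshifts and other indels are
excluded entirely — π is a per-site substitution statistic.  If a CDS
position carries alt alleles of both classes, each class contributes its
own per-site term; the mixed case is not otherwise defined.

Group assignment: purifying below 0.8, intermediate on the closed interval
[0.8, 1.5], diversifying above 1.5.  The ratio is undefined when π_S = 0 or
when fewer than `min_syn_sites` (default 1) synonymous polymorphic sites
exist — a guess at why such tools occasionally cannot analyze a gene, and
flagged as such.  The estimator here is a standard allele-frequency π with
Nei–Gojobori sites; other packages' ratios can differ by a method constant,
so validation rests on closed forms and synthetic recovery rather than on
matching another tool's absolute values.

## Poly(A)-site calling and nonstop fractions

Internal priming places spurious mRNA–poly(A) junctions immediately 5' of
genomic A-tracts.  Masking removes tags whose 3' end falls inside any run
of ≥ `min_run` (default 8) A's on the tag's sense strand plus a `flank`
(default 20 nt, a tag-length proxy) extending upstream in that strand's
orientation; for minus-strand tags the target is a T-run in plus
coordinates with the flank extending right.  Masking is idempotent and
shrinks monotonically as `min_run` grows (tested).

Surviving tag ends are single-linkage clustered within `merge_window`
(default 24 nt, common poly(A)-site clustering practice); the
representative position is the modal end (smallest on ties) and the tag
count is the cluster size, so tag counts are conserved.  Sites are zoned
against a gene model: CDS-internal, intronic, 3' side of the stop codon
(within `downstream_extent`, default 500 nt), 5' of the start codon (within
an equal upstream extent), antisense, or intergenic.  The per-gene nonstop
fraction is CDS-internal tags over all sense-strand tags of the gene; a
gene with no sense tags reports a missing value, never 0.  Per-sample
fractions are reported alongside the pooled one.  Read alignment itself and
differential APA statistics are out of scope; the module consumes aligned
junction coordinates.

## Pseudogene evidence

Four independent evidence classes, five rules, all thresholds configurable:

| rule | class | default trigger |
|---|---|---|
| R1 | disruption | severe nonsense at frequency ≥ 1 accession |
| R2 | disruption | severe frameshift at frequency ≥ 1 accession |
| R3 | nonstop | nonstop fraction ≥ 0.5 |
| R4 | expression | normalized expression ≤ 2 (floor = 1) |
| R5 | diversity | ≥ 100 distinct missense and group diversifying/undefined |

A truncation is *severe* when it falls before 90% of the protein length
(`severe_cutoff = 0.90`); C-terminal truncations never trigger disruption,
so a common stop in the last few percent of a protein cannot drive a call.
The call is `pseudogene_candidate` with ≥ 2 triggered classes — R1 and R2
are one class, because a nonsense and a frameshift are two flavours of the
same observation (a fixed truncation), not independent lines of evidence.
Disruption alone gives `dispensable_candidate`: the gene is intact in most
of the population yet tolerates homozygous loss in some accessions, which
speaks to dispensability rather than pseudogenization.  Anything else is
`functional`.  Missing signals never trigger rules.

The disruption frequency threshold defaults to 1 because the surveyed lines
are inbred: even a private truncation is a homozygous knockout in a viable
accession, which is exactly the dispensability observation.  The nonstop
(0.5), expression (2× floor), and missense (100) thresholds are
calibrations chosen to reproduce the qualitative calls of the packaged
calibration fixture (three lineage-specific CFIIm-related genes →
pseudogene candidates; CstF50 and PAPS3 → dispensable candidates), not
measured biological constants, and the output records which rules fired so
a reader can audit every call.  Expression normalization divides each
sample (tissue) by its minimum across genes, so 1 is the floor; zeros must
be replaced by an explicit positive floor before normalizing.

The calibration attribute table shipped under `src/pacvar/data/` is
labelled synthetic: the truncating variants and their frequencies come from
the packaged survey tables, but the protein lengths, missense counts for
three of the five genes, and the nonstop/expression values are constructed
stand-ins for genotype-level sources that are not desk-scale.

## Synthetic-data generator

The population model is acceptance sampling, chosen over a coalescent
because the statistic under test (π_N/π_S) depends only on the relative
diversity at synonymous and nonsynonymous sites, and acceptance sampling
makes the expectation derivable in closed form.  Candidate SNPs are
proposed uniformly over CDS sites with a uniform alternate base — exactly
the Nei–Gojobori site proportions — and accepted with probability 1 if
synonymous and ω if nonsynonymous (for ω > 1 the roles flip, suppressing
synonymous proposals by 1/ω), so E[π_N/π_S] = ω.  Accepted variants get a
uniform carrier count in [1, n−1] and a random accession subset; the
frequency distribution cancels in the ratio.  Accessions are haploid in
effect (homozygous inbred lines).  The default proposal density is 0.5 per
CDS site, emulating the polymorphism supply of a 1000+-accession panel in
which a large fraction of coding sites segregate somewhere in the
collection.

Injections place a chosen effect (nonsense, missense, frameshift, in-frame
indel) at a chosen codon and accession frequency by pre-seeding the codon
one substitution away from the intended outcome; truth tables record every
injected and random variant so recovery is exactly checkable.  Generated
genes avoid AAA/TTT codons and generated intergenic/intronic sequence has
A/T runs longer than 5 broken, so the only maskable A-tracts are the
planted internal-priming decoys; decoy tags are placed immediately 5' of
each planted tract and must vanish after masking.  Indel injections use
codon-aligned exons, lengths 1–6 nt exercise both frame outcomes.

Deliberately not modelled: linkage and recombination, demography,
sequencing error, heterozygosity, multi-nucleotide substitutions.  Passing
recovery tests therefore shows estimator correctness under idealized
sampling, not robustness to population structure or data artifacts.

## Problem sizes and numerics

The recovery experiments use 200 accessions, 300-codon genes, 50 replicates
per ω ∈ {0.1, 1.0, 3.0}, and 500 tags per gene for poly(A)-site recovery —
sizes at which the closed-form expectations are comfortably resolvable and
the whole suite stays interactive.  Oracle checks are exhaustive on
100-codon fixtures (all 9 single-base mutants per codon; all 1–6 nt indels
at every position).  Ties in modal poly(A)-site positions break to the
smallest coordinate; table sorts break ties by protein position ascending;
frequency-spectrum bins are closed integer ranges and must partition the
frequency axis from 1.  All generators are `numpy.random.default_rng`
seeded explicitly; identical seeds give byte-identical emitted files.

## Known limitations

- π_N/π_S absolute values are estimator-specific; only closed forms and
  synthetic recovery are claimed, not agreement with any other package's
  printed ratios.
- The evidence rules formalize qualitative reasoning; the defaults are
  calibrations (documented above), and calls are labelled "candidate" —
  no claim of organismal essentiality is made.
- Variants are classified one at a time; compound heterozygous or
  same-codon combined effects are not modelled.
- Zone assignment attaches a site to the first gene model giving a
  non-intergenic zone; overlapping gene arrangements need curated model
  sets.
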
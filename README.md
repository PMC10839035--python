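# pacvar

Population-scale analysis of natural variation in genes encoding the plant
mRNA polyadenylation complex (PAC) — the 15–20-subunit machinery that
cleaves pre-mRNA and adds the poly(A) tail.  Across large collections of
inbred *Arabidopsis thaliana* accessions, some PAC-encoding genes are nearly
invariant while others tolerate heavy missense loads, premature stop codons,
frameshifts, and transcripts that are polyadenylated inside the coding
region (nonstop RNAs).  `pacvar` turns that kind of survey into a tested,
reusable pipeline for anyone asking "which members of a gene family look
conserved, which look dispensable, and which look like pseudogenes?" from
population VCFs, gene annotations, 3'-end sequencing tags, and expression
tables.

## What it computes

**Variant effects.** Each coding SNP or short indel is classified against a
strand-aware gene model (built from GFF3 + FASTA, with support for merging
split annotations into one ORF) as missense, silent, nonsense, frameshift,
in-frame indel, or stop-loss, with abbreviated HGVS-style names
(`p.Asn175fs/c.525_526delCA`) and accession frequencies.

**Diversity and selection.** Per gene, expected synonymous and
nonsynonymous site counts follow Nei–Gojobori counting: position *j* of
codon *c* contributes `f_syn = (# synonymous single-base neighbours)/3`
synonymous sites, so `n_sites + s_sites = 3 × codons`.  Per-site diversity
is the unbiased heterozygosity over *n* accessions,

    pi_site = n/(n-1) * (1 - sum_i p_i^2),

summed over polymorphic sites of each class and normalised by the site
totals.  The ratio π_N/π_S assigns each gene to a selection group:
purifying (< 0.8), intermediate (0.8–1.5), or diversifying (> 1.5).

**Tabulation.** Frequency spectra per effect class, tables of variants seen
above an accession-count threshold, nonsense/frameshift tables, and
per-accession missense burdens.

**Poly(A) sites.** 3'-end tags (BED6) are cleaned of internal-priming
artifacts by masking genomic A-tracts (≥ 8 A's plus a 20-nt upstream flank
on the tag's sense strand), clustered into peaks (single-linkage, 24 nt),
zoned against gene models, and summarised as a per-gene *nonstop fraction*:
the share of sense-strand tags whose poly(A) site lies inside the CDS.

**Pseudogene evidence.** Disruption (severe truncations segregating in the
population), nonstop transcription, floor-level expression, and a
diversifying missense burden are combined into a per-gene call:
`functional`, `dispensable_candidate` (disruption only — the gene is intact
in most accessions but tolerates loss), or `pseudogene_candidate` (at least
two independent evidence classes).

**Synthetic data.** A generator produces genomes, multi-exon gene models,
acceptance-sampled populations whose expected π_N/π_S equals a chosen ω,
injected disruptions at chosen frequencies, PAT-seq tag sets with planted
internal-priming decoys, and expression tables — so the whole pipeline is
testable without downloads.

## Worked example

Simulate three 300-codon genes in a 200-accession population under three
selection regimes, classify every variant, and recover the regimes:

```python
from pacvar.simulate import GeneSpec, SimulationConfig, simulate_population
from pacvar.variants import annotate_population
from pacvar.diversity import gene_diversity

cfg = SimulationConfig(seed=1, n_accessions=200,
    genes=[GeneSpec("conserved", 300, omega=0.1),
           GeneSpec("neutral", 300, omega=1.0),
           GeneSpec("diversified", 300, omega=3.0)])
sim = simulate_population(cfg)
effects = annotate_population(sim.models, sim.variants)
for m in sim.models:
    r = gene_diversity(m, [e for e in effects if e.gene_id == m.gene_id], 200)
    print(f"{m.gene_id:12s} pi_N={r.pi_n:.4f} pi_S={r.pi_s:.4f} "
          f"ratio={r.ratio:.3f} group={r.group}")
```

prints

```
conserved    pi_N=0.0155 pi_S=0.1969 ratio=0.079 group=purifying
neutral      pi_N=0.1648 pi_S=0.1679 ratio=0.982 group=intermediate
diversified  pi_N=0.1754 pi_S=0.0571 ratio=3.072 group=diversifying
```

ω is the relative acceptance probability of nonsynonymous changes in the
generator, so the recovered ratios (0.079, 0.98, 3.07) sitting near 0.1, 1,
and 3 show the estimator recovering the simulated selection regime, and the
groups are read off the 0.8/1.5 cut-points.

The package also ships the published survey tables for the 31 *Arabidopsis*
PAC genes.  Summarising them from the command line:

```
pacvar -q tabulate --outdir out \
    --table src/pacvar/data/pac_missense_gt1000.tsv \
    --table src/pacvar/data/pac_nonsense.tsv \
    --table src/pacvar/data/pac_frameshift.tsv
```

prints

```
{
 "missense_variants": 17,
 "missense_genes": 10,
 "nonsense_variants": 22,
 "nonsense_genes": 9,
 "frameshift_variants": 53,
 "frameshift_genes": 13
}
```

i.e. 22 nonsense mutations across 9 genes, 53 frameshifts across 13 genes,
and 17 missense variants carried by more than 1000 accessions across 10
genes, with per-table TSV output written to `out/`.

A full pipeline run (`pacvar run --config pipeline.yaml`) executes models →
annotate → diversity → tabulate → patseq → evidence and writes a manifest
with SHA-256 checksums of every artifact; `pacvar simulate` emits a
complete synthetic input set (FASTA/GFF3/VCF/BED/TSV plus a truth-table
JSON).

## Layout

- `src/pacvar/` — library (`gene_models`, `variants`, `diversity`,
  `tabulation`, `patseq`, `evidence`, `simulate`, `tables`, `pipeline`,
  `cli`)
- `src/pacvar/data/` — packaged survey tables and the synthetic calibration
  attribute table
- `docs/methods.md` — models, estimators, defaults, and limitations
- `tests/` — pytest suite, including exhaustive oracle checks and the
  acceptance properties
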
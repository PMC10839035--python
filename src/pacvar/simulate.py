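"""Synthetic data generator: genomes, accession populations, PAT-seq tags.

The population model is acceptance sampling, not a coalescent: candidate
point mutations are proposed uniformly over CDS sites (uniform alternate
base), and a proposal is accepted with probability 1 if synonymous and
``omega`` if nonsynonymous (for omega > 1 the roles flip: nonsynonymous
proposals are always accepted and synonymous ones with probability
1/omega).  Because proposals hit synonymous and nonsynonymous "sites" in
exactly the Nei-Gojobori proportions, the expected pi_N/pi_S of the
resulting population equals omega.  Accepted variants are assigned to a
uniform-size random subset of accessions (the inbred lines are haploid in
effect; carriers are homozygous).  There is no linkage, recombination,
demography, or sequencing error.

PAT-seq tags are drawn per gene with a configurable CDS-internal fraction;
internal-priming decoys are planted as A >= 8 tracts downstream of genes
with tags placed immediately 5' of each tract, which the masking step of
:mod:`pacvar.patseq` must remove.

Generated intergenic and intronic sequence has A/T runs longer than 5
broken, so the only maskable tracts are the planted decoys.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .gene_models import GeneModel, STOP_CODONS, revcomp, translate
from .variants import (
    FRAMESHIFT,
    IN_FRAME_INDEL,
    MISSENSE,
    NONSENSE,
    SILENT,
    VariantRecord,
)
from .patseq import TagAlignment

_BASES = "ACGT"
# sense codons, minus AAA/TTT so generated CDS cannot contain A/T runs >= 6
_CODON_POOL = [
    a + b + c
    for a in _BASES for b in _BASES for c in _BASES
    if a + b + c not in STOP_CODONS and a + b + c not in ("AAA", "TTT")
]
# codons pre-seeded at injection positions: one substitution away from the
# intended outcome
_SEED_CODON = {NONSENSE: "TGG", MISSENSE: "GCT"}


@dataclass(frozen=True)
class GeneSpec:
    """One simulated gene.

    ``mutation_rate`` is the proposal density per CDS site.  The default of
    0.5 emulates the polymorphism supply of a 1000+-accession inbred panel,
    where a large fraction of coding sites segregate somewhere in the
    collection; it is the density, not the acceptance rate, so realized
    polymorphism is lower for omega != 1.
    """

    name: str
    n_codons: int = 100
    n_exons: int = 1
    strand: str = "+"
    omega: float = 1.0
    mutation_rate: float = 0.5  # proposals per CDS site


@dataclass(frozen=True)
class Injection:
    gene: str
    effect_class: str  # nonsense, missense, frameshift, in_frame_indel
    protein_pos: int
    frequency: int


@dataclass(frozen=True)
class PatseqGeneSpec:
    gene: str
    total_tags: int = 500
    cds_internal_fraction: float = 0.0
    decoy_tracts: int = 0
    decoy_tags: int = 25


@dataclass
class SimulationConfig:
    seed: int
    n_accessions: int = 100
    genes: list[GeneSpec] = field(default_factory=list)
    injections: list[Injection] = field(default_factory=list)
    patseq: list[PatseqGeneSpec] = field(default_factory=list)
    expression: dict[str, dict[str, float]] = field(default_factory=dict)
    samples: list[str] = field(default_factory=lambda: ["s1"])
    chrom: str = "chr1"
    intergenic: int = 800
    intron_length: int = 120
    downstream: int = 700

    def __post_init__(self) -> None:
        for inj in self.injections:
            if inj.frequency > self.n_accessions:
                raise ValueError(
                    f"injection frequency {inj.frequency} exceeds population"
                )
        for g in self.genes:
            if g.omega <= 0:
                raise ValueError(f"{g.name}: omega must be > 0")
        for p in self.patseq:
            if not 0.0 <= p.cds_internal_fraction <= 1.0:
                raise ValueError("cds_internal_fraction must be in [0, 1]")


@dataclass
class PopulationSim:
    config: SimulationConfig
    genome: dict[str, str]
    models: list[GeneModel]
    variants: list[VariantRecord]
    truth: dict
    accessions: list[str]
    decoy_tracts: dict[str, list[tuple[int, int]]]  # gene -> (start, end) 1-based


def _break_runs(seq: list[str], rng: np.random.Generator, max_run: int = 5) -> None:
    """Substitute bases in place so no A or T run exceeds ``max_run``."""
    run, prev = 1, seq[0] if seq else ""
    for i in range(1, len(seq)):
        if seq[i] == prev and prev in "AT":
            run += 1
            if run > max_run:
                choices = [b for b in "CG"]
                seq[i] = choices[rng.integers(0, 2)]
                run, prev = 1, seq[i]
        else:
            run, prev = 1, seq[i]


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    seq = [_BASES[i] for i in rng.integers(0, 4, size=n)]
    if seq:
        _break_runs(seq, rng)
    return seq


def _make_cds(
    rng: np.random.Generator, spec: GeneSpec, injections: Sequence[Injection]
) -> str:
    codons = ["ATG"]
    codons += [_CODON_POOL[i] for i in rng.integers(0, len(_CODON_POOL),
                                                    size=spec.n_codons - 2)]
    codons.append("TAA")
    for inj in injections:
        if not 1 <= inj.protein_pos <= spec.n_codons - 1:
            raise ValueError(
                f"injection at codon {inj.protein_pos} outside protein of "
                f"{spec.name} ({spec.n_codons - 1} residues + stop)"
            )
        if inj.protein_pos == 1:
            raise ValueError("cannot inject at the start codon")
        seed = _SEED_CODON.get(inj.effect_class)
        if seed:
            codons[inj.protein_pos - 1] = seed
    return "".join(codons)


def _exon_segments(
    cds_len: int, n_exons: int, strand: str, genome_cursor: int, intron: int
) -> tuple[list[tuple[int, int]], int]:
    """Split a CDS into exons at codon boundaries; returns segments in
    genomic order and the cursor past the gene."""
    base = cds_len // (3 * n_exons) * 3
    lens = [base] * n_exons
    lens[-1] = cds_len - base * (n_exons - 1)
    segs = []
    pos = genome_cursor
    for L in lens:
        segs.append((pos, pos + L - 1))
        pos += L + intron
    pos -= intron
    return segs, pos


def build_genome(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, str], list[GeneModel], dict[str, list[tuple[int, int]]]]:
    """Lay out genes on one chromosome and return genome, models, decoys."""
    inj_by_gene: dict[str, list[Injection]] = {}
    for inj in config.injections:
        inj_by_gene.setdefault(inj.gene, []).append(inj)
    patseq_by_gene = {p.gene: p for p in config.patseq}

    chunks: list[str] = []
    cursor = 1
    models: list[GeneModel] = []
    decoys: dict[str, list[tuple[int, int]]] = {}

    for spec in config.genes:
        gap = _random_seq(rng, config.intergenic)
        chunks.append("".join(gap))
        cursor += config.intergenic

        cds = _make_cds(rng, spec, inj_by_gene.get(spec.name, ()))
        segs, cursor_after = _exon_segments(
            len(cds), spec.n_exons, spec.strand, cursor, config.intron_length
        )
        # fill gene body: exon sequence (sense or revcomp) + introns
        gene_sense = cds if spec.strand == "+" else revcomp(cds)
        body: list[str] = []
        off = 0
        for i, (s, e) in enumerate(segs):
            seg_len = e - s + 1
            body.append(gene_sense[off: off + seg_len])
            off += seg_len
            if i < len(segs) - 1:
                body.append("".join(_random_seq(rng, config.intron_length)))
        chunks.append("".join(body))
        cursor = cursor_after

        translation_order = segs if spec.strand == "+" else segs[::-1]
        model = GeneModel(
            gene_id=spec.name,
            display_name=spec.name,
            chrom=config.chrom,
            strand=spec.strand,
            cds_segments=translation_order,
            cds_sequence=cds,
            protein_sequence=translate(cds),
        )
        models.append(model)

        # downstream region; plant decoy A-tracts for PAT-seq if requested
        down = _random_seq(rng, config.downstream)
        pspec = patseq_by_gene.get(spec.name)
        if pspec and pspec.decoy_tracts:
            tract_base = "A" if spec.strand == "+" else "T"
            for k in range(pspec.decoy_tracts):
                # offset into the downstream gap, away from the 3'UTR site
                start_off = 300 + 60 * k
                if start_off + 10 > config.downstream:
                    raise ValueError("downstream region too small for decoys")
                for j in range(10):
                    down[start_off + j] = tract_base
                g_start = cursor + start_off
                decoys.setdefault(spec.name, []).append((g_start, g_start + 9))
        chunks.append("".join(down))
        cursor += config.downstream

    genome = {config.chrom: "".join(chunks)}
    for m in models:
        m.validate()
    return genome, models, decoys


def _genomic_alleles(model: GeneModel, cds_pos: int, ref_s: str, alt_s: str):
    """Sense-strand CDS alleles -> genomic (pos, ref, alt)."""
    g = model.cds_to_genomic(cds_pos)
    if model.strand == "+":
        return g, ref_s, alt_s
    comp = str.maketrans("ACGT", "TGCA")
    return g, ref_s.translate(comp), alt_s.translate(comp)


def simulate_variants_for_model(
    model: GeneModel,
    omega: float,
    mutation_rate: float,
    accessions: Sequence[str],
    rng: np.random.Generator,
    exclude_cds: frozenset[int] = frozenset(),
) -> tuple[list[VariantRecord], list[dict]]:
    """Acceptance-sampled SNPs for one gene; returns (records, truth rows)."""
    n_acc = len(accessions)
    cds = model.cds_sequence
    sites = np.array(
        [i for i in range(1, len(cds) - 2) if i not in exclude_cds]
    )
    n_prop = int(round(mutation_rate * len(sites)))
    chosen = rng.choice(sites, size=min(n_prop, len(sites)), replace=False)
    records, truth = [], []
    for cds_pos in sorted(int(c) for c in chosen):
        ref_b = cds[cds_pos - 1]
        alts = [b for b in _BASES if b != ref_b]
        alt_b = alts[rng.integers(0, 3)]
        idx = (cds_pos - 1) // 3
        within = (cds_pos - 1) % 3
        codon = cds[3 * idx: 3 * idx + 3]
        mutant = codon[:within] + alt_b + codon[within + 1:]
        syn = translate(codon) == translate(mutant)
        if omega <= 1.0:
            p_accept = 1.0 if syn else omega
        else:
            p_accept = (1.0 / omega) if syn else 1.0
        if rng.random() > p_accept:
            continue
        k = int(rng.integers(1, n_acc)) if n_acc > 1 else 1
        carriers = frozenset(rng.choice(accessions, size=k, replace=False))
        g, ref_g, alt_g = _genomic_alleles(model, cds_pos, ref_b, alt_b)
        records.append(VariantRecord(model.chrom, g, ref_g, alt_g, carriers))
        cls = SILENT if syn else (NONSENSE if translate(mutant) == "*" else MISSENSE)
        truth.append(
            {
                "gene": model.gene_id, "class": cls, "cds_pos": cds_pos,
                "protein_pos": idx + 1, "pos": g, "ref": ref_g, "alt": alt_g,
                "frequency": k,
            }
        )
    return records, truth


def _inject_variant(
    model: GeneModel,
    genome: Mapping[str, str],
    inj: Injection,
    accessions: Sequence[str],
    rng: np.random.Generator,
) -> tuple[VariantRecord, dict]:
    p = inj.protein_pos
    if p >= len(model.protein_sequence):
        raise ValueError(
            f"injection position {p} past protein end of {model.gene_id}"
        )
    carriers = frozenset(rng.choice(accessions, size=inj.frequency, replace=False))
    chrom_seq = genome[model.chrom]
    if inj.effect_class == NONSENSE:
        # seeded TGG -> TAG by G>A at codon position 2
        cds_pos = 3 * (p - 1) + 2
        g, ref_g, alt_g = _genomic_alleles(model, cds_pos, "G", "A")
        rec = VariantRecord(model.chrom, g, ref_g, alt_g, carriers)
    elif inj.effect_class == MISSENSE:
        # seeded GCT (Ala) -> CCT (Pro)
        cds_pos = 3 * (p - 1) + 1
        g, ref_g, alt_g = _genomic_alleles(model, cds_pos, "G", "C")
        rec = VariantRecord(model.chrom, g, ref_g, alt_g, carriers)
    elif inj.effect_class in (FRAMESHIFT, IN_FRAME_INDEL):
        ndel = 2 if inj.effect_class == FRAMESHIFT else 3
        cds_first = 3 * (p - 1) + 1
        g_positions = sorted(
            model.cds_to_genomic(cds_first + i) for i in range(ndel)
        )
        if g_positions[-1] - g_positions[0] != ndel - 1:
            raise ValueError(
                f"injection codon {p} of {model.gene_id} spans an exon boundary"
            )
        anchor = g_positions[0] - 1
        ref_g = chrom_seq[anchor - 1: g_positions[-1]]
        rec = VariantRecord(model.chrom, anchor, ref_g, ref_g[0], carriers)
        cds_pos = cds_first
    else:
        raise ValueError(f"cannot inject effect class {inj.effect_class!r}")
    truth = {
        "gene": model.gene_id, "class": inj.effect_class, "cds_pos": cds_pos,
        "protein_pos": p, "pos": rec.pos, "ref": rec.ref, "alt": rec.alt,
        "frequency": inj.frequency,
    }
    return rec, truth


def simulate_population(config: SimulationConfig) -> PopulationSim:
    """Generate the full synthetic population (deterministic under the seed)."""
    rng = np.random.default_rng(config.seed)
    genome, models, decoys = build_genome(config, rng)
    accessions = [f"acc{i:04d}" for i in range(1, config.n_accessions + 1)]
    by_name = {m.gene_id: m for m in models}

    variants: list[VariantRecord] = []
    truth: dict = {
        "seed": config.seed,
        "n_accessions": config.n_accessions,
        "genes": {},
        "injections": [],
    }

    inj_by_gene: dict[str, list[Injection]] = {}
    for inj in config.injections:
        inj_by_gene.setdefault(inj.gene, []).append(inj)

    for spec in config.genes:
        model = by_name[spec.name]
        exclude = frozenset(
            off
            for inj in inj_by_gene.get(spec.name, ())
            for off in range(3 * (inj.protein_pos - 1) + 1, 3 * inj.protein_pos + 1)
        )
        recs, rows = simulate_variants_for_model(
            model, spec.omega, spec.mutation_rate, accessions, rng, exclude
        )
        variants.extend(recs)
        counts = {SILENT: 0, MISSENSE: 0, NONSENSE: 0}
        for r in rows:
            counts[r["class"]] += 1
        truth["genes"][spec.name] = {
            "n_codons": spec.n_codons,
            "omega": spec.omega,
            "counts": counts,
            "variants": rows,
        }

    for inj in config.injections:
        rec, row = _inject_variant(by_name[inj.gene], genome, inj, accessions, rng)
        variants.append(rec)
        truth["injections"].append(row)

    variants.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    return PopulationSim(config, genome, models, variants, truth, accessions, decoys)


def simulate_patseq(sim: PopulationSim) -> list[TagAlignment]:
    """Draw 3'-end tags per gene with the configured CDS-internal fraction.

    Uses a generator seeded from the simulation seed (offset so tag draws do
    not perturb the population stream).  Decoy tags are placed immediately
    5' of each planted A-tract and must be removed by masking.
    """
    rng = np.random.default_rng(sim.config.seed + 1)
    by_name = {m.gene_id: m for m in sim.models}
    samples = sim.config.samples
    tags: list[TagAlignment] = []
    for pspec in sim.config.patseq:
        model = by_name[pspec.gene]
        # fixed representative sites: mid-CDS and ~120 nt past the stop
        internal_cds = max(4, 3 * ((model.protein_length // 2)))
        internal_pos = model.cds_to_genomic(internal_cds)
        sign = 1 if model.strand == "+" else -1
        utr_pos = model.stop_genomic_pos + sign * 120
        for _ in range(pspec.total_tags):
            internal = rng.random() < pspec.cds_internal_fraction
            base = internal_pos if internal else utr_pos
            pos = int(base + sign * int(rng.integers(0, 4)))
            sample = samples[int(rng.integers(0, len(samples)))]
            tags.append(TagAlignment(model.chrom, model.strand, pos, sample))
        for (t_start, t_end) in sim.decoy_tracts.get(pspec.gene, ()):
            for _ in range(pspec.decoy_tags):
                jitter = int(rng.integers(0, 3))
                if model.strand == "+":
                    pos = t_start - 1 - jitter
                else:
                    pos = t_end + 1 + jitter
                sample = samples[int(rng.integers(0, len(samples)))]
                tags.append(TagAlignment(model.chrom, model.strand, pos, sample))
    return tags


def simulate_expression(sim: PopulationSim):
    """Per-gene per-tissue expression values around the configured means."""
    import pandas as pd

    rng = np.random.default_rng(sim.config.seed + 2)
    expr = sim.config.expression
    tissues = sorted({t for v in expr.values() for t in v})
    rows = {}
    for gene, means in expr.items():
        rows[gene] = {
            t: float(means.get(t, 0.0) * rng.lognormal(0.0, 0.1))
            for t in tissues
        }
    return pd.DataFrame.from_dict(rows, orient="index")[tissues]


# -- file writers ------------------------------------------------------------

def write_fasta(genome: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def write_gff3(models: Sequence[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            lo, hi = m.cds_span
            fh.write(
                f"{m.chrom}\tpacvar\tgene\t{lo}\t{hi}\t.\t{m.strand}\t.\t"
                f"ID=gene:{m.gene_id}\n"
            )
            fh.write(
                f"{m.chrom}\tpacvar\tmRNA\t{lo}\t{hi}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id};Parent=gene:{m.gene_id}\n"
            )
            phase = 0
            for s, e in m.cds_segments:
                fh.write(
                    f"{m.chrom}\tpacvar\tCDS\t{s}\t{e}\t.\t{m.strand}\t{phase}\t"
                    f"ID=cds:{m.gene_id};Parent={m.gene_id}\n"
                )
                phase = (3 - ((e - s + 1) - phase) % 3) % 3


def write_vcf(sim: PopulationSim, path: str) -> None:
    """Plain-text VCF 4.2 with homozygous diploid genotypes per accession."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, seq in sim.genome.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sim.accessions) + "\n"
        )
        for v in sim.variants:
            gts = "\t".join(
                "1/1" if acc in v.carriers else "0/0" for acc in sim.accessions
            )
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_truth(sim: PopulationSim, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(sim.truth, fh, indent=1, sort_keys=True)


def write_outputs(sim: PopulationSim, outdir: str) -> dict[str, str]:
    """Emit FASTA/GFF3/VCF/BED/TSV/JSON for a simulation; returns paths."""
    import os

    from .patseq import write_bed6

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "fasta": os.path.join(outdir, "genome.fa"),
        "gff3": os.path.join(outdir, "genes.gff3"),
        "vcf": os.path.join(outdir, "population.vcf"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_fasta(sim.genome, paths["fasta"])
    write_gff3(sim.models, paths["gff3"])
    write_vcf(sim, paths["vcf"])
    write_truth(sim, paths["truth"])
    if sim.config.patseq:
        paths["bed"] = os.path.join(outdir, "tags.bed")
        write_bed6(simulate_patseq(sim), paths["bed"])
    if sim.config.expression:
        paths["expression"] = os.path.join(outdir, "expression.tsv")
        simulate_expression(sim).to_csv(
            paths["expression"], sep="\t", index_label="gene_id"
        )
    return paths
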
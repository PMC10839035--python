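"""Variant effect classification against translate-and-compare oracles."""

import numpy as np
import pytest

from pacvar.gene_models import revcomp, translate
from pacvar.variants import (
    FRAMESHIFT,
    IN_FRAME_INDEL,
    MISSENSE,
    NONSENSE,
    SILENT,
    STOP_LOSS,
    UNCLASSIFIABLE,
    NonCodingVariantError,
    VariantRecord,
    annotate_population,
    classify_indel,
    classify_snp,
)

from conftest import random_cds, synthetic_gene

_COMP = str.maketrans("ACGT", "TGCA")


# -- independent oracles ------------------------------------------------------

def snp_oracle(cds: str, off: int, alt: str) -> str:
    """Re-translate the full mutant CDS and diff the proteins."""
    mutant = cds[: off - 1] + alt + cds[off:]
    p_ref, p_alt = translate(cds), translate(mutant)
    if p_ref == p_alt:
        return SILENT
    i = next(k for k in range(len(p_ref)) if p_ref[k] != p_alt[k])
    if p_ref[i] == "*":
        return STOP_LOSS
    if p_alt[i] == "*":
        return NONSENSE
    return MISSENSE


def indel_oracle(cds: str, first: int, del_len: int, ins: str) -> str:
    """Rebuild the mutant CDS: frameshift iff translation diverges past the
    edit and never re-synchronizes (the reading frame downstream shifts)."""
    mutant = cds[: first - 1] + ins + cds[first - 1 + del_len:]
    net = len(ins) - del_len
    if net % 3 != 0:
        return FRAMESHIFT
    p_ref, p_mut = translate(cds), translate(mutant)
    ref_internal = p_ref[:-1]
    mut_internal = p_mut[:-1] if p_mut.endswith("*") else p_mut
    if "*" in mut_internal:
        return NONSENSE
    return IN_FRAME_INDEL


def _variant_for_cds_snp(model, genome, off: int, alt_sense: str) -> VariantRecord:
    g = model.cds_to_genomic(off)
    ref_g = genome[model.chrom][g - 1]
    alt_g = alt_sense if model.strand == "+" else alt_sense.translate(_COMP)
    return VariantRecord(model.chrom, g, ref_g, alt_g, frozenset({"a1"}))


# -- SNPs ---------------------------------------------------------------------

def test_missense_example_asp364ala(rng):
    """Codon 364 GAT (Asp) mutated to GCT (Ala) is missense at 364."""
    cds = random_cds(rng, 400)
    cds = cds[: 3 * 363] + "GAT" + cds[3 * 364:]
    model, genome = synthetic_gene(cds)
    v = _variant_for_cds_snp(model, genome, 3 * 363 + 2, "C")
    e = classify_snp(model, v)
    assert (e.effect_class, e.protein_pos, e.ref_aa, e.alt_aa) == (
        MISSENSE, 364, "D", "A")
    assert e.protein_notation == "p.Asp364Ala"


def test_third_position_silent(rng):
    cds = "ATG" + "GGT" + "TAA"  # Gly codon 2
    model, genome = synthetic_gene(cds)
    e = classify_snp(model, _variant_for_cds_snp(model, genome, 6, "C"))
    assert e.effect_class == SILENT
    assert e.protein_pos == 2


def test_stop_loss_is_its_own_class():
    cds = "ATGGGTTAA"
    model, genome = synthetic_gene(cds)
    e = classify_snp(model, _variant_for_cds_snp(model, genome, 8, "C"))  # TAA->TCA
    assert e.effect_class == STOP_LOSS


def test_non_coding_snp_raises():
    model, genome = synthetic_gene("ATGGGTTAA", exon_lens=[6, 3])
    intron_pos = model.cds_segments[0][1] + 1
    with pytest.raises(NonCodingVariantError):
        classify_snp(model, VariantRecord("chr1", intron_pos, "C", "A",
                                          frozenset({"a"})))


@pytest.mark.parametrize("strand", ["+", "-"])
def test_every_single_base_change_matches_oracle(rng, strand):
    """Exhaustive: all 9 mutants of every codon of a 20-codon CDS, vs the
    full re-translation oracle, on both strands."""
    cds = random_cds(rng, 20)
    model, genome = synthetic_gene(cds, strand=strand, exon_lens=[30, 30])
    for off in range(1, len(cds) + 1):
        for alt in "ACGT":
            if alt == cds[off - 1]:
                continue
            e = classify_snp(model, _variant_for_cds_snp(model, genome, off, alt))
            assert e.effect_class == snp_oracle(cds, off, alt), (off, alt)
            assert e.cds_pos == off


def test_strand_invariance_of_snp_effects(rng):
    """A variant and its reverse-complement representation on a mirror
    minus-strand fixture yield identical protein-level effects."""
    cds = random_cds(rng, 25)
    plus, gplus = synthetic_gene(cds, strand="+")
    minus, gminus = synthetic_gene(cds, strand="-")
    for off in range(1, len(cds) + 1):
        for alt in "ACGT":
            if alt == cds[off - 1]:
                continue
            ep = classify_snp(plus, _variant_for_cds_snp(plus, gplus, off, alt))
            em = classify_snp(minus, _variant_for_cds_snp(minus, gminus, off, alt))
            assert (ep.effect_class, ep.protein_pos, ep.ref_aa, ep.alt_aa) == (
                em.effect_class, em.protein_pos, em.ref_aa, em.alt_aa)


# -- indels -------------------------------------------------------------------

def _deletion_variant(model, genome, cds_first: int, n: int) -> VariantRecord:
    """VCF-style deletion of CDS offsets [cds_first, cds_first+n-1]."""
    gs = sorted(model.cds_to_genomic(cds_first + i) for i in range(n))
    anchor = gs[0] - 1
    chrom_seq = genome[model.chrom]
    ref = chrom_seq[anchor - 1: gs[-1]]
    return VariantRecord(model.chrom, anchor, ref, ref[0], frozenset({"a"}))


def _insertion_variant(model, genome, cds_after: int, ins_sense: str) -> VariantRecord:
    """Insertion between CDS offsets cds_after and cds_after+1."""
    if model.strand == "+":
        g = model.cds_to_genomic(cds_after)
        ins = ins_sense
    else:
        g = model.cds_to_genomic(cds_after + 1)
        ins = revcomp(ins_sense)
    chrom_seq = genome[model.chrom]
    anchor = chrom_seq[g - 1]
    return VariantRecord(model.chrom, g, anchor, anchor + ins, frozenset({"a"}))


def test_frameshift_example_asn175(rng):
    """2-nt deletion at CDS 525-526 in a gene with Asn at codon 175."""
    cds = random_cds(rng, 300)
    cds = cds[: 3 * 174] + "AACATG" + cds[3 * 176:]  # Asn175 Met176, CA at 525-526
    model, genome = synthetic_gene(cds)
    assert cds[524:526] == "CA"
    e = classify_indel(model, _deletion_variant(model, genome, 525, 2))
    assert e.effect_class == FRAMESHIFT
    assert e.notation == "p.Asn175fs/c.525_526delCA"
    assert e.frequency == 1


def test_codon_aligned_deletion_is_in_frame(rng):
    cds = random_cds(rng, 50)
    model, genome = synthetic_gene(cds)
    e = classify_indel(model, _deletion_variant(model, genome, 3 * 9 + 1, 3))
    assert e.effect_class in (IN_FRAME_INDEL, NONSENSE)
    assert e.effect_class == indel_oracle(cds, 3 * 9 + 1, 3, "")


def test_indel_spanning_cds_boundary_is_unclassifiable(rng):
    cds = random_cds(rng, 20)
    model, genome = synthetic_gene(cds, exon_lens=[30, 30])
    # deletion straddling the first exon's 3' edge into the intron
    g_last = model.cds_segments[0][1]
    chrom_seq = genome[model.chrom]
    ref = chrom_seq[g_last - 2: g_last + 2]  # one coding + intron bases
    v = VariantRecord("chr1", g_last - 1, ref, ref[0], frozenset({"a"}))
    assert classify_indel(model, v).effect_class == UNCLASSIFIABLE


@pytest.mark.parametrize("strand", ["+", "-"])
def test_random_indels_match_reconstruction_oracle(rng, strand):
    """1-6 nt deletions and insertions across a 60-codon CDS agree with the
    rebuild-and-retranslate oracle."""
    cds = random_cds(rng, 60)
    model, genome = synthetic_gene(cds, strand=strand)
    for _ in range(150):
        n = int(rng.integers(1, 7))
        if rng.random() < 0.5:
            first = int(rng.integers(2, len(cds) - n - 3))
            e = classify_indel(model, _deletion_variant(model, genome, first, n))
            expected = indel_oracle(cds, first, n, "")
        else:
            after = int(rng.integers(2, len(cds) - 4))
            ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
            e = classify_indel(model, _insertion_variant(model, genome, after, ins))
            expected = indel_oracle(cds, after + 1, 0, ins)
        assert e.effect_class == expected


def test_insertion_at_codon_boundary_names_flanking_residues(rng):
    cds = "ATG" + "TCT" + "GAT" + random_cds(rng, 20)[9:]  # Ser2 Asp3
    model, genome = synthetic_gene(cds)
    e = classify_indel(model, _insertion_variant(model, genome, 6, "C"))
    assert e.effect_class == FRAMESHIFT
    assert e.protein_notation == "p.Ser2_Asp3fs"
    assert e.cds_notation == "c.6_7insC"


# -- population annotation ----------------------------------------------------

def test_duplicate_records_merge_carriers(rng):
    cds = random_cds(rng, 20)
    model, genome = synthetic_gene(cds)
    v1 = _variant_for_cds_snp(model, genome, 4, _other_base(cds[3]))
    v1 = VariantRecord(v1.chrom, v1.pos, v1.ref, v1.alt, frozenset({"a1"}))
    v2 = VariantRecord(v1.chrom, v1.pos, v1.ref, v1.alt, frozenset({"a2"}))
    effects = annotate_population([model], [v1, v2])
    assert len(effects) == 1
    assert effects[0].frequency == 2
    assert effects[0].carriers == frozenset({"a1", "a2"})


def test_empty_variant_list_gives_empty_effects(rng):
    model, _ = synthetic_gene(random_cds(rng, 10))
    assert annotate_population([model], []) == []


def test_non_coding_records_are_skipped(rng):
    model, _ = synthetic_gene(random_cds(rng, 10))
    v = VariantRecord("chr1", 5, "C", "T", frozenset({"a"}))  # upstream pad
    assert annotate_population([model], [v]) == []


def test_class_partition_every_in_cds_snp_has_one_class(rng):
    cds = random_cds(rng, 30)
    model, genome = synthetic_gene(cds)
    classes = {MISSENSE, SILENT, NONSENSE, STOP_LOSS, UNCLASSIFIABLE}
    for off in range(1, len(cds) + 1):
        for alt in "ACGT":
            if alt == cds[off - 1]:
                continue
            e = classify_snp(model, _variant_for_cds_snp(model, genome, off, alt))
            assert e.effect_class in classes


def _other_base(b: str) -> str:
    return {"A": "G", "C": "T", "G": "A", "T": "C"}[b]
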
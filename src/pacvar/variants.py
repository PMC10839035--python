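"""Protein-level classification of population coding variants.

Each variant (SNP or short indel) is classified against a
:class:`~pacvar.gene_models.GeneModel` into one of: ``missense``, ``silent``,
``nonsense``, ``frameshift``, ``in_frame_indel``, ``stop_loss``, or
``unclassifiable``.  Notation follows the abbreviated HGVS dialect used in
population-survey tables ("p.Asn175fs/c.525_526delCA": no transcript prefix,
"fs" without extension length).

Carriers are accessions: the surveyed populations are inbred lines, so a
genotype with any alternate allele counts the accession once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pysam
from Bio.SeqUtils import seq3

from .gene_models import GeneModel, revcomp, translate

log = logging.getLogger(__name__)

MISSENSE = "missense"
SILENT = "silent"
NONSENSE = "nonsense"
FRAMESHIFT = "frameshift"
IN_FRAME_INDEL = "in_frame_indel"
STOP_LOSS = "stop_loss"
UNCLASSIFIABLE = "unclassifiable"

EFFECT_CLASSES = (
    MISSENSE,
    SILENT,
    NONSENSE,
    FRAMESHIFT,
    IN_FRAME_INDEL,
    STOP_LOSS,
    UNCLASSIFIABLE,
)

_COMP = str.maketrans("ACGTN", "TGCAN")


class NonCodingVariantError(ValueError):
    """Variant does not touch the coding region of the model."""


class ReferenceMismatchError(ValueError):
    """VCF REF allele disagrees with the reference genome/CDS."""


def aa3(aa: str) -> str:
    """Three-letter residue name; '*' maps to '*'."""
    return "*" if aa == "*" else seq3(aa)


@dataclass(frozen=True)
class VariantRecord:
    """One population variant (genomic, 1-based, as in VCF).

    ``carriers`` holds the ids of homozygous-carrier accessions; a site-list
    record without genotypes may instead give ``carrier_count``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    carriers: frozenset[str] = frozenset()
    carrier_count: int | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.chrom}:{self.pos} ref == alt")

    @property
    def frequency(self) -> int:
        if self.carriers:
            return len(self.carriers)
        return self.carrier_count or 0

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class VariantEffect:
    """Protein-level consequence of one non-redundant variant."""

    gene_id: str
    effect_class: str
    protein_pos: int | None
    ref_aa: str  # 1-letter; "" when not applicable
    alt_aa: str  # 1-letter, "*", or "fs"
    protein_notation: str
    cds_notation: str
    frequency: int
    cds_pos: int | None = None  # CDS offset of the first changed base
    ref: str = ""  # sense-strand CDS alleles (SNPs)
    alt: str = ""
    carriers: frozenset[str] = frozenset()

    @property
    def notation(self) -> str:
        if self.protein_notation and self.cds_notation:
            return f"{self.protein_notation}/{self.cds_notation}"
        return self.protein_notation or self.cds_notation

    @property
    def key(self) -> tuple[str, str, str]:
        """Non-redundancy key: distinct (gene, class, cds notation)."""
        return (self.gene_id, self.effect_class, self.cds_notation)


def trim_variant(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared suffix then prefix, keeping VCF left-alignment semantics."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def classify_snp(model: GeneModel, variant: VariantRecord) -> VariantEffect:
    """Classify a single-base substitution against one gene model."""
    if not variant.is_snp:
        raise ValueError("classify_snp requires len(ref) == len(alt) == 1")
    off = model.genomic_to_cds(variant.pos)
    if off is None:
        raise NonCodingVariantError(
            f"{variant.chrom}:{variant.pos} outside CDS of {model.gene_id}"
        )
    ref_s, alt_s = variant.ref.upper(), variant.alt.upper()
    if model.strand == "-":
        ref_s, alt_s = ref_s.translate(_COMP), alt_s.translate(_COMP)
    if model.cds_sequence[off - 1] != ref_s:
        raise ReferenceMismatchError(
            f"{model.gene_id} c.{off}: expected {model.cds_sequence[off - 1]}, "
            f"VCF says {ref_s}"
        )
    idx, codon, within = model.codon_at(off)
    mutant = codon[: within - 1] + alt_s + codon[within:]
    cds_notation = f"c.{off}{ref_s}>{alt_s}"
    if "N" in codon or "N" in mutant:
        return VariantEffect(
            model.gene_id, UNCLASSIFIABLE, idx, "", "", "", cds_notation,
            variant.frequency, cds_pos=off, ref=ref_s, alt=alt_s,
            carriers=variant.carriers,
        )
    aa_ref = translate(codon)
    aa_alt = translate(mutant)
    if aa_ref == aa_alt:
        cls, prot = SILENT, f"p.{aa3(aa_ref)}{idx}="
    elif aa_ref == "*":
        cls, prot = STOP_LOSS, f"p.*{idx}{aa3(aa_alt)}"
    elif aa_alt == "*":
        cls, prot = NONSENSE, f"p.{aa3(aa_ref)}{idx}*"
    else:
        cls, prot = MISSENSE, f"p.{aa3(aa_ref)}{idx}{aa3(aa_alt)}"
    return VariantEffect(
        model.gene_id, cls, idx, aa_ref, aa_alt, prot, cds_notation,
        variant.frequency, cds_pos=off, ref=ref_s, alt=alt_s,
        carriers=variant.carriers,
    )


def _unclassifiable(model: GeneModel, variant: VariantRecord) -> VariantEffect:
    return VariantEffect(
        model.gene_id, UNCLASSIFIABLE, None, "", "", "",
        f"g.{variant.pos}{variant.ref}>{variant.alt}", variant.frequency,
        carriers=variant.carriers,
    )


def classify_indel(model: GeneModel, variant: VariantRecord) -> VariantEffect:
    """Classify a short insertion or deletion against one gene model.

    The indel footprint must lie fully inside the CDS; edits that span a
    CDS boundary (splice junction or UTR) are ``unclassifiable``.
    """
    pos, ref, alt = trim_variant(variant.pos, variant.ref.upper(), variant.alt.upper())
    if len(ref) == len(alt):
        raise ValueError("classify_indel requires an insertion or a deletion")
    # strip the VCF anchor base shared at the left edge
    if ref and alt and ref[0] == alt[0]:
        pos += 1
        ref, alt = ref[1:], alt[1:]
    if ref and alt:
        return _unclassifiable(model, variant)  # complex substitution

    if ref:  # deletion of `ref` at genomic [pos, pos+len-1]
        offs = [model.genomic_to_cds(p) for p in range(pos, pos + len(ref))]
        if any(o is None for o in offs):
            return _unclassifiable(model, variant)
        offs = sorted(offs)  # minus strand maps descending
        if offs[-1] - offs[0] != len(offs) - 1:
            return _unclassifiable(model, variant)  # spans an intron
        c_start, c_end = offs[0], offs[-1]
        del_seq = model.cds_sequence[c_start - 1: c_end]
        mutant = model.cds_sequence[: c_start - 1] + model.cds_sequence[c_end:]
        first_changed = c_start
        if len(del_seq) == 1:
            cds_notation = f"c.{c_start}del{del_seq}"
        else:
            cds_notation = f"c.{c_start}_{c_end}del{del_seq}"
        net = -len(del_seq)
    else:  # insertion of `alt` between genomic pos-1 and pos
        left, right = pos - 1, pos
        o_left = model.genomic_to_cds(left)
        o_right = model.genomic_to_cds(right)
        if o_left is None or o_right is None:
            return _unclassifiable(model, variant)
        lo, hi = sorted((o_left, o_right))
        if hi - lo != 1:
            return _unclassifiable(model, variant)
        ins = alt if model.strand == "+" else revcomp(alt)
        mutant = model.cds_sequence[:lo] + ins + model.cds_sequence[lo:]
        first_changed = lo + 1
        cds_notation = f"c.{lo}_{hi}ins{ins}"
        net = len(ins)

    freq = variant.frequency
    if net % 3 != 0:
        idx = (first_changed - 1) // 3 + 1
        aa = translate(model.codon_at(min(first_changed, len(model.cds_sequence)))[1])
        if net > 0 and (first_changed - 1) % 3 == 0 and idx > 1:
            # insertion at a codon boundary: name both flanking residues
            aa_prev = model.protein_sequence[idx - 2]
            prot = f"p.{aa3(aa_prev)}{idx - 1}_{aa3(aa)}{idx}fs"
        else:
            prot = f"p.{aa3(aa)}{idx}fs"
        return VariantEffect(
            model.gene_id, FRAMESHIFT, idx, aa, "fs", prot, cds_notation, freq,
            cds_pos=first_changed, carriers=variant.carriers,
        )

    # in-frame: re-translate to catch a newly introduced stop
    prot_mut = translate(mutant)
    idx = (first_changed - 1) // 3 + 1
    aa = model.protein_sequence[idx - 1]
    internal = prot_mut[:-1] if prot_mut.endswith("*") else prot_mut
    if "*" in internal:
        stop_at = internal.index("*") + 1
        prot = f"p.{aa3(aa)}{idx}_ins*" if net > 0 else f"p.{aa3(aa)}{idx}del*"
        return VariantEffect(
            model.gene_id, NONSENSE, stop_at, aa, "*", prot, cds_notation, freq,
            cds_pos=first_changed, carriers=variant.carriers,
        )
    op = "ins" if net > 0 else "del"
    prot = f"p.{aa3(aa)}{idx}{op}"
    return VariantEffect(
        model.gene_id, IN_FRAME_INDEL, idx, aa, op, prot, cds_notation, freq,
        cds_pos=first_changed, carriers=variant.carriers,
    )


def classify_variant(model: GeneModel, variant: VariantRecord) -> VariantEffect:
    if variant.is_snp:
        return classify_snp(model, variant)
    return classify_indel(model, variant)


def _owner(models: Sequence[GeneModel], v: VariantRecord) -> GeneModel | None:
    for m in models:
        if m.chrom != v.chrom:
            continue
        span = range(v.pos, v.pos + max(len(v.ref), 1))
        if any(m.genomic_to_cds(p) is not None for p in span):
            return m
    return None


def annotate_population(
    models: Sequence[GeneModel], variants: Iterable[VariantRecord]
) -> list[VariantEffect]:
    """Classify every variant and merge duplicates into non-redundant effects.

    One effect per distinct (gene, chrom, pos, ref, alt); carrier sets are
    unioned so the frequency counts distinct accessions.  Variants outside
    every model's CDS are skipped with a log entry.
    """
    merged: dict[tuple, VariantRecord] = {}
    owners: dict[tuple, GeneModel] = {}
    for v in variants:
        m = _owner(models, v)
        if m is None:
            log.info("non-coding variant skipped: %s:%s %s>%s",
                     v.chrom, v.pos, v.ref, v.alt)
            continue
        key = (m.gene_id, v.chrom, v.pos, v.ref.upper(), v.alt.upper())
        if key in merged:
            prev = merged[key]
            merged[key] = replace(
                prev,
                carriers=prev.carriers | v.carriers,
                carrier_count=(prev.carrier_count or 0) + (v.carrier_count or 0)
                if not (prev.carriers or v.carriers)
                else None,
            )
        else:
            merged[key] = v
            owners[key] = m
    effects = []
    for key, v in merged.items():
        try:
            effects.append(classify_variant(owners[key], v))
        except (NonCodingVariantError, ReferenceMismatchError) as exc:
            log.warning("skipped %s: %s", key, exc)
    return effects


def read_vcf(path: str) -> list[VariantRecord]:
    """Read a VCF 4.x into :class:`VariantRecord` objects.

    Multi-allelic sites are split into biallelic records.  With per-sample
    genotypes, an accession carrying any copy of the alternate allele is a
    carrier; without samples, the carrier count is taken from INFO/AC.
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            for ai, alt in enumerate(rec.alts or (), start=1):
                if samples:
                    carriers = frozenset(
                        s for s in samples
                        if ai in (rec.samples[s].get("GT") or ())
                    )
                    if not carriers:
                        continue
                    records.append(
                        VariantRecord(rec.chrom, rec.pos, rec.ref, alt, carriers)
                    )
                else:
                    ac = rec.info.get("AC")
                    count = (
                        ac[ai - 1] if isinstance(ac, tuple) else ac
                    ) if ac is not None else 1
                    records.append(
                        VariantRecord(
                            rec.chrom, rec.pos, rec.ref, alt,
                            carrier_count=int(count),
                        )
                    )
    return records
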
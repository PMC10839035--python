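"""Strand-aware coding gene models built from GFF3 + FASTA.

A :class:`GeneModel` stores the CDS of one transcript as an ordered list of
genomic segments (1-based, inclusive, in translation order), the spliced
sense-strand CDS sequence, and its translation.  Minus-strand genes are
reverse-complemented into sense orientation on load.  The module also
supports merge directives that concatenate split annotations (e.g. two
adjacent gene models that together encode a single ORF) into one model.

Coordinate conventions: GFF3 and VCF are 1-based inclusive and are kept that
way internally; BED input (handled in :mod:`pacvar.patseq`) is converted
from 0-based half-open on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import gffutils
from Bio.Seq import Seq
from pyfaidx import Fasta

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a CDS with the standard nuclear code ('*' for stops)."""
    return str(Seq(cds).translate(table=1))


class IncompleteCDSError(ValueError):
    """CDS length is not a multiple of 3."""


class MergeError(ValueError):
    """A merge directive produced an invalid ORF."""


@dataclass(frozen=True)
class MergeDirective:
    """Concatenate the CDS of several annotations into one model.

    ``input_gene_ids`` are given in translation order (5'->3' of the mRNA).
    All inputs must share a chromosome and strand.
    """

    output_gene_id: str
    input_gene_ids: tuple[str, ...]
    display_name: str | None = None

    def __post_init__(self) -> None:
        if len(self.input_gene_ids) < 2:
            raise MergeError(
                f"merge {self.output_gene_id}: needs at least two inputs"
            )


@dataclass
class GeneModel:
    """One transcript's coding region in sense orientation.

    ``cds_segments`` are (start, end) genomic intervals, 1-based inclusive
    with start <= end, ordered 5'->3' along the mRNA (descending genomic
    coordinates for minus-strand genes).
    """

    gene_id: str
    display_name: str
    chrom: str
    strand: str
    cds_segments: list[tuple[int, int]]
    cds_sequence: str
    protein_sequence: str

    @property
    def stop_genomic_pos(self) -> int:
        """Genomic coordinate of the last base of the stop codon."""
        last = self.cds_segments[-1]
        return last[1] if self.strand == "+" else last[0]

    @property
    def protein_length(self) -> int:
        """Number of residues excluding the terminal stop."""
        return len(self.protein_sequence) - 1

    @property
    def cds_span(self) -> tuple[int, int]:
        """Genomic (min, max) over all CDS segments."""
        starts = [s for s, _ in self.cds_segments]
        ends = [e for _, e in self.cds_segments]
        return min(starts), max(ends)

    def validate(self) -> None:
        n = sum(e - s + 1 for s, e in self.cds_segments)
        if len(self.cds_sequence) != n:
            raise ValueError(f"{self.gene_id}: segment/sequence length mismatch")
        if n % 3 != 0:
            raise IncompleteCDSError(f"incomplete CDS: {self.gene_id}")
        prot = translate(self.cds_sequence)
        if prot != self.protein_sequence:
            raise ValueError(f"{self.gene_id}: stored protein does not match CDS")
        if not prot.endswith("*"):
            raise ValueError(f"{self.gene_id}: CDS does not end with a stop codon")
        if "*" in prot[:-1]:
            raise ValueError(f"{self.gene_id}: internal stop codon")
        # segments non-overlapping
        ivs = sorted(self.cds_segments)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping CDS segments")

    # -- coordinate mapping -------------------------------------------------

    def genomic_to_cds(self, pos: int) -> int | None:
        """1-based CDS offset of genomic position ``pos``, or None if non-coding."""
        off = 0
        for s, e in self.cds_segments:
            if s <= pos <= e:
                if self.strand == "+":
                    return off + (pos - s) + 1
                return off + (e - pos) + 1
            off += e - s + 1
        return None

    def cds_to_genomic(self, cds_offset: int) -> int:
        """Inverse of :meth:`genomic_to_cds` over coding positions."""
        if not 1 <= cds_offset <= len(self.cds_sequence):
            raise IndexError(f"CDS offset {cds_offset} out of range")
        off = cds_offset - 1
        for s, e in self.cds_segments:
            seg_len = e - s + 1
            if off < seg_len:
                return s + off if self.strand == "+" else e - off
            off -= seg_len
        raise AssertionError("unreachable")

    def codon_at(self, cds_offset: int) -> tuple[int, str, int]:
        """Return (codon_index, codon, within-codon position 1..3)."""
        if not 1 <= cds_offset <= len(self.cds_sequence):
            raise IndexError(f"CDS offset {cds_offset} out of range")
        idx = (cds_offset - 1) // 3 + 1
        codon = self.cds_sequence[3 * (idx - 1): 3 * idx]
        return idx, codon, (cds_offset - 1) % 3 + 1


def _segments_from_gff(db: gffutils.FeatureDB, transcript_id: str):
    feats = [
        f
        for f in db.features_of_type("CDS")
        if transcript_id in f.attributes.get("Parent", [])
    ]
    if not feats:
        raise KeyError(f"no CDS features for transcript {transcript_id}")
    strand = feats[0].strand
    chrom = feats[0].seqid
    feats.sort(key=lambda f: f.start, reverse=(strand == "-"))
    return chrom, strand, [(f.start, f.end) for f in feats]


def _build_model(
    gene_id: str,
    display_name: str,
    chrom: str,
    strand: str,
    segments: list[tuple[int, int]],
    genome: Mapping[str, str] | Fasta,
    validate: bool = True,
) -> GeneModel:
    parts = []
    for s, e in segments:
        chunk = str(genome[chrom][s - 1: e])
        parts.append(chunk if strand == "+" else revcomp(chunk))
    cds = "".join(parts).upper()
    if validate and len(cds) % 3 != 0:
        raise IncompleteCDSError(f"incomplete CDS: {gene_id}")
    model = GeneModel(
        gene_id=gene_id,
        display_name=display_name,
        chrom=chrom,
        strand=strand,
        cds_segments=list(segments),
        cds_sequence=cds,
        protein_sequence=translate(cds) if len(cds) % 3 == 0 else "",
    )
    if validate:
        model.validate()
    return model


def _merge_models(directive: MergeDirective, parts: Sequence[GeneModel]) -> GeneModel:
    chroms = {m.chrom for m in parts}
    strands = {m.strand for m in parts}
    if len(chroms) != 1 or len(strands) != 1:
        raise MergeError(
            f"merge {directive.output_gene_id}: inputs on different chromosomes/strands"
        )
    strand = strands.pop()
    segments: list[tuple[int, int]] = []
    seq_parts: list[str] = []
    for i, m in enumerate(parts):
        segs = list(m.cds_segments)
        seq = m.cds_sequence
        # Upstream constituents: drop a terminal stop so the merged CDS has
        # exactly one stop, at its end.
        if i < len(parts) - 1 and seq[-3:] in STOP_CODONS:
            seq = seq[:-3]
            s, e = segs[-1]
            if e - s + 1 <= 3:
                segs = segs[:-1]
            else:
                segs[-1] = (s + 3, e) if strand == "-" else (s, e - 3)
        segments.extend(segs)
        seq_parts.append(seq)
    cds = "".join(seq_parts)
    if len(cds) % 3 != 0:
        raise IncompleteCDSError(f"incomplete CDS: {directive.output_gene_id}")
    prot = translate(cds)
    if "*" in prot[:-1]:
        raise MergeError(f"merge produced internal stop: {directive.output_gene_id}")
    model = GeneModel(
        gene_id=directive.output_gene_id,
        display_name=directive.display_name or directive.output_gene_id,
        chrom=chroms.pop(),
        strand=strand,
        cds_segments=segments,
        cds_sequence=cds,
        protein_sequence=prot,
    )
    model.validate()
    return model


def load_gene_models(
    gff3: str,
    fasta: str,
    transcripts: Mapping[str, str] | Sequence[str] | None = None,
    merges: Sequence[MergeDirective] = (),
) -> list[GeneModel]:
    """Build :class:`GeneModel` objects from a GFF3 and a genome FASTA.

    Parameters
    ----------
    gff3, fasta
        Paths to the annotation and genome files.
    transcripts
        Transcript ids to load; a mapping gives ``{transcript_id:
        display_name}``.  ``None`` loads every transcript with CDS features.
    merges
        Directives whose constituents are concatenated in translation order
        into a single model (the upstream constituent's stop codon, if
        present, is dropped).  Constituent ids are consumed by the merge and
        not reported separately.
    """
    db = gffutils.create_db(
        gff3, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genome = Fasta(fasta, sequence_always_upper=True)

    if transcripts is None:
        ids = sorted(
            {
                p
                for f in db.features_of_type("CDS")
                for p in f.attributes.get("Parent", [])
            }
        )
        names = {t: t for t in ids}
    elif isinstance(transcripts, Mapping):
        names = dict(transcripts)
    else:
        names = {t: t for t in transcripts}

    merged_inputs = {g for m in merges for g in m.input_gene_ids}
    models: dict[str, GeneModel] = {}
    for tid in names:
        chrom, strand, segs = _segments_from_gff(db, tid)
        # merge constituents need not be valid standalone ORFs
        models[tid] = _build_model(
            tid, names[tid], chrom, strand, segs, genome,
            validate=tid not in merged_inputs,
        )

    out: list[GeneModel] = []
    for tid, model in models.items():
        if tid not in merged_inputs:
            out.append(model)
    for directive in merges:
        missing = [g for g in directive.input_gene_ids if g not in models]
        if missing:
            # merge inputs need not be in the requested set; load on demand
            for g in missing:
                chrom, strand, segs = _segments_from_gff(db, g)
                models[g] = _build_model(g, g, chrom, strand, segs, genome,
                                         validate=False)
        out.append(
            _merge_models(directive, [models[g] for g in directive.input_gene_ids])
        )
    return out
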
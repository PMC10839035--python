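"""Shared fixtures: in-memory synthetic gene models and tiny genomes."""

from __future__ import annotations

import numpy as np
import pytest

from pacvar.gene_models import GeneModel, revcomp, translate

STOPS = {"TAA", "TAG", "TGA"}
BASES = "ACGT"
SENSE_CODONS = [
    a + b + c for a in BASES for b in BASES for c in BASES
    if a + b + c not in STOPS
]


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random sense codons + TAA."""
    body = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS),
                                                  size=n_codons - 2)]
    return "ATG" + "".join(body) + "TAA"


def synthetic_gene(
    cds: str,
    strand: str = "+",
    exon_lens: list[int] | None = None,
    left: int = 101,
    intron: int = 47,
    chrom: str = "chr1",
    pad: int = 200,
) -> tuple[GeneModel, dict[str, str]]:
    """Place ``cds`` on a synthetic chromosome and return (model, genome).

    ``exon_lens`` are CDS-order exon lengths (must sum to len(cds)); introns
    are C-runs so they can never harbour stops, A-tracts, or ref mismatches.
    """
    if exon_lens is None:
        exon_lens = [len(cds)]
    assert sum(exon_lens) == len(cds)
    gene_sense = cds if strand == "+" else revcomp(cds)
    genomic_lens = exon_lens if strand == "+" else exon_lens[::-1]

    segs: list[tuple[int, int]] = []
    parts: list[str] = ["C" * (left - 1)]
    cur = left
    off = 0
    for i, L in enumerate(genomic_lens):
        segs.append((cur, cur + L - 1))
        parts.append(gene_sense[off: off + L])
        off += L
        cur += L
        if i < len(genomic_lens) - 1:
            parts.append("C" * intron)
            cur += intron
    parts.append("C" * pad)
    genome = {chrom: "".join(parts)}

    translation_order = segs if strand == "+" else segs[::-1]
    model = GeneModel(
        gene_id="toy",
        display_name="toy",
        chrom=chrom,
        strand=strand,
        cds_segments=translation_order,
        cds_sequence=cds,
        protein_sequence=translate(cds),
    )
    model.validate()
    return model, genome


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
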
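"""Poly(A)-site calling from 3'-end tag alignments (PAT-seq style).

The 3'-most base of each tag marks an mRNA-poly(A) junction.  Genomic
A-tracts cause internal-priming artifacts: oligo(dT) anneals to the tract
and the apparent junction lands immediately 5' of it.  Tags whose ends fall
inside a masked window (the tract plus an upstream flank, on the tag's sense
strand) are discarded before clustering.

Surviving ends are single-linkage clustered within a merge window into
:class:`PolyASiteCall` peaks, classified into zones relative to a gene model
(CDS-internal, 3' side of the stop codon, 5' UTR, intronic, antisense), and
summarised as a per-gene nonstop fraction: the share of sense-strand tags
whose poly(A) site lies inside the protein-coding region.  Transcripts
polyadenylated there lack a stop codon and are nonstop-decay substrates.
"""

from __future__ import annotations

import bisect
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pyfaidx import Fasta

from .gene_models import GeneModel

CDS_INTERNAL = "cds_internal"
THREE_PRIME = "three_prime_utr"
FIVE_PRIME = "five_prime_utr"
INTRONIC = "intronic"
ANTISENSE = "antisense"
INTERGENIC = "intergenic"

SENSE_ZONES = (CDS_INTERNAL, THREE_PRIME, FIVE_PRIME, INTRONIC)


@dataclass(frozen=True)
class TagAlignment:
    """One aligned 3'-end tag: the coordinate of its 3'-most base."""

    chrom: str
    strand: str
    three_prime_end: int  # 1-based genomic
    sample_id: str = "pooled"


@dataclass
class PolyASiteCall:
    chrom: str
    strand: str
    position: int  # modal junction coordinate of the cluster
    tag_count: int
    sample_counts: dict[str, int] = field(default_factory=dict)
    gene_id: str | None = None
    zone: str = INTERGENIC


def read_bed6(path: str) -> list[TagAlignment]:
    """Read tag 3' ends from BED6 (name = sample id, strand required).

    The BED interval is the junction base: 0-based half-open, so the 1-based
    3' end is ``end`` for + tags and ``start + 1`` for - tags.
    """
    tags = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"BED6 required, got {len(f)} fields: {line}")
            chrom, start, end, name, _score, strand = f[:6]
            pos = int(end) if strand == "+" else int(start) + 1
            tags.append(TagAlignment(chrom, strand, pos, name))
    return tags


def write_bed6(tags: Sequence[TagAlignment], path: str) -> None:
    with open(path, "w") as fh:
        for t in tags:
            fh.write(
                f"{t.chrom}\t{t.three_prime_end - 1}\t{t.three_prime_end}\t"
                f"{t.sample_id}\t0\t{t.strand}\n"
            )


class AMask:
    """Masked intervals per (chrom, strand), sorted and merged."""

    def __init__(self, intervals: Mapping[tuple[str, str], list[tuple[int, int]]]):
        self.intervals = {
            key: _merge_intervals(ivs) for key, ivs in intervals.items()
        }
        self._starts = {
            key: [s for s, _ in ivs] for key, ivs in self.intervals.items()
        }

    def contains(self, chrom: str, strand: str, pos: int) -> bool:
        key = (chrom, strand)
        ivs = self.intervals.get(key)
        if not ivs:
            return False
        i = bisect.bisect_right(self._starts[key], pos) - 1
        return i >= 0 and ivs[i][0] <= pos <= ivs[i][1]


def _merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _runs(seq: str, base: str, min_run: int) -> list[tuple[int, int]]:
    """1-based (start, end) of maximal runs of ``base`` of length >= min_run."""
    runs = []
    i, n = 0, len(seq)
    while i < n:
        if seq[i] == base:
            j = i
            while j < n and seq[j] == base:
                j += 1
            if j - i >= min_run:
                runs.append((i + 1, j))
            i = j
        else:
            i += 1
    return runs


def build_a_mask(
    genome: str | Mapping[str, str], min_run: int = 8, flank: int = 20
) -> AMask:
    """Mask internal-priming windows around genomic A-tracts.

    For + tags the oligo(dT) target is an A-run on the plus strand and the
    spurious junction sits 5' (left) of it, so the run plus ``flank`` bases
    upstream are masked.  For - tags the target is a T-run on the plus
    strand (an A-run on the minus strand) and the flank extends right.
    ``genome`` may be a FASTA path or an in-memory {chrom: sequence} mapping.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    seqs: Mapping[str, str]
    if isinstance(genome, str):
        fa = Fasta(genome, sequence_always_upper=True)
        seqs = {name: str(fa[name][:]) for name in fa.keys()}
    else:
        seqs = {k: v.upper() for k, v in genome.items()}
    intervals: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for chrom, seq in seqs.items():
        plus = [
            (max(1, s - flank), e) for s, e in _runs(seq, "A", min_run)
        ]
        minus = [
            (s, min(len(seq), e + flank)) for s, e in _runs(seq, "T", min_run)
        ]
        if plus:
            intervals[(chrom, "+")] = plus
        if minus:
            intervals[(chrom, "-")] = minus
    return AMask(intervals)


def filter_tags(tags: Iterable[TagAlignment], mask: AMask) -> list[TagAlignment]:
    """Drop tags whose 3' end falls in a masked interval on its strand."""
    return [
        t for t in tags
        if not mask.contains(t.chrom, t.strand, t.three_prime_end)
    ]


def cluster_sites(
    tags: Sequence[TagAlignment], merge_window: int = 24
) -> list[PolyASiteCall]:
    """Single-linkage clustering of tag 3' ends within ``merge_window`` nt.

    Tags on the same chromosome and strand whose ends are separated by at
    most the window (chained) form one site; the representative position is
    the modal end (smallest on ties) and the tag count is the cluster size.
    """
    by_key: dict[tuple[str, str], list[TagAlignment]] = {}
    for t in tags:
        by_key.setdefault((t.chrom, t.strand), []).append(t)
    sites = []
    for (chrom, strand), group in sorted(by_key.items()):
        group.sort(key=lambda t: t.three_prime_end)
        cluster: list[TagAlignment] = []
        for t in group:
            if cluster and t.three_prime_end - cluster[-1].three_prime_end > merge_window:
                sites.append(_make_site(chrom, strand, cluster))
                cluster = []
            cluster.append(t)
        if cluster:
            sites.append(_make_site(chrom, strand, cluster))
    return sites


def _make_site(chrom: str, strand: str, cluster: Sequence[TagAlignment]) -> PolyASiteCall:
    ends = Counter(t.three_prime_end for t in cluster)
    modal = min(
        (pos for pos, c in ends.items() if c == max(ends.values()))
    )
    samples = Counter(t.sample_id for t in cluster)
    return PolyASiteCall(chrom, strand, modal, len(cluster), dict(samples))


def classify_site(
    site: PolyASiteCall,
    model: GeneModel,
    downstream_extent: int = 500,
    upstream_extent: int = 500,
) -> str:
    """Zone of a poly(A) site relative to one gene model."""
    if site.chrom != model.chrom:
        return INTERGENIC
    lo, hi = model.cds_span
    pos = site.position
    if site.strand != model.strand:
        if lo <= pos <= hi:
            return ANTISENSE
        return INTERGENIC
    if model.genomic_to_cds(pos) is not None:
        return CDS_INTERNAL
    if lo <= pos <= hi:
        return INTRONIC
    if model.strand == "+":
        if hi < pos <= hi + downstream_extent:
            return THREE_PRIME
        if lo - upstream_extent <= pos < lo:
            return FIVE_PRIME
    else:
        if lo - downstream_extent <= pos < lo:
            return THREE_PRIME
        if hi < pos <= hi + upstream_extent:
            return FIVE_PRIME
    return INTERGENIC


def assign_sites(
    sites: Iterable[PolyASiteCall],
    models: Sequence[GeneModel],
    downstream_extent: int = 500,
    upstream_extent: int = 500,
) -> list[PolyASiteCall]:
    """Attach each site to the first gene giving a non-intergenic zone."""
    out = []
    for site in sites:
        site.gene_id, site.zone = None, INTERGENIC
        for m in models:
            zone = classify_site(site, m, downstream_extent, upstream_extent)
            if zone != INTERGENIC:
                site.gene_id, site.zone = m.gene_id, zone
                break
        out.append(site)
    return out


def nonstop_fraction(sites: Iterable[PolyASiteCall]) -> float | None:
    """Fraction of a gene's sense-strand tags at CDS-internal sites.

    Returns None (missing, not 0) when the gene has no sense-strand tags.
    """
    internal = total = 0
    for s in sites:
        if s.zone in SENSE_ZONES:
            total += s.tag_count
            if s.zone == CDS_INTERNAL:
                internal += s.tag_count
    if total == 0:
        return None
    return internal / total


def gene_nonstop_table(
    sites: Sequence[PolyASiteCall], per_sample: bool = True
) -> pd.DataFrame:
    """Pooled (and optionally per-sample) nonstop fraction per gene."""
    genes = sorted({s.gene_id for s in sites if s.gene_id})
    rows = []
    for g in genes:
        gsites = [s for s in sites if s.gene_id == g]
        row: dict[str, object] = {
            "gene_id": g,
            "nonstop_fraction": nonstop_fraction(gsites),
            "tags": sum(s.tag_count for s in gsites if s.zone in SENSE_ZONES),
        }
        if per_sample:
            samples = sorted({k for s in gsites for k in s.sample_counts})
            for sample in samples:
                internal = sum(
                    s.sample_counts.get(sample, 0)
                    for s in gsites if s.zone == CDS_INTERNAL
                )
                total = sum(
                    s.sample_counts.get(sample, 0)
                    for s in gsites if s.zone in SENSE_ZONES
                )
                row[f"nonstop_{sample}"] = internal / total if total else None
        rows.append(row)
    return pd.DataFrame(rows)
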
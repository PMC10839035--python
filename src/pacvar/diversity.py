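"""Per-gene synonymous / nonsynonymous nucleotide diversity (pi_N / pi_S).

Site counting follows Nei & Gojobori: each position of each non-stop codon
contributes f_syn = (synonymous single-base neighbours) / 3 to the
synonymous site total and 1 - f_syn to the nonsynonymous total, so
n_sites + s_sites = 3 x (number of non-stop codons).  Changes that create a
stop codon count as nonsynonymous.

Per-site diversity is the unbiased heterozygosity over accessions,
pi_site = n/(n-1) * (1 - sum p_i^2), summed over polymorphic sites of each
class and normalised by the corresponding site total.  The ratio pi_N/pi_S
places each gene in one of three selection groups: purifying (< 0.8),
intermediate (0.8-1.5, closed interval), diversifying (> 1.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .gene_models import GeneModel, translate
from .variants import MISSENSE, NONSENSE, SILENT, VariantEffect

log = logging.getLogger(__name__)

PURIFYING = "purifying"
INTERMEDIATE = "intermediate"
DIVERSIFYING = "diversifying"
UNDEFINED = "undefined"

_BASES = "ACGT"


@dataclass(frozen=True)
class SiteCounts:
    gene_id: str
    n_sites: float
    s_sites: float


@dataclass(frozen=True)
class DiversityResult:
    gene_id: str
    pi_n: float
    pi_s: float
    ratio: float | None
    group: str
    n_syn_polymorphic: int = 0
    n_nonsyn_polymorphic: int = 0


def codon_site_fractions(codon: str) -> list[float]:
    """Synonymous fraction f_syn at each of the codon's three positions."""
    aa = translate(codon)
    fractions = []
    for i in range(3):
        syn = sum(
            1
            for b in _BASES
            if b != codon[i] and translate(codon[:i] + b + codon[i + 1:]) == aa
        )
        fractions.append(syn / 3)
    return fractions


def count_sites(model: GeneModel) -> SiteCounts:
    """Nei-Gojobori expected site counts; the terminal stop codon is excluded.

    Codons containing an ambiguity base contribute to neither tally.
    """
    n_sites = s_sites = 0.0
    cds = model.cds_sequence
    for i in range(0, len(cds) - 3, 3):  # stop codon excluded
        codon = cds[i: i + 3]
        if "N" in codon:
            log.info("%s: codon %d contains N, excluded from site counts",
                     model.gene_id, i // 3 + 1)
            continue
        for f in codon_site_fractions(codon):
            s_sites += f
            n_sites += 1 - f
    return SiteCounts(model.gene_id, n_sites, s_sites)


def site_pi(allele_counts: Sequence[int], n: int) -> float:
    """Unbiased per-site diversity over ``n`` accessions.

    ``allele_counts`` are carrier counts per allele (including the
    reference) and must sum to ``n``.
    """
    if n < 2:
        raise ValueError("site_pi requires n >= 2 accessions")
    if sum(allele_counts) != n:
        raise ValueError("allele counts must sum to n")
    het = 1.0 - sum((c / n) ** 2 for c in allele_counts)
    return n / (n - 1) * het


def classify_ratio(
    ratio: float | None, boundaries: tuple[float, float] = (0.8, 1.5)
) -> str:
    if ratio is None:
        return UNDEFINED
    lo, hi = boundaries
    if ratio < lo:
        return PURIFYING
    if ratio > hi:
        return DIVERSIFYING
    return INTERMEDIATE


def gene_diversity(
    model: GeneModel,
    effects: Iterable[VariantEffect],
    n_accessions: int,
    min_syn_sites: int = 1,
    boundaries: tuple[float, float] = (0.8, 1.5),
) -> DiversityResult:
    """Collective pi_N, pi_S, their ratio, and the selection group for a gene.

    Only classified SNPs enter: silent ones are synonymous; missense and
    nonsense are nonsynonymous.  Frameshifts and other indels are excluded
    (pi is a per-site substitution statistic).  With fewer than
    ``min_syn_sites`` synonymous polymorphic sites, or pi_S = 0, the ratio
    and group are undefined.
    """
    if n_accessions < 1:
        raise ValueError("n_accessions must be >= 1")
    sites = count_sites(model)

    by_site: dict[tuple[int, str], list[int]] = {}
    for e in effects:
        if e.gene_id != model.gene_id or e.cds_pos is None:
            continue
        if e.effect_class == SILENT:
            cls = "syn"
        elif e.effect_class in (MISSENSE, NONSENSE):
            cls = "nonsyn"
        else:
            continue
        if len(e.ref) != 1 or len(e.alt) != 1:
            continue
        by_site.setdefault((e.cds_pos, cls), []).append(e.frequency)

    pi = {"syn": 0.0, "nonsyn": 0.0}
    poly = {"syn": 0, "nonsyn": 0}
    for (pos, cls), freqs in by_site.items():
        alt_total = sum(freqs)
        if alt_total > n_accessions:
            raise ValueError(
                f"{model.gene_id} c.{pos}: carriers exceed population size"
            )
        counts = [n_accessions - alt_total, *freqs]
        pi[cls] += site_pi(counts, n_accessions)
        poly[cls] += 1

    pi_n = pi["nonsyn"] / sites.n_sites if sites.n_sites else 0.0
    pi_s = pi["syn"] / sites.s_sites if sites.s_sites else 0.0
    if pi_s == 0.0 or poly["syn"] < min_syn_sites:
        ratio = None
    else:
        ratio = pi_n / pi_s
    return DiversityResult(
        model.gene_id, pi_n, pi_s, ratio, classify_ratio(ratio, boundaries),
        n_syn_polymorphic=poly["syn"], n_nonsyn_polymorphic=poly["nonsyn"],
    )
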
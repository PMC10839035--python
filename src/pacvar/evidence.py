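"""Per-gene pseudogene-evidence reports.

Four independent evidence classes are evaluated from the upstream modules:

* disruption — a severe (non-C-terminal) nonsense (rule R1) or frameshift
  (rule R2) segregating at or above a frequency threshold;
* nonstop transcription — a majority of poly(A) sites inside the CDS (R3);
* expression — normalized expression near the floor (R4);
* diversity — a heavy missense burden on a gene whose pi_N/pi_S group is
  diversifying or undefined (R5).

A gene is called ``pseudogene_candidate`` when at least two evidence classes
trigger (R1 and R2 are one class: a single fixed truncation, however it
arose, is not two independent observations).  A gene whose only evidence is
disruption is a ``dispensable_candidate`` — intact in most accessions but
tolerating loss in some.  Everything else is ``functional``.  Missing
signals (no PAT-seq tags, no expression data) never trigger a rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .diversity import DIVERSIFYING, UNDEFINED
from .variants import FRAMESHIFT, NONSENSE, VariantEffect

FUNCTIONAL = "functional"
DISPENSABLE = "dispensable_candidate"
PSEUDOGENE = "pseudogene_candidate"

SEVERE = "severe"
C_TERMINAL = "c_terminal"


@dataclass(frozen=True)
class RuleConfig:
    """Thresholds for the evidence rules; all configurable.

    ``severe_cutoff``: a truncation before this fraction of the protein
    length is severe.  ``min_truncation_frequency``: accession count at or
    above which a severe truncation triggers R1/R2 (1 = any accession; the
    surveyed lines are inbred, so even a private homozygous truncation is an
    intact-gene knockout).  ``nonstop_threshold``: minimum CDS-internal tag
    fraction for R3.  ``expression_threshold``: maximum normalized
    expression (floor = 1) for R4.  ``missense_threshold``: minimum count of
    distinct missense variants for R5.
    """

    severe_cutoff: float = 0.90
    min_truncation_frequency: int = 1
    nonstop_threshold: float = 0.5
    expression_threshold: float = 2.0
    missense_threshold: int = 100

    def __post_init__(self) -> None:
        for name in ("severe_cutoff", "nonstop_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_truncation_frequency < 1:
            raise ValueError("min_truncation_frequency must be >= 1")


@dataclass(frozen=True)
class TruncatingVariant:
    """Minimal view of a nonsense or frameshift effect for rule evaluation."""

    effect_class: str
    protein_pos: int
    frequency: int


@dataclass
class GeneSignals:
    """All signals for one gene; nonstop and expression may be missing."""

    gene_id: str
    protein_length: int
    truncations: list[TruncatingVariant] = field(default_factory=list)
    missense_count: int = 0
    pi_ratio_group: str = UNDEFINED
    nonstop_fraction: float | None = None
    relative_expression: float | None = None


@dataclass
class EvidenceReport:
    gene_id: str
    n_nonsense: int
    max_nonsense_frequency: int
    n_frameshift: int
    max_frameshift_frequency: int
    severe_truncation_present: bool
    missense_count: int
    pi_ratio_group: str
    nonstop_fraction: float | None
    relative_expression: float | None
    call: str
    triggered_rules: list[str]


def severity(
    effect: VariantEffect | TruncatingVariant,
    protein_length: int,
    cutoff: float = 0.90,
) -> str:
    """'severe' if the truncation falls before ``cutoff`` of the protein."""
    if effect.effect_class not in (NONSENSE, FRAMESHIFT):
        raise ValueError("severity applies to truncating effects only")
    if effect.protein_pos is None:
        raise ValueError("truncating effect lacks a protein position")
    return SEVERE if effect.protein_pos / protein_length < cutoff else C_TERMINAL


def normalize_expression(values: Sequence[float], floor: float | None = None) -> np.ndarray:
    """Scale an expression vector so its minimum equals 1.

    Non-positive entries are replaced by ``floor`` before scaling (a floor
    must be supplied if any are present); ratios between positive values are
    preserved.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty expression vector")
    if (arr <= 0).any():
        if floor is None or floor <= 0:
            raise ValueError(
                "non-positive expression values require a positive floor"
            )
        arr = np.where(arr <= 0, floor, arr)
    return arr / arr.min()


def normalize_expression_table(df, floor: float = 0.01):
    """Per-column (per-sample) floor-to-1 normalization of a genes x tissues table."""
    return df.apply(lambda col: normalize_expression(col.values, floor=floor), axis=0)


def signals_from_effects(
    gene_id: str,
    protein_length: int,
    effects: Iterable[VariantEffect],
    pi_ratio_group: str = UNDEFINED,
    nonstop_fraction: float | None = None,
    relative_expression: float | None = None,
) -> GeneSignals:
    """Assemble :class:`GeneSignals` from classified effects for one gene."""
    truncs = []
    missense = 0
    for e in effects:
        if e.gene_id != gene_id:
            continue
        if e.effect_class in (NONSENSE, FRAMESHIFT) and e.protein_pos is not None:
            truncs.append(
                TruncatingVariant(e.effect_class, e.protein_pos, e.frequency)
            )
        elif e.effect_class == "missense":
            missense += 1
    return GeneSignals(
        gene_id, protein_length, truncs, missense, pi_ratio_group,
        nonstop_fraction, relative_expression,
    )


def evaluate_gene(signals: GeneSignals, config: RuleConfig = RuleConfig()) -> EvidenceReport:
    """Evaluate the evidence rules for one gene and make the categorical call."""
    nonsense = [t for t in signals.truncations if t.effect_class == NONSENSE]
    frameshift = [t for t in signals.truncations if t.effect_class == FRAMESHIFT]

    def severe_and_frequent(variants: list[TruncatingVariant]) -> bool:
        return any(
            severity(t, signals.protein_length, config.severe_cutoff) == SEVERE
            and t.frequency >= config.min_truncation_frequency
            for t in variants
        )

    triggered: list[str] = []
    if severe_and_frequent(nonsense):
        triggered.append("R1")
    if severe_and_frequent(frameshift):
        triggered.append("R2")
    if (
        signals.nonstop_fraction is not None
        and signals.nonstop_fraction >= config.nonstop_threshold
    ):
        triggered.append("R3")
    if (
        signals.relative_expression is not None
        and signals.relative_expression <= config.expression_threshold
    ):
        triggered.append("R4")
    if (
        signals.missense_count >= config.missense_threshold
        and signals.pi_ratio_group in (DIVERSIFYING, UNDEFINED)
    ):
        triggered.append("R5")

    classes = {
        "disruption" if r in ("R1", "R2") else r for r in triggered
    }
    if len(classes) >= 2:
        call = PSEUDOGENE
    elif classes == {"disruption"}:
        call = DISPENSABLE
    else:
        call = FUNCTIONAL

    severe_present = any(
        severity(t, signals.protein_length, config.severe_cutoff) == SEVERE
        for t in signals.truncations
    )
    return EvidenceReport(
        gene_id=signals.gene_id,
        n_nonsense=len(nonsense),
        max_nonsense_frequency=max((t.frequency for t in nonsense), default=0),
        n_frameshift=len(frameshift),
        max_frameshift_frequency=max((t.frequency for t in frameshift), default=0),
        severe_truncation_present=severe_present,
        missense_count=signals.missense_count,
        pi_ratio_group=signals.pi_ratio_group,
        nonstop_fraction=signals.nonstop_fraction,
        relative_expression=signals.relative_expression,
        call=call,
        triggered_rules=triggered,
    )


def evaluate_genes(
    all_signals: Iterable[GeneSignals], config: RuleConfig = RuleConfig()
) -> list[EvidenceReport]:
    return [evaluate_gene(s, config) for s in all_signals]
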
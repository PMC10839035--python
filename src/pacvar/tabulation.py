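"""Population summary tables: frequency spectra, high-frequency variants,
nonsense/frameshift tables, and per-accession missense burdens.

All outputs are pandas DataFrames ready for TSV export or plotting.  A
variant is "non-redundant" when its (gene, effect class, CDS notation)
tuple is distinct.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .variants import FRAMESHIFT, MISSENSE, NONSENSE, VariantEffect, aa3

#: Default accession-frequency bins: (low, high) inclusive; None = open end.
DEFAULT_BINS: tuple[tuple[int, int | None], ...] = (
    (1, 1),
    (2, 10),
    (11, 100),
    (101, 1000),
    (1001, None),
)


def _bin_label(lo: int, hi: int | None) -> str:
    if hi is None:
        return f">{lo - 1}"
    if lo == hi:
        return str(lo)
    return f"{lo}-{hi}"


def _validate_bins(bins: Sequence[tuple[int, int | None]]) -> None:
    prev_hi = 0
    for lo, hi in bins:
        if lo != prev_hi + 1:
            raise ValueError("bins must be contiguous, non-overlapping, from 1")
        if hi is not None and hi < lo:
            raise ValueError(f"bin ({lo}, {hi}) is empty")
        if hi is None:
            prev_hi = None
            break
        prev_hi = hi
    else:
        return
    if prev_hi is not None:
        raise ValueError("last bin must be open-ended or cover the maximum")


def nonredundant(effects: Iterable[VariantEffect]) -> list[VariantEffect]:
    seen: dict[tuple, VariantEffect] = {}
    for e in effects:
        seen.setdefault(e.key, e)
    return list(seen.values())


def spectrum(
    effects: Iterable[VariantEffect],
    bins: Sequence[tuple[int, int | None]] = DEFAULT_BINS,
) -> pd.DataFrame:
    """Count non-redundant variants per effect class per frequency bin.

    Returns a DataFrame indexed by effect class with one column per bin.
    """
    _validate_bins(bins)
    labels = [_bin_label(lo, hi) for lo, hi in bins]
    rows: dict[str, dict[str, int]] = {}
    for e in nonredundant(effects):
        for (lo, hi), label in zip(bins, labels):
            if e.frequency >= lo and (hi is None or e.frequency <= hi):
                rows.setdefault(e.effect_class, dict.fromkeys(labels, 0))
                rows[e.effect_class][label] += 1
                break
        else:
            raise ValueError(f"frequency {e.frequency} not covered by bins")
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    return df.reindex(columns=labels, fill_value=0)


def high_frequency_table(
    effects: Iterable[VariantEffect], threshold: int
) -> pd.DataFrame:
    """Effects seen in more than ``threshold`` accessions.

    Columns mirror the survey-table schema: Gene_Name, Wild_Type, Position,
    SNP, Frequency; rows sorted by gene, then frequency descending, then
    protein position.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    rows = [
        {
            "Gene_Name": e.gene_id,
            "Wild_Type": aa3(e.ref_aa) if e.ref_aa else "",
            "Position": e.protein_pos,
            "SNP": aa3(e.alt_aa) if e.alt_aa not in ("", "fs", "*") else e.alt_aa,
            "Frequency": e.frequency,
        }
        for e in nonredundant(effects)
        if e.frequency > threshold
    ]
    df = pd.DataFrame(rows, columns=["Gene_Name", "Wild_Type", "Position",
                                     "SNP", "Frequency"])
    if len(df):
        df = df.sort_values(
            ["Gene_Name", "Frequency", "Position"],
            ascending=[True, False, True],
        ).reset_index(drop=True)
    return df


def disruption_tables(
    effects: Iterable[VariantEffect],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(nonsense table, frameshift table) of non-redundant effects.

    Nonsense rows: Gene_Name, Wild_Type, Position, Frequency.
    Frameshift rows: gene_name, sequence_change (combined p./c. notation),
    Frequency.
    """
    nr = nonredundant(effects)
    non = [
        {
            "Gene_Name": e.gene_id,
            "Wild_Type": aa3(e.ref_aa) if e.ref_aa else "",
            "Position": e.protein_pos,
            "Frequency": e.frequency,
        }
        for e in nr
        if e.effect_class == NONSENSE
    ]
    fs = [
        {
            "gene_name": e.gene_id,
            "sequence_change": e.notation,
            "Frequency": e.frequency,
        }
        for e in nr
        if e.effect_class == FRAMESHIFT
    ]
    non_df = pd.DataFrame(non, columns=["Gene_Name", "Wild_Type", "Position",
                                        "Frequency"])
    fs_df = pd.DataFrame(fs, columns=["gene_name", "sequence_change",
                                      "Frequency"])
    if len(non_df):
        non_df = non_df.sort_values(
            ["Gene_Name", "Frequency", "Position"], ascending=[True, False, True]
        ).reset_index(drop=True)
    if len(fs_df):
        fs_df = fs_df.sort_values(
            ["gene_name", "Frequency"], ascending=[True, False]
        ).reset_index(drop=True)
    return non_df, fs_df


def accession_burdens(effects: Iterable[VariantEffect]) -> pd.DataFrame:
    """Per-accession counts of distinct missense variants, per gene and total.

    Requires carrier sets on the effects (not just frequencies).  Returns a
    DataFrame indexed by accession id with one column per gene plus 'total'.
    """
    counts: dict[str, dict[str, int]] = {}
    for e in nonredundant(effects):
        if e.effect_class != MISSENSE:
            continue
        for acc in e.carriers:
            gene_counts = counts.setdefault(acc, {})
            gene_counts[e.gene_id] = gene_counts.get(e.gene_id, 0) + 1
    df = pd.DataFrame.from_dict(counts, orient="index").fillna(0).astype(int)
    df = df.sort_index().sort_index(axis=1)
    df["total"] = df.sum(axis=1)
    return df


def summary_counts(effects: Iterable[VariantEffect]) -> dict[str, int]:
    """Headline totals: non-redundant variants and affected genes per class."""
    nr = nonredundant(effects)
    out: dict[str, int] = {}
    for cls in (MISSENSE, NONSENSE, FRAMESHIFT):
        sub = [e for e in nr if e.effect_class == cls]
        out[f"{cls}_variants"] = len(sub)
        out[f"{cls}_genes"] = len({e.gene_id for e in sub})
    return out
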
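"""Readers for published-style variant survey tables.

Three TSV schemas are accepted (headers are matched case-insensitively):

* high-frequency missense — ``Gene_Name  Wild_Type  Position  SNP  Frequency``
* nonsense — ``Gene_Name  Wild_Type  Position  Frequency``
* frameshift — ``gene_name  sequence_change  Frequency`` where
  sequence_change is "p.Asn175fs/c.525_526delCA"-style notation (the p. part
  may be absent).

The package ships the three survey tables for the 31 Arabidopsis
polyadenylation-complex genes, compiled from the 1001 Genomes collection,
plus a synthetic calibration table of per-gene attributes used by the
evidence-module examples and tests.
"""

from __future__ import annotations

import re
from importlib import resources

import pandas as pd
from Bio.SeqUtils import seq1

from .variants import FRAMESHIFT, MISSENSE, NONSENSE, VariantEffect


class TableFormatError(ValueError):
    pass


_P_PART = re.compile(
    r"^p\.(?P<aa1>[A-Z][a-z]{2})(?P<pos1>\d+)(?:_(?P<aa2>[A-Z][a-z]{2})(?P<pos2>\d+))?fs$"
)
_C_PART = re.compile(
    r"^c\.(?P<start>\d+)(?:_(?P<end>\d+))?(?P<op>del|ins)(?P<bases>[ACGTN]*)$"
)


def _aa1(three: str, line_no: int) -> str:
    try:
        return seq1(three)
    except Exception as exc:  # pragma: no cover - defensive
        raise TableFormatError(f"line {line_no}: bad residue {three!r}") from exc


def parse_sequence_change(change: str, line_no: int = 0) -> dict:
    """Parse a combined 'p.…fs/c.…' (or bare 'c.…') notation string."""
    p_part, c_part = "", change
    if change.startswith("p."):
        if "/" not in change:
            raise TableFormatError(
                f"line {line_no}: missing c. part in {change!r}"
            )
        p_part, c_part = change.split("/", 1)
    c_m = _C_PART.match(c_part)
    if not c_m:
        raise TableFormatError(f"line {line_no}: malformed notation {change!r}")
    if p_part:
        p_m = _P_PART.match(p_part)
        if not p_m:
            raise TableFormatError(f"line {line_no}: malformed notation {change!r}")
        protein_pos = int(p_m.group("pos1"))
        ref_aa = _aa1(p_m.group("aa1"), line_no)
    else:
        protein_pos = (int(c_m.group("start")) - 1) // 3 + 1
        ref_aa = ""
    return {
        "protein_pos": protein_pos,
        "ref_aa": ref_aa,
        "protein_notation": p_part,
        "cds_notation": c_part,
        "cds_pos": int(c_m.group("start")),
    }


def read_table_fixture(path) -> list[VariantEffect]:
    """Read one of the three survey-table schemas into VariantEffect rows.

    The effect class is inferred from the header: a SNP column means
    missense, a sequence_change column means frameshift, otherwise nonsense.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    effects: list[VariantEffect] = []
    if {"gene_name", "wild_type", "position", "snp", "frequency"} <= set(cols):
        for i, row in df.iterrows():
            line = i + 2
            pos = int(row["position"])
            ref_aa = _aa1(row["wild_type"], line)
            alt_aa = _aa1(row["snp"], line)
            effects.append(
                VariantEffect(
                    row["gene_name"], MISSENSE, pos, ref_aa, alt_aa,
                    f"p.{row['wild_type']}{pos}{row['snp']}",
                    f"c.{pos}.missense",  # site-level surrogate: no alleles printed
                    int(row["frequency"]),
                )
            )
    elif {"gene_name", "sequence_change", "frequency"} <= set(cols):
        for i, row in df.iterrows():
            line = i + 2
            parsed = parse_sequence_change(str(row["sequence_change"]), line)
            effects.append(
                VariantEffect(
                    row["gene_name"], FRAMESHIFT, parsed["protein_pos"],
                    parsed["ref_aa"], "fs", parsed["protein_notation"],
                    parsed["cds_notation"], int(row["frequency"]),
                    cds_pos=parsed["cds_pos"],
                )
            )
    elif {"gene_name", "wild_type", "position", "frequency"} <= set(cols):
        for i, row in df.iterrows():
            line = i + 2
            pos = int(row["position"])
            ref_aa = _aa1(row["wild_type"], line)
            effects.append(
                VariantEffect(
                    row["gene_name"], NONSENSE, pos, ref_aa, "*",
                    f"p.{row['wild_type']}{pos}*", f"c.{pos}.nonsense",
                    int(row["frequency"]),
                )
            )
    else:
        raise TableFormatError(f"unrecognized table header: {list(df.columns)}")
    return effects


def _data_path(name: str):
    return resources.files("pacvar.data").joinpath(name)


def load_survey_tables() -> list[VariantEffect]:
    """All packaged survey-table effects (missense > 1000, nonsense, frameshift)."""
    effects = []
    for name in ("pac_missense_gt1000.tsv", "pac_nonsense.tsv", "pac_frameshift.tsv"):
        with resources.as_file(_data_path(name)) as p:
            effects.extend(read_table_fixture(p))
    return effects


def build_calibration_signals() -> list:
    """Per-gene evidence signals for the five focal genes.

    Truncating variants (with accession frequencies) come from the packaged
    survey tables; protein lengths, missense counts, pi groups and the
    nonstop/expression stand-ins come from the synthetic calibration
    attribute table.  Returns :class:`pacvar.evidence.GeneSignals` objects.
    """
    from .evidence import GeneSignals, TruncatingVariant

    attrs = load_calibration_attributes()
    effects = load_survey_tables()
    signals = []
    for gene, row in attrs.iterrows():
        truncs = [
            TruncatingVariant(e.effect_class, e.protein_pos, e.frequency)
            for e in effects
            if e.gene_id == gene and e.effect_class in (NONSENSE, FRAMESHIFT)
        ]
        ns, expr = row["nonstop_fraction"], row["relative_expression"]
        signals.append(
            GeneSignals(
                gene, int(row["protein_length"]), truncs,
                missense_count=int(row["missense_count"]),
                pi_ratio_group=row["pi_group"],
                nonstop_fraction=None if pd.isna(ns) else float(ns),
                relative_expression=None if pd.isna(expr) else float(expr),
            )
        )
    return signals


def load_calibration_attributes() -> pd.DataFrame:
    """Synthetic per-gene calibration attributes for the evidence module.

    Protein lengths and the nonstop/expression columns are constructed
    stand-ins (the genotype-level sources are not desk-scale); the missense
    counts for PCFS1/PCFS5 and the pi groups follow the published survey.
    """
    with resources.as_file(
        _data_path("calibration_gene_attributes_synthetic.tsv")
    ) as p:
        return pd.read_csv(p, sep="\t", na_values=["NA"]).set_index("gene_id")
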
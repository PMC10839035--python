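"""End-to-end pipeline: models -> annotate -> diversity -> tabulate ->
patseq -> evidence, driven by one YAML configuration file.

Stages with missing optional inputs (PAT-seq BED, expression TSV) are
skipped with a warning and the evidence stage degrades gracefully (its
nonstop/expression signals stay missing).  Every emitted artifact is listed
in a manifest with a SHA-256 checksum so deterministic stages can be
audited across reruns.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Any

import pandas as pd
import yaml

from . import diversity as div
from . import evidence as ev
from . import patseq as ps
from . import tabulation as tab
from .gene_models import GeneModel, MergeDirective, load_gene_models
from .variants import VariantEffect, annotate_population, read_vcf

log = logging.getLogger("pacvar.pipeline")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    gff3: str
    fasta: str
    vcf: str
    outdir: str
    n_accessions: int
    transcripts: dict[str, str] | None = None
    merges: list[dict] = field(default_factory=list)
    bed: str | None = None
    expression: str | None = None
    bins: list[list[int | None]] | None = None
    high_frequency_threshold: int = 1000
    min_run: int = 8
    flank: int = 20
    merge_window: int = 24
    downstream_extent: int = 500
    rules: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            cfg = cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"invalid configuration: {exc}") from exc
        for key in ("gff3", "fasta", "vcf"):
            p = getattr(cfg, key)
            if not os.path.exists(p):
                raise ConfigError(f"{key} path does not exist: {p}")
        return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def effects_to_frame(effects: list[VariantEffect]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": e.gene_id,
                "effect_class": e.effect_class,
                "protein_pos": e.protein_pos,
                "ref_aa": e.ref_aa,
                "alt_aa": e.alt_aa,
                "protein_notation": e.protein_notation,
                "cds_notation": e.cds_notation,
                "frequency": e.frequency,
                "cds_pos": e.cds_pos,
            }
            for e in effects
        ]
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the output manifest."""
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict[str, Any] = {"outputs": {}, "stages": {}}

    def emit(name: str, path: str) -> None:
        manifest["outputs"][name] = {"path": path, "sha256": _sha256(path)}

    # stage 1: gene models
    merges = [
        MergeDirective(m["output_gene_id"], tuple(m["input_gene_ids"]),
                       m.get("display_name"))
        for m in config.merges
    ]
    models = load_gene_models(
        config.gff3, config.fasta, config.transcripts, merges
    )
    log.info("models: %d gene models", len(models))
    manifest["stages"]["models"] = {"n_models": len(models)}

    # stage 2: variant annotation
    records = read_vcf(config.vcf)
    effects = annotate_population(models, records)
    eff_path = os.path.join(config.outdir, "effects.tsv")
    effects_to_frame(effects).to_csv(eff_path, sep="\t", index=False)
    emit("effects", eff_path)
    manifest["stages"]["annotate"] = {
        "n_records": len(records), "n_effects": len(effects),
    }

    # stage 3: diversity
    rows = []
    for m in models:
        res = div.gene_diversity(
            m, [e for e in effects if e.gene_id == m.gene_id], config.n_accessions
        )
        rows.append(asdict(res))
    div_path = os.path.join(config.outdir, "diversity.tsv")
    pd.DataFrame(rows).to_csv(div_path, sep="\t", index=False)
    emit("diversity", div_path)
    div_by_gene = {r["gene_id"]: r for r in rows}

    # stage 4: tabulation
    bins = (
        tuple((lo, hi) for lo, hi in config.bins)
        if config.bins else tab.DEFAULT_BINS
    )
    spec_path = os.path.join(config.outdir, "spectrum.tsv")
    tab.spectrum(effects, bins).to_csv(spec_path, sep="\t", index_label="effect_class")
    emit("spectrum", spec_path)
    hf_path = os.path.join(config.outdir, "high_frequency.tsv")
    tab.high_frequency_table(effects, config.high_frequency_threshold).to_csv(
        hf_path, sep="\t", index=False
    )
    emit("high_frequency", hf_path)
    non_df, fs_df = tab.disruption_tables(effects)
    non_path = os.path.join(config.outdir, "nonsense.tsv")
    fs_path = os.path.join(config.outdir, "frameshift.tsv")
    non_df.to_csv(non_path, sep="\t", index=False)
    fs_df.to_csv(fs_path, sep="\t", index=False)
    emit("nonsense", non_path)
    emit("frameshift", fs_path)
    burdens_path = os.path.join(config.outdir, "accession_burdens.tsv")
    tab.accession_burdens(effects).to_csv(burdens_path, sep="\t",
                                          index_label="accession_id")
    emit("accession_burdens", burdens_path)

    # stage 5: patseq (optional)
    nonstop: dict[str, float | None] = {}
    if config.bed and os.path.exists(config.bed):
        tags = ps.read_bed6(config.bed)
        mask = ps.build_a_mask(config.fasta, config.min_run, config.flank)
        kept = ps.filter_tags(tags, mask)
        sites = ps.assign_sites(
            ps.cluster_sites(kept, config.merge_window), models,
            config.downstream_extent,
        )
        site_path = os.path.join(config.outdir, "polya_sites.tsv")
        pd.DataFrame(
            [
                {
                    "chrom": s.chrom, "strand": s.strand, "position": s.position,
                    "tag_count": s.tag_count, "gene_id": s.gene_id, "zone": s.zone,
                }
                for s in sites
            ]
        ).to_csv(site_path, sep="\t", index=False)
        emit("polya_sites", site_path)
        ns_df = ps.gene_nonstop_table(sites)
        ns_path = os.path.join(config.outdir, "nonstop_fractions.tsv")
        ns_df.to_csv(ns_path, sep="\t", index=False)
        emit("nonstop_fractions", ns_path)
        nonstop = dict(zip(ns_df["gene_id"], ns_df["nonstop_fraction"]))
        manifest["stages"]["patseq"] = {
            "n_tags": len(tags), "n_masked": len(tags) - len(kept),
            "n_sites": len(sites),
        }
    else:
        log.warning("patseq stage skipped: no BED input")
        manifest["stages"]["patseq"] = {"skipped": True}

    # stage 6: expression (optional) + evidence
    expression: dict[str, float] = {}
    if config.expression and os.path.exists(config.expression):
        expr = pd.read_csv(config.expression, sep="\t", index_col=0)
        norm = ev.normalize_expression_table(expr, floor=0.01)
        expression = norm.max(axis=1).to_dict()
    else:
        log.warning("expression input missing; evidence degrades gracefully")

    rules = ev.RuleConfig(**config.rules) if config.rules else ev.RuleConfig()
    reports = []
    for m in models:
        sig = ev.signals_from_effects(
            m.gene_id, m.protein_length,
            [e for e in effects if e.gene_id == m.gene_id],
            pi_ratio_group=div_by_gene[m.gene_id]["group"],
            nonstop_fraction=nonstop.get(m.gene_id),
            relative_expression=expression.get(m.gene_id),
        )
        reports.append(asdict(ev.evaluate_gene(sig, rules)))
    evid_path = os.path.join(config.outdir, "evidence.json")
    with open(evid_path, "w") as fh:
        json.dump({"rules": asdict(rules), "reports": reports}, fh, indent=1)
    emit("evidence", evid_path)
    summary_path = os.path.join(config.outdir, "evidence.tsv")
    pd.DataFrame(reports).drop(columns=["triggered_rules"]).assign(
        triggered_rules=[",".join(r["triggered_rules"]) for r in reports]
    ).to_csv(summary_path, sep="\t", index=False)
    emit("evidence_summary", summary_path)

    manifest_path = os.path.join(config.outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
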
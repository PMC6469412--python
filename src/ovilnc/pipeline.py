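"""End-to-end orchestration: funnel -> classification -> expression calls ->
targets -> conservation/synteny -> QTL -> network modules -> enrichment.

The pipeline is driven by a :class:`PipelineConfig` (usually loaded from
a YAML file) pointing at the input bundle; every stage writes a TSV into
the output directory and logs its counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from Bio import SeqIO

from . import comparative, enrich, netmod, qtl as qtl_mod
from .expression import ExpressionMatrix, breed_specific, classify_de, feature_stats
from .funnel import (
    CodingScores,
    EvidenceRecord,
    FilterParams,
    run_funnel,
)
from .genome import (
    GenomeAnnotation,
    PROTEIN_CODING,
    read_bed,
    read_gtf,
    write_gtf,
)
from .targets import cis_targets, host_gene, targets_table, trans_targets

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Missing or inconsistent pipeline configuration."""


class DataError(ValueError):
    """Missing or malformed input data."""


@dataclass
class PipelineConfig:
    indir: Path
    outdir: Path
    species: tuple[str, ...] = ("bovine", "human", "chicken")
    filter_params: FilterParams = field(default_factory=FilterParams)
    trans_r_min: float = 0.99
    trans_p_max: float = 5e-5
    network_r_min: float = 0.95
    cis_window: int = 100_000
    de_fdr_max: float = 0.1
    conservation_emax: float = 1e-5
    qtl_trait: Optional[str] = None
    qtl_max_span: Optional[int] = None
    module_min_size: int = 6
    module_p_max: float = 0.01
    module_penalty: float = 2.0
    enrich_fdr_max: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            indir = Path(raw.pop("indir"))
            outdir = Path(raw.pop("outdir"))
        except KeyError as exc:
            raise ConfigError(f"config missing required key: {exc}") from exc
        fp = FilterParams(**raw.pop("filter_params", {}))
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        if "species" in raw:
            raw["species"] = tuple(raw["species"])
        return cls(indir=indir, outdir=outdir, filter_params=fp, **raw)


def _require(path: Path) -> Path:
    if not path.exists():
        raise DataError(f"required input file does not exist: {path}")
    return path


def load_evidence(indir: Path) -> dict[str, EvidenceRecord]:
    """Assemble per-transcript evidence from the hits/domains/scores tables."""
    ev: dict[str, EvidenceRecord] = {}

    def rec(tid: str) -> EvidenceRecord:
        if tid not in ev:
            ev[tid] = EvidenceRecord(tid)
        return ev[tid]

    hom = pd.read_csv(_require(indir / "homology_hits.tsv"), sep="\t")
    for _, row in hom.iterrows():
        rec(str(row["transcript_id"])).hits.append((str(row["db"]), float(row["evalue"])))
    dom = pd.read_csv(_require(indir / "domains.tsv"), sep="\t")
    for _, row in dom.iterrows():
        rec(str(row["transcript_id"])).domain_hits.append(
            (str(row["domain_id"]), float(row["evalue"]))
        )
    scores = pd.read_csv(_require(indir / "coding_scores.tsv"), sep="\t")
    for _, row in scores.iterrows():
        rec(str(row["transcript_id"])).coding_scores = CodingScores(
            float(row["cpc2"]), float(row["cnci"]), float(row["cpat"]),
            float(row["plek"]), str(row["feelnc"]),
        )
    return ev


@dataclass
class PipelineResult:
    candidates: list
    report: object
    breed_specific: dict[str, str]
    de_records: list
    targets: pd.DataFrame
    conservation: pd.DataFrame
    synteny_venn: dict
    qtl_table: pd.DataFrame
    modules: list
    enrichment: pd.DataFrame
    stats: pd.DataFrame


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every stage over the input bundle and write the output bundle."""
    indir, outdir = Path(cfg.indir), Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    log.info("reading annotation and inputs from %s", indir)
    ref = read_gtf(_require(indir / "reference.gtf"))
    assembled = read_gtf(_require(indir / "assembled.gtf"))
    repeats = read_bed(_require(indir / "repeats.bed"))
    expr = ExpressionMatrix.from_tsv(
        _require(indir / "expression.tsv"), _require(indir / "groups.tsv")
    )
    sequences = {
        r.id: str(r.seq) for r in SeqIO.parse(str(_require(indir / "transcripts.fa")), "fasta")
    }
    evidence = load_evidence(indir)

    # ---- funnel -----------------------------------------------------------
    candidates, report = run_funnel(
        assembled, ref, repeats, expr, evidence, cfg.filter_params, sequences
    )
    lincs = [c for c in candidates if c.category == "lincRNA"]
    ilncs = [c for c in candidates if c.category == "ilncRNA"]
    counts["candidates_lincRNA"] = len(lincs)
    counts["candidates_ilncRNA"] = len(ilncs)
    pd.DataFrame(report.to_rows()).to_csv(outdir / "funnel_report.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"transcript_id": k, "reason": v} for k, v in sorted(report.rejections.items())]
    ).to_csv(outdir / "rejected.tsv", sep="\t", index=False)
    cand_ann = GenomeAnnotation(
        {c.transcript_id: c.transcript for c in candidates}
    )
    write_gtf(
        cand_ann,
        outdir / "candidates.gtf",
        extra_attrs={c.transcript_id: {"category": c.category} for c in candidates},
    )

    # ---- breed specificity ------------------------------------------------
    bs = {}
    for c in candidates:
        call = breed_specific(c.transcript_id, expr)
        if call is not None:
            bs[c.transcript_id] = call
    pd.DataFrame(
        [{"lnc_id": k, "breed": v} for k, v in sorted(bs.items())]
    ).to_csv(outdir / "breed_specific.tsv", sep="\t", index=False)

    # ---- DE consumption ---------------------------------------------------
    de_table = pd.read_csv(_require(indir / "de_table.tsv"), sep="\t")
    de_records = classify_de(de_table, fdr_max=cfg.de_fdr_max)
    counts["de_features"] = len(de_records)

    # ---- targets ----------------------------------------------------------
    assignments = []
    for c in lincs:
        assignments.extend(cis_targets(c.transcript, ref, cfg.cis_window))
    for c in ilncs:
        assignments.append(host_gene(c.transcript, ref))
    cand_ids = [c.transcript_id for c in candidates]
    lnc_expr = expr.df.loc[[i for i in cand_ids if i in expr.df.index]]
    coding_genes = sorted(ref.genes_of_biotype(PROTEIN_CODING))
    mrna_expr = expr.df.loc[[g for g in coding_genes if g in expr.df.index]]
    trans = trans_targets(lnc_expr, mrna_expr, cfg.trans_r_min, cfg.trans_p_max)
    assignments.extend(trans)
    tt = targets_table(assignments)
    tt.to_csv(outdir / "targets.tsv", sep="\t", index=False)
    counts["trans_interactions"] = len(trans)

    # ---- conservation -----------------------------------------------------
    hit_frames = []
    for sp in cfg.species:
        for direction, tag in (
            (comparative.SHEEP_AS_QUERY, "query"),
            (comparative.SHEEP_AS_SUBJECT, "subject"),
        ):
            path = indir / f"cons_{sp}_{tag}.tsv"
            if path.exists() and path.stat().st_size > 0:
                hit_frames.append(comparative.read_blast6(path, sp, direction))
    hits = (
        pd.concat(hit_frames, ignore_index=True)
        if hit_frames
        else pd.DataFrame(columns=["query_id", "subject_id", "species", "e_value",
                                   "alignment_length", "direction"])
    )
    hits = hits[hits["query_id"].isin(set(cand_ids))]
    cons = comparative.conservation_summary(hits, cfg.conservation_emax)
    cons.to_csv(outdir / "conservation.tsv", sep="\t", index=False)

    # ---- synteny ----------------------------------------------------------
    records = []
    for sp in cfg.species:
        lincs_tab = comparative.read_positions_tsv(_require(indir / f"foreign_lincs_{sp}.tsv"))
        genes_tab = comparative.read_positions_tsv(_require(indir / f"foreign_genes_{sp}.tsv"))
        orthologs = comparative.read_orthologs_tsv(_require(indir / f"orthologs_{sp}.tsv"))
        pairs = comparative.foreign_flank_pairs(lincs_tab, genes_tab)
        for c in lincs:
            records.append(
                comparative.synteny_conserved(c.transcript, ref, sp, pairs, orthologs)
            )
    venn = comparative.synteny_venn(records)
    pd.DataFrame(
        [
            {"lnc_id": r.lnc_id, "species": r.species,
             "left": r.sheep_neighbors[0], "right": r.sheep_neighbors[1],
             "foreign_linc": r.matched_foreign_linc,
             "conserved_synteny": r.conserved_synteny, "flag": r.flag}
            for r in records
        ]
    ).to_csv(outdir / "synteny.tsv", sep="\t", index=False)
    counts["syntenic_lincRNAs"] = len(set().union(*venn["sets"].values())) if venn["sets"] else 0

    # ---- QTL --------------------------------------------------------------
    qtls = qtl_mod.read_qtl_table(_require(indir / "qtl.tsv"))
    lnc_spans = {c.transcript_id: c.transcript.span for c in candidates}
    qtl_table = qtl_mod.qtl_annotate(
        lnc_spans, qtls, trait_filter=cfg.qtl_trait, max_qtl_span=cfg.qtl_max_span
    )
    qtl_table.to_csv(outdir / "qtl_annotation.tsv", sep="\t", index=False)
    counts["qtl_located_lncRNAs"] = qtl_table["lnc_id"].nunique() if len(qtl_table) else 0

    # ---- network + modules ------------------------------------------------
    coexp = trans_targets(lnc_expr, mrna_expr, cfg.network_r_min, cfg.trans_p_max)
    ppi = netmod.read_ppi_tsv(_require(indir / "ppi.tsv"))
    net = netmod.build_network(coexp, ppi)
    modules = netmod.detect_modules(
        net, cfg.module_min_size, cfg.module_p_max, penalty=cfg.module_penalty
    )
    netmod.modules_table(modules).to_csv(outdir / "modules.tsv", sep="\t", index=False)
    counts["significant_modules"] = len(modules)

    # ---- enrichment -------------------------------------------------------
    sets = enrich.read_gmt(_require(indir / "gene_sets.gmt"))
    background = set(coding_genes) | {
        n for n, d in net.nodes(data=True) if d.get("kind") == netmod.KIND_CODING
    }
    frames = []
    if modules:  # one over-representation run per detected module
        for i, m in enumerate(modules, start=1):
            query = sorted(set(m.members) & background)
            if not query:
                continue
            res = enrich.ora(query, sets, background, cfg.enrich_fdr_max)
            res.insert(0, "module", i)
            frames.append(res)
    else:  # no modules: test the trans-target gene set instead
        query = sorted({a.gene_id for a in trans} & background)
        if query:
            res = enrich.ora(query, sets, background, cfg.enrich_fdr_max)
            res.insert(0, "module", 0)
            frames.append(res)
    enrichment = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["module", "set_id", "name", "set_size", "overlap",
                                   "p_value", "fdr", "significant"])
    )
    enrichment = enrichment.sort_values(
        ["fdr", "p_value", "module", "set_id"]
    ).reset_index(drop=True)
    enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    # ---- descriptive stats ------------------------------------------------
    classes = {
        "novel lincRNA": [c.transcript_id for c in lincs],
        "novel ilncRNA": [c.transcript_id for c in ilncs],
    }
    transcripts = {c.transcript_id: c.transcript for c in candidates}
    stats = feature_stats(classes, transcripts, sequences, expr)
    stats.to_csv(outdir / "feature_stats.tsv", sep="\t")

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(
            {"counts": counts, "funnel": report.to_rows(),
             "params": {"trans_r_min": cfg.trans_r_min, "network_r_min": cfg.network_r_min,
                        "de_fdr_max": cfg.de_fdr_max, "module_p_max": cfg.module_p_max,
                        "seed": cfg.seed}},
            fh, indent=1,
        )
    log.info("pipeline finished: %s", counts)
    return PipelineResult(
        candidates, report, bs, de_records, tt, cons, venn, qtl_table, modules,
        enrichment, stats,
    )
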
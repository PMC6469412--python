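"""Seeded generator of a complete miniature two-breed RNA-seq world.

The generator emits every post-assembly input the pipeline consumes —
reference and assembled GTFs, transcript FASTA, repeat BED, expression
and grouping tables, a Cuffdiff-like DE table, homology / domain /
coding-score evidence, cross-species conservation and synteny tables, a
QTL table, a PPI edge list and a GMT collection — together with a truth
table recording what was planted where.

The defaults mirror the study design the pipeline targets: three samples
per breed for a fat-tailed (Lori-Bakhtiari) vs thin-tailed (Zel)
comparison; 10 + 5 breed-specific lincRNA genes and 2 + 1 breed-specific
ilncRNA genes; nine lincRNA loci syntenic across all foreign species;
planted cross-species alignment lengths averaging 284 nt (bovine) and
312 nt (human); seven differentially expressed lncRNAs; and three
cohesive network modules of sizes 9-12.  Every decoy transcript violates
exactly one funnel rule.  A fixed seed fixes every output byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .funnel import find_longest_orf
from .genome import (
    GenomeAnnotation,
    GenomeInterval,
    KNOWN_LNCRNA,
    NOVEL,
    PROTEIN_CODING,
    TranscriptModel,
    write_gtf,
)

SPECIES_SUFFIX = {"bovine": "BOV", "human": "HUM", "chicken": "GAL"}

#: funnel decoy kinds -> (report step, rejection reason)
DECOY_KINDS = {
    "min_length": ("structural", "min_length"),
    "monoexon_long": ("structural", "monoexon_too_long"),
    "monoexon_repeat": ("structural", "monoexon_repeat"),
    "low_expression": ("expression", "low_expression"),
    "homology": ("homology", "homology_hit"),
    "domain": ("protein_domain", "protein_domain"),
    "coding_votes": ("coding_potential", "coding_vote"),
    "long_orf": ("orf_length", "long_orf"),
    "proximity": ("gene_proximity", "gene_proximity"),
}


class LayoutError(ValueError):
    """The requested world does not fit on the configured chromosomes."""


@dataclass
class WorldConfig:
    seed: int = 0
    n_chromosomes: int = 3
    n_coding_genes: int = 60
    chrom_length_bp: int = 5_000_000
    n_known_lincrnas: int = 9
    n_planted_lincrnas: int = 30
    n_planted_ilncrnas: int = 6
    n_decoys_per_filter: int = 5
    samples_per_breed: int = 3
    breeds: tuple[str, str] = ("Lori-Bakhtiari", "Zel")
    n_breed_specific_linc: tuple[int, int] = (10, 5)  # per breed, lincRNA genes
    n_breed_specific_ilnc: tuple[int, int] = (2, 1)
    n_trans_pairs: int = 10
    n_trans_negative: int = 2
    n_trans_decoys: int = 4
    species: tuple[str, ...] = ("bovine", "human", "chicken")
    n_syntenic_all: int = 9
    n_syntenic_partial: int = 6
    n_conserved: dict = field(
        default_factory=lambda: {"bovine": 12, "human": 8, "chicken": 0}
    )
    mean_alignment_length: dict = field(
        default_factory=lambda: {"bovine": 284, "human": 312}
    )
    n_de_lncrnas: int = 7
    n_qtl: int = 10
    n_qtl_contained: int = 7
    n_network_cliques: int = 3
    clique_size_range: tuple[int, int] = (9, 12)
    n_network_proteins: int = 290
    ppi_noise_p: float = 0.01
    gc_target: float = 0.48
    expr_sigma: float = 0.2  # log-scale noise of planted FPKM

    def __post_init__(self) -> None:
        specials = (
            self.n_syntenic_all
            + self.n_syntenic_partial
            + sum(self.n_breed_specific_linc)
        )
        if self.n_planted_lincrnas < specials:
            raise ValueError(
                f"n_planted_lincrnas={self.n_planted_lincrnas} cannot host "
                f"{specials} special lincRNAs"
            )
        if sum(self.n_breed_specific_ilnc) > self.n_planted_ilncrnas:
            raise ValueError("more breed-specific ilncRNAs than planted ilncRNAs")


@dataclass
class TruthTable:
    """Ground truth of every planted element of a generated world."""

    planted_lincrnas: list[str] = field(default_factory=list)
    planted_ilncrnas: dict[str, str] = field(default_factory=dict)  # tid -> host gene
    decoys: dict[str, tuple[str, str]] = field(default_factory=dict)  # tid -> (step, reason)
    breed_specific: dict[str, str] = field(default_factory=dict)  # tid -> breed
    trans_pairs: list[tuple[str, str, int]] = field(default_factory=list)
    trans_decoys: list[tuple[str, str]] = field(default_factory=list)
    conserved: dict[str, dict[str, int]] = field(default_factory=dict)
    syntenic: dict[str, list[str]] = field(default_factory=dict)  # tid -> species
    qtl_contained: dict[str, list[str]] = field(default_factory=dict)  # qtl -> lnc ids
    qtl_traits: dict[str, str] = field(default_factory=dict)
    modules: list[list[str]] = field(default_factory=list)
    enriched_set_id: str = ""
    de_features: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


@dataclass
class World:
    config: WorldConfig
    outdir: Path
    paths: dict[str, Path]
    truth: TruthTable


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def _noncoding_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    """Random sequence guaranteed to lack any ORF of >= 300 aa."""
    for _ in range(50):
        seq = _random_seq(rng, length, gc)
        if find_longest_orf(seq) < 300:
            return seq
    raise RuntimeError("could not draw a noncoding sequence")  # pragma: no cover


def _long_orf_seq(rng: np.random.Generator, length: int, gc: float, aa: int = 320) -> str:
    """Sequence whose longest ORF is >= ``aa`` amino acids."""
    stops = {"TAA", "TAG", "TGA"}
    codons = []
    while len(codons) < aa:
        c = _random_seq(rng, 3, gc)
        if c not in stops and c != "ATG":
            codons.append(c)
    core = "ATG" + "".join(codons) + "TAA"
    pad = max(0, length - len(core))
    left = pad // 2 - (pad // 2) % 3  # keep frame irrelevant; any padding works
    seq = _noncoding_seq(rng, pad - left, gc) + core + _noncoding_seq(rng, left, gc) \
        if pad else core
    return seq


def _exon_chain(
    rng: np.random.Generator,
    start: int,
    n_exons: int,
    exon_len: tuple[int, int],
    intron_len: tuple[int, int],
    chrom: str,
    strand: str,
    big_intron: Optional[int] = None,
) -> list[GenomeInterval]:
    exons = []
    pos = start
    for i in range(n_exons):
        ln = int(rng.integers(exon_len[0], exon_len[1] + 1))
        exons.append(GenomeInterval(chrom, pos, pos + ln, strand))
        if i < n_exons - 1:
            gap = (
                big_intron
                if big_intron is not None and i == 0
                else int(rng.integers(intron_len[0], intron_len[1] + 1))
            )
            pos = pos + ln + gap
    return exons


def _lognormal_row(rng, mean_fpkm: float, n: int, sigma: float) -> np.ndarray:
    return mean_fpkm * np.exp(rng.normal(0.0, sigma, size=n))


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------


def generate_world(cfg: WorldConfig, outdir: str | Path) -> World:
    """Write the complete world bundle into ``outdir`` and return it with truth."""
    rng = np.random.default_rng(cfg.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = TruthTable()
    paths: dict[str, Path] = {}

    samples = [
        f"{breed}_{i + 1}" for breed in cfg.breeds for i in range(cfg.samples_per_breed)
    ]
    groups = {s: s.rsplit("_", 1)[0] for s in samples}

    # ---- coding-gene layout ----------------------------------------------
    chroms = [str(i + 1) for i in range(cfg.n_chromosomes)]
    per_chrom = cfg.n_coding_genes // cfg.n_chromosomes
    host_flags = set()  # gene indices that must carry a wide first intron
    host_pool = list(range(1, cfg.n_coding_genes, 3))[: cfg.n_planted_ilncrnas]
    host_flags.update(host_pool)

    ref = GenomeAnnotation()
    gene_spans: dict[str, GenomeInterval] = {}
    gaps: list[tuple[str, str, str, int, int]] = []  # chrom, left gene, right gene, start, end
    gi = 0
    for chrom in chroms:
        cursor = 50_000
        prev_gene = None
        prev_end = None
        for _ in range(per_chrom):
            gene_id = f"GENE{gi:03d}"
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(2, 13))
            big = int(rng.integers(6000, 8001)) if gi in host_flags else None
            exons = _exon_chain(
                rng, cursor, n_ex, (120, 300), (600, 3000), chrom, strand, big
            )
            t = TranscriptModel(f"{gene_id}.t1", gene_id, exons, PROTEIN_CODING)
            ref.transcripts[t.transcript_id] = t
            gene_spans[gene_id] = t.span
            if prev_gene is not None:
                gaps.append((chrom, prev_gene, gene_id, prev_end, t.span.start))
            prev_gene, prev_end = gene_id, t.span.end
            cursor = t.span.end + int(rng.integers(60_000, 80_001))
            if cursor > cfg.chrom_length_bp:
                raise LayoutError(
                    f"chromosome {chrom}: layout exceeds {cfg.chrom_length_bp} bp"
                )
            gi += 1
    ref._invalidate()

    # ---- slot allocation --------------------------------------------------
    n_specials = cfg.n_syntenic_all + cfg.n_syntenic_partial
    syn_gap_idx = []
    i = 0
    while len(syn_gap_idx) < n_specials and i < len(gaps):
        syn_gap_idx.append(i)
        i += 2  # alternate gaps so no two syntenic loci share a flank gene
    if len(syn_gap_idx) < n_specials:
        raise LayoutError("not enough gaps for syntenic loci")
    other_slots = []
    for j, gap in enumerate(gaps):
        if j in syn_gap_idx:
            continue
        _, _, _, s, e = gap
        w = e - s
        other_slots.append((j, s + int(0.35 * w)))
        other_slots.append((j, s + int(0.65 * w)))

    def take_slot() -> tuple[int, int]:
        if not other_slots:
            raise LayoutError("ran out of intergenic slots")
        return other_slots.pop(0)

    assembled = GenomeAnnotation()
    sequences: dict[str, str] = {}

    def add_novel(
        tid: str,
        chrom: str,
        pos: int,
        n_exons: int,
        exon_len: tuple[int, int],
        seq_kind: str = "clean",
    ) -> TranscriptModel:
        strand = "+" if rng.random() < 0.5 else "-"
        exons = _exon_chain(rng, pos, n_exons, exon_len, (200, 2000), chrom, strand)
        gene_id = tid.rsplit(".", 1)[0]
        t = TranscriptModel(tid, gene_id, exons, NOVEL)
        assembled.transcripts[tid] = t
        n = t.spliced_length
        if seq_kind == "long_orf":
            sequences[tid] = _long_orf_seq(rng, n, cfg.gc_target)
        else:
            sequences[tid] = _noncoding_seq(rng, n, cfg.gc_target)
        return t

    # planted lincRNAs ------------------------------------------------------
    linc_ids = [f"lincRNA.{i + 1}.1" for i in range(cfg.n_planted_lincrnas)]
    truth.planted_lincrnas = list(linc_ids)
    syn_ids = linc_ids[:n_specials]
    syn_flanks: dict[str, tuple[str, str]] = {}
    for tid, j in zip(syn_ids, syn_gap_idx):
        chrom, left, right, s, e = gaps[j]
        pos = s + int(0.40 * (e - s))
        add_novel(tid, chrom, pos, int(rng.integers(2, 5)), (150, 500))
        syn_flanks[tid] = (left, right)
    for tid in linc_ids[n_specials:]:
        j, pos = take_slot()
        chrom = gaps[j][0]
        add_novel(tid, chrom, pos, int(rng.integers(1, 5)), (250, 500))

    # planted ilncRNAs ------------------------------------------------------
    ilnc_ids = [f"ilncRNA.{i + 1}.1" for i in range(cfg.n_planted_ilncrnas)]
    for tid, g in zip(ilnc_ids, host_pool):
        host = f"GENE{g:03d}"
        host_t = ref.transcripts[f"{host}.t1"]
        intron = host_t.introns[0]
        pos = intron.start + 300
        t = add_novel(tid, intron.chrom, pos, 1, (300, 600))
        truth.planted_ilncrnas[tid] = host
        assert t.span.end < intron.end - 200

    # decoys ----------------------------------------------------------------
    decoy_rows_expr_low: list[str] = []
    for kind, (step, reason) in DECOY_KINDS.items():
        for k in range(cfg.n_decoys_per_filter):
            tid = f"decoy.{kind}.{k + 1}.1"
            if kind == "proximity":
                chrom, left, right, s, e = gaps[k % len(gaps)]
                pos = s + 400 + 60 * k
                add_novel(tid, chrom, pos, 2, (150, 400))
            elif kind == "min_length":
                j, pos = take_slot()
                add_novel(tid, gaps[j][0], pos, 1, (150, 200))
            elif kind == "monoexon_long":
                j, pos = take_slot()
                add_novel(tid, gaps[j][0], pos, 1, (10_001, 12_000))
            elif kind == "monoexon_repeat":
                j, pos = take_slot()
                add_novel(tid, gaps[j][0], pos, 1, (400, 900))
            elif kind == "long_orf":
                j, pos = take_slot()
                add_novel(tid, gaps[j][0], pos, 2, (600, 900), seq_kind="long_orf")
            else:
                j, pos = take_slot()
                add_novel(tid, gaps[j][0], pos, 2, (150, 500))
            if kind == "low_expression":
                decoy_rows_expr_low.append(tid)
            truth.decoys[tid] = (step, reason)

    # known lincRNAs in the reference --------------------------------------
    for i in range(cfg.n_known_lincrnas):
        j, pos = take_slot()
        chrom = gaps[j][0]
        strand = "+" if rng.random() < 0.5 else "-"
        exons = _exon_chain(rng, pos, int(rng.integers(1, 4)), (200, 800), (300, 1500), chrom, strand)
        gid = f"KNOWNLNC{i:02d}"
        ref.transcripts[f"{gid}.t1"] = TranscriptModel(f"{gid}.t1", gid, exons, KNOWN_LNCRNA)
    ref._invalidate()

    # repeats covering the designated mono-exon decoys ----------------------
    repeat_rows = []
    for tid, (step, reason) in truth.decoys.items():
        if reason != "monoexon_repeat":
            continue
        e = assembled.transcripts[tid].exons[0]
        repeat_rows.append((e.chrom, e.start + 50, min(e.end, e.start + 250)))
    repeat_rows.sort()

    # ---- expression -------------------------------------------------------
    novel_ids = sorted(assembled.transcripts)
    n_s = len(samples)
    half = cfg.samples_per_breed
    expr_rows: dict[str, np.ndarray] = {}
    for tid in novel_ids:
        expr_rows[tid] = _lognormal_row(rng, 5.0, n_s, cfg.expr_sigma)
    for gid in sorted(gene_spans):
        expr_rows[gid] = _lognormal_row(rng, 8.0, n_s, cfg.expr_sigma)
    for gid in sorted(g for g in ref.gene_spans if g.startswith("KNOWNLNC")):
        expr_rows[gid] = _lognormal_row(rng, 3.0, n_s, cfg.expr_sigma)

    # breed-specific planted rows
    nonsyn = linc_ids[n_specials:]
    bs_lori = nonsyn[: cfg.n_breed_specific_linc[0]]
    bs_zel = nonsyn[
        cfg.n_breed_specific_linc[0] : cfg.n_breed_specific_linc[0] + cfg.n_breed_specific_linc[1]
    ]
    bs_ilnc_lori = ilnc_ids[: cfg.n_breed_specific_ilnc[0]]
    bs_ilnc_zel = ilnc_ids[
        cfg.n_breed_specific_ilnc[0] : sum(cfg.n_breed_specific_ilnc)
    ]

    def plant_specific(tid: str, breed_idx: int) -> None:
        on = _lognormal_row(rng, 4.0, half, cfg.expr_sigma)
        off = rng.uniform(0.0, 0.3, size=half)
        row = np.concatenate([on, off] if breed_idx == 0 else [off, on])
        expr_rows[tid] = row
        truth.breed_specific[tid] = cfg.breeds[breed_idx]

    for tid in bs_lori + bs_ilnc_lori:
        plant_specific(tid, 0)
    for tid in bs_zel + bs_ilnc_zel:
        plant_specific(tid, 1)

    for tid in decoy_rows_expr_low:
        row = np.concatenate([[rng.uniform(1.2, 3.0)], rng.uniform(0.0, 0.8, size=n_s - 1)])
        expr_rows[tid] = row

    # trans pairs: shared latent profile, |r| > 0.999 by construction
    trans_lncs = syn_ids[: cfg.n_trans_pairs]
    partner_genes = sorted(gene_spans)[-(cfg.n_trans_pairs + cfg.n_trans_decoys):]
    for k, (tid, gid) in enumerate(zip(trans_lncs, partner_genes[: cfg.n_trans_pairs])):
        sign = -1 if k < cfg.n_trans_negative else 1
        while True:
            latent = rng.uniform(2.0, 10.0, size=n_s)
            x = latent * np.exp(rng.normal(0, 0.003, size=n_s))
            y = (2.0 * latent if sign > 0 else 14.0 - latent) * np.exp(
                rng.normal(0, 0.003, size=n_s)
            )
            r = float(np.corrcoef(x, y)[0, 1])
            if abs(r) > 0.999 and (x >= 1).sum() >= 2:
                break
        expr_rows[tid] = x
        expr_rows[gid] = y
        truth.trans_pairs.append((tid, gid, sign))
    decoy_lncs = syn_ids[cfg.n_trans_pairs : cfg.n_trans_pairs + cfg.n_trans_decoys]
    for tid, gid in zip(decoy_lncs, partner_genes[cfg.n_trans_pairs :]):
        while True:
            r = float(np.corrcoef(expr_rows[tid], expr_rows[gid])[0, 1])
            if abs(r) < 0.5:
                break
            expr_rows[tid] = _lognormal_row(rng, 5.0, n_s, cfg.expr_sigma)
        truth.trans_decoys.append((tid, gid))

    expr_df = pd.DataFrame.from_dict(expr_rows, orient="index", columns=samples)
    expr_df = expr_df.round(4).sort_index()

    # ---- DE table ---------------------------------------------------------
    de_lncs = (bs_lori[:3] + bs_zel[:3] + bs_ilnc_lori[:1])[: cfg.n_de_lncrnas]
    de_rows = []
    for fid in sorted(expr_df.index):
        mean_a = float(expr_df.loc[fid, samples[:half]].mean())
        mean_b = float(expr_df.loc[fid, samples[half:]].mean())
        if fid in de_lncs:
            fdr = float(rng.uniform(0.005, 0.09))
        elif fid.startswith("GENE") and rng.random() < 0.25:
            fdr = float(rng.uniform(0.001, 0.09))
        else:
            fdr = float(rng.uniform(0.3, 0.95))
        de_rows.append(
            {"feature_id": fid, "mean_a": round(mean_a, 4), "mean_b": round(mean_b, 4),
             "fdr": round(fdr, 4)}
        )
        if fid in de_lncs:
            truth.de_features[fid] = {
                "fdr": round(fdr, 4),
                "direction": "up" if mean_a > mean_b else "down",
            }
    de_df = pd.DataFrame(de_rows)

    # ---- evidence tables --------------------------------------------------
    hom_rows = []
    dbs = ("UniProtKB", "miRBase", "Rfam")
    for k, tid in enumerate(t for t, (s, r) in sorted(truth.decoys.items()) if r == "homology_hit"):
        hom_rows.append((tid, dbs[k % 3], 10.0 ** -float(rng.uniform(6, 20))))
    # boundary noise: hits at/above threshold never reject
    for tid in linc_ids[:2]:
        hom_rows.append((tid, "Rfam", 1e-5))
        hom_rows.append((tid, "UniProtKB", 1e-4))
    hom_df = pd.DataFrame(sorted(hom_rows), columns=["transcript_id", "db", "evalue"])

    dom_rows = []
    for k, tid in enumerate(t for t, (s, r) in sorted(truth.decoys.items()) if r == "protein_domain"):
        dom_rows.append((tid, f"PF{10000 + k:05d}", 10.0 ** -float(rng.uniform(6, 30))))
    dom_df = pd.DataFrame(sorted(dom_rows), columns=["transcript_id", "domain_id", "evalue"])

    score_rows = []
    coding_decoys = {t for t, (s, r) in truth.decoys.items() if r == "coding_vote"}
    for tid in novel_ids:
        if tid in coding_decoys:
            row = {
                "transcript_id": tid,
                "cpc2": round(float(rng.uniform(0.6, 0.95)), 4),
                "cnci": round(float(rng.uniform(0.2, 1.5)), 4),
                "cpat": round(float(rng.uniform(0.4, 0.9)), 4),
                "plek": round(float(rng.uniform(-1.5, -0.1)), 4),
                "feelnc": "noncoding",
            }
        else:
            row = {
                "transcript_id": tid,
                "cpc2": round(float(rng.uniform(0.0, 0.4)), 4),
                "cnci": round(float(rng.uniform(-2.0, -0.1)), 4),
                "cpat": round(float(rng.uniform(0.0, 0.3)), 4),
                "plek": round(float(rng.uniform(-2.0, -0.1)), 4),
                "feelnc": "noncoding",
            }
        score_rows.append(row)
    score_df = pd.DataFrame(score_rows)

    # ---- conservation hit tables -----------------------------------------
    def planted_lengths(n: int, mean: int) -> list[int]:
        if n == 0:
            return []
        deltas = rng.integers(10, 80, size=n // 2)
        out = []
        for d in deltas:
            out += [mean - int(d), mean + int(d)]
        if n % 2:
            out.append(mean)
        return out

    cons_files: dict[str, dict[str, list]] = {}
    for sp in cfg.species:
        n_c = cfg.n_conserved.get(sp, 0)
        ids = linc_ids[:n_c]
        lens = planted_lengths(n_c, cfg.mean_alignment_length.get(sp, 300))
        truth.conserved[sp] = dict(zip(ids, map(int, lens)))
        q_rows, s_rows = [], []
        for k, (tid, ln) in enumerate(zip(ids, lens)):
            e = 10.0 ** -float(rng.uniform(6, 30))
            foreign = f"NON{SPECIES_SUFFIX[sp]}T{k:06d}"
            row_q = [tid, foreign, 91.2, int(ln), 5, 0, 1, int(ln), 1, int(ln), e, 200.0]
            row_s = [foreign, tid, 91.2, int(ln), 5, 0, 1, int(ln), 1, int(ln), e, 200.0]
            (q_rows if k % 3 != 2 else s_rows).append(row_q if k % 3 != 2 else row_s)
        # sub-threshold noise hits: never conserved
        for tid in linc_ids[-2:]:
            q_rows.append([tid, f"NOISE{SPECIES_SUFFIX[sp]}", 80.0, 60, 10, 2, 1, 60, 1, 60, 1e-3, 40.0])
        cons_files[sp] = {"query": q_rows, "subject": s_rows}

    # ---- synteny tables ---------------------------------------------------
    syn_all_ids = syn_ids[: cfg.n_syntenic_all]
    partial_ids = syn_ids[cfg.n_syntenic_all : n_specials]
    partial_plan = {}
    subsets = [("bovine",), ("bovine", "human"), ("human",)]
    for k, tid in enumerate(partial_ids):
        partial_plan[tid] = subsets[k % len(subsets)]
    for tid in syn_all_ids:
        truth.syntenic[tid] = sorted(cfg.species)
    for tid, sps in partial_plan.items():
        truth.syntenic[tid] = sorted(sps)

    foreign_tables = {}
    for sp in cfg.species:
        suffix = SPECIES_SUFFIX[sp]
        genes_rows, lincs_rows = [], []
        cursor = 1
        chrom = f"{suffix}_1"
        planted_here = [t for t in syn_ids if sp in truth.syntenic.get(t, [])]
        for k, tid in enumerate(planted_here):
            left, right = syn_flanks[tid]
            genes_rows.append((f"{left}_{suffix}", chrom, cursor, cursor + 2999))
            lincs_rows.append((f"NONLNC{suffix}{k:04d}", chrom, cursor + 9000, cursor + 9999))
            genes_rows.append((f"{right}_{suffix}", chrom, cursor + 18000, cursor + 20999))
            cursor += 40_000
        # noise blocks: foreign-only flank pairs
        for k in range(3):
            genes_rows.append((f"FG{suffix}{2 * k}", chrom, cursor, cursor + 2999))
            lincs_rows.append((f"NOISELNC{suffix}{k}", chrom, cursor + 9000, cursor + 9999))
            genes_rows.append((f"FG{suffix}{2 * k + 1}", chrom, cursor + 18000, cursor + 20999))
            cursor += 40_000
        ortho = {
            g: f"{g}_{suffix}"
            for g in sorted(gene_spans)
            if g not in ("GENE058", "GENE059")  # planted missing orthologs
        }
        foreign_tables[sp] = (genes_rows, lincs_rows, ortho)

    # ---- QTL table --------------------------------------------------------
    anchors = (bs_lori[3:7] + bs_zel[3:5] if len(bs_zel) > 4 else bs_lori[3:9])
    anchors = (anchors + ilnc_ids[-1:])[: cfg.n_qtl_contained]
    qtl_rows = []
    traits = ["Tail fat deposition", "Fat weight", "Carcass fat percentage"]
    for k, tid in enumerate(anchors):
        span = assembled.transcripts[tid].span
        if k < 4:
            lm, rm = int(rng.integers(30_000, 200_000)), int(rng.integers(30_000, 200_000))
        else:
            lm, rm = int(rng.integers(500_000, 700_000)), int(rng.integers(500_000, 700_000))
        start = max(1, span.start + 1 - lm)
        end = span.end + rm
        trait = traits[0] if k < 4 else traits[1 + k % 2]
        qtl_rows.append({"qtl_id": f"QTL{126_987 + k}", "trait": trait,
                         "chrom": span.chrom, "start": start, "end": end})
    for k in range(cfg.n_qtl - cfg.n_qtl_contained):
        # an interval inside a non-host coding gene span: contains no lncRNA
        g = sorted(set(gene_spans) - {f"GENE{h:03d}" for h in host_pool})[k]
        s = gene_spans[g]
        qtl_rows.append({"qtl_id": f"QTL{127_900 + k}", "trait": traits[2],
                         "chrom": s.chrom, "start": s.start + 1, "end": s.end})
    qtl_df = pd.DataFrame(qtl_rows)

    # containment truth by direct arithmetic over planted gene spans
    lnc_spans = {
        tid: assembled.transcripts[tid].span
        for tid in list(linc_ids) + list(ilnc_ids)
    }
    for row in qtl_rows:
        qid = row["qtl_id"]
        truth.qtl_traits[qid] = row["trait"]
        inside = sorted(
            tid
            for tid, s in lnc_spans.items()
            if s.chrom == row["chrom"]
            and s.start >= row["start"] - 1
            and s.end <= row["end"]
        )
        if inside:
            truth.qtl_contained[qid] = inside

    # ---- PPI + modules ----------------------------------------------------
    prots = [f"PROT{i:03d}" for i in range(cfg.n_network_proteins)]
    ppi_rows = []
    cursor = 0
    for m in range(cfg.n_network_cliques):
        size = int(rng.integers(cfg.clique_size_range[0], cfg.clique_size_range[1] + 1))
        members = prots[cursor : cursor + size]
        cursor += size
        truth.modules.append(sorted(members))
        for i in range(size):
            for j in range(i + 1, size):
                ppi_rows.append(
                    (members[i], members[j], int(rng.integers(850, 1000)))
                )
    clique_nodes = {n for mod in truth.modules for n in mod}
    for i in range(len(prots)):
        for j in range(i + 1, len(prots)):
            if prots[i] in clique_nodes and prots[j] in clique_nodes:
                continue
            if rng.random() < cfg.ppi_noise_p:
                ppi_rows.append((prots[i], prots[j], int(rng.integers(150, 401))))
    ppi_df = pd.DataFrame(ppi_rows, columns=["protein1", "protein2", "combined_score"])

    # ---- gene sets --------------------------------------------------------
    background = sorted(gene_spans) + prots
    planted_set = sorted(truth.modules[0]) + prots[-3:]
    truth.enriched_set_id = "SET_PLANTED"
    gmt_lines = ["SET_PLANTED\tplanted enriched module genes\t" + "\t".join(planted_set)]
    for k in range(10):
        members = sorted(rng.choice(background, size=15, replace=False))
        gmt_lines.append(f"SET_RND{k:02d}\trandom background set\t" + "\t".join(members))

    # ---- write everything -------------------------------------------------
    def p(name: str) -> Path:
        q = outdir / name
        paths[name] = q
        return q

    write_gtf(ref, p("reference.gtf"))
    write_gtf(assembled, p("assembled.gtf"))
    SeqIO.write(
        [SeqRecord(Seq(sequences[t]), id=t, description="") for t in sorted(sequences)],
        p("transcripts.fa"),
        "fasta",
    )
    with open(p("repeats.bed"), "w") as fh:
        for chrom, s, e in repeat_rows:
            fh.write(f"{chrom}\t{s}\t{e}\tsimple_repeat\n")
    expr_df.to_csv(p("expression.tsv"), sep="\t", index_label="feature_id")
    pd.DataFrame({"sample": samples, "breed": [groups[s] for s in samples]}).to_csv(
        p("groups.tsv"), sep="\t", index=False
    )
    de_df.to_csv(p("de_table.tsv"), sep="\t", index=False)
    hom_df.to_csv(p("homology_hits.tsv"), sep="\t", index=False)
    dom_df.to_csv(p("domains.tsv"), sep="\t", index=False)
    score_df.to_csv(p("coding_scores.tsv"), sep="\t", index=False)
    for sp in cfg.species:
        for direction, rows in (("query", cons_files[sp]["query"]),
                                ("subject", cons_files[sp]["subject"])):
            with open(p(f"cons_{sp}_{direction}.tsv"), "w") as fh:
                for row in rows:
                    fh.write("\t".join(str(x) for x in row) + "\n")
        genes_rows, lincs_rows, ortho = foreign_tables[sp]
        pd.DataFrame(genes_rows, columns=["id", "chrom", "start", "end"]).to_csv(
            p(f"foreign_genes_{sp}.tsv"), sep="\t", index=False
        )
        pd.DataFrame(lincs_rows, columns=["id", "chrom", "start", "end"]).to_csv(
            p(f"foreign_lincs_{sp}.tsv"), sep="\t", index=False
        )
        pd.DataFrame(
            {"sheep_gene": list(ortho), "foreign_gene": list(ortho.values())}
        ).to_csv(p(f"orthologs_{sp}.tsv"), sep="\t", index=False)
    qtl_df.to_csv(p("qtl.tsv"), sep="\t", index=False)
    ppi_df.to_csv(p("ppi.tsv"), sep="\t", index=False)
    with open(p("gene_sets.gmt"), "w") as fh:
        fh.write("\n".join(gmt_lines) + "\n")
    truth.to_json(p("truth.json"))
    with open(p("manifest.json"), "w") as fh:
        json.dump({k: str(v.name) for k, v in sorted(paths.items())}, fh, indent=1)

    return World(cfg, outdir, paths, truth)
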
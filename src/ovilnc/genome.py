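"""Core genomic data types, GTF I/O, interval algebra and positional classification.

All coordinates are handled internally as 0-based, half-open intervals.
GTF files on disk are 1-based, inclusive; conversion happens at the I/O
boundary only.  Positional class codes follow the intergenic ("u") /
intronic ("i") vocabulary used when comparing an assembled transcriptome
against a reference annotation: a transcript is ``u`` when none of its
exons touches any annotated gene span, ``i`` when its whole span lies
inside a single intron of a protein-coding transcript, and ``overlap``
otherwise.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

#: biotype vocabulary used throughout the package
PROTEIN_CODING = "protein_coding"
KNOWN_LNCRNA = "known_lncRNA"
NOVEL = "novel"
OTHER = "other"

_BIOTYPE_FROM_GTF = {
    "protein_coding": PROTEIN_CODING,
    "lncRNA": KNOWN_LNCRNA,
    "lincRNA": KNOWN_LNCRNA,
    "novel": NOVEL,
}
_BIOTYPE_TO_GTF = {
    PROTEIN_CODING: "protein_coding",
    KNOWN_LNCRNA: "lncRNA",
    NOVEL: "novel",
    OTHER: "other",
}


class GTFParseError(ValueError):
    """Raised when a GTF file cannot be parsed; names the offending line."""


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def gene_distance(a: GenomeInterval, b: GenomeInterval) -> Optional[float]:
    """Gap in bp between two intervals.

    Returns ``None`` when the intervals intersect ("overlapping"), ``0``
    when they touch, and ``math.inf`` when they sit on different
    chromosomes.  With half-open coordinates the gap is
    ``max(starts) - min(ends)`` when non-negative.
    """
    if a.chrom != b.chrom:
        return math.inf
    d = max(a.start, b.start) - min(a.end, b.end)
    if d < 0:
        return None
    return d


@dataclass
class TranscriptModel:
    """A stranded, exon-structured transcript on one chromosome."""

    transcript_id: str
    gene_id: str
    exons: list[GenomeInterval]
    biotype: str = NOVEL

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"{self.transcript_id}: exons span chrom/strand")
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.start < prev.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomeInterval:
        return GenomeInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def spliced_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> list[GenomeInterval]:
        out = []
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.start > prev.end:
                out.append(GenomeInterval(self.chrom, prev.end, cur.start, self.strand))
        return out


@dataclass
class GenomeAnnotation:
    """A collection of transcripts with interval indexes for fast queries."""

    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._invalidate()

    def _invalidate(self) -> None:
        self._gene_spans: Optional[dict[str, GenomeInterval]] = None
        self._gene_biotypes: Optional[dict[str, str]] = None
        self._gene_tree: Optional[dict[str, IntervalTree]] = None
        self._intron_tree: Optional[dict[str, IntervalTree]] = None
        self._sorted_spans: Optional[dict[str, list]] = None

    def add(self, t: TranscriptModel) -> None:
        self.transcripts[t.transcript_id] = t
        self._invalidate()

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts.values())

    # ---- gene-level views -------------------------------------------------

    @property
    def gene_spans(self) -> dict[str, GenomeInterval]:
        """Gene span = hull of all transcripts sharing a gene_id."""
        if self._gene_spans is None:
            spans: dict[str, GenomeInterval] = {}
            biotypes: dict[str, str] = {}
            for t in self.transcripts.values():
                s = t.span
                if t.gene_id in spans:
                    old = spans[t.gene_id]
                    spans[t.gene_id] = GenomeInterval(
                        old.chrom, min(old.start, s.start), max(old.end, s.end), old.strand
                    )
                else:
                    spans[t.gene_id] = s
                    biotypes[t.gene_id] = t.biotype
                if t.biotype == PROTEIN_CODING:
                    biotypes[t.gene_id] = PROTEIN_CODING
            self._gene_spans = spans
            self._gene_biotypes = biotypes
        return self._gene_spans

    @property
    def gene_biotypes(self) -> dict[str, str]:
        _ = self.gene_spans
        return self._gene_biotypes  # type: ignore[return-value]

    def genes_of_biotype(self, *biotypes: str) -> dict[str, GenomeInterval]:
        wanted = set(biotypes)
        return {
            g: s for g, s in self.gene_spans.items() if self.gene_biotypes[g] in wanted
        }

    def _annotated_gene_tree(self) -> dict[str, IntervalTree]:
        """Interval trees over gene spans of coding and known-lncRNA genes."""
        if self._gene_tree is None:
            trees: dict[str, IntervalTree] = {}
            for g, s in self.genes_of_biotype(PROTEIN_CODING, KNOWN_LNCRNA).items():
                trees.setdefault(s.chrom, IntervalTree()).addi(s.start, s.end, g)
            self._gene_tree = trees
        return self._gene_tree

    def _coding_intron_tree(self) -> dict[str, IntervalTree]:
        if self._intron_tree is None:
            trees: dict[str, IntervalTree] = {}
            for t in self.transcripts.values():
                if t.biotype != PROTEIN_CODING:
                    continue
                for iv in t.introns:
                    trees.setdefault(iv.chrom, IntervalTree()).addi(
                        iv.start, iv.end, t.gene_id
                    )
            self._intron_tree = trees
        return self._intron_tree

    def coding_spans_sorted(self) -> dict[str, list[tuple[int, int, str]]]:
        """Per-chrom protein-coding gene spans sorted by start (for scans)."""
        if self._sorted_spans is None:
            per: dict[str, list[tuple[int, int, str]]] = {}
            for g, s in self.genes_of_biotype(PROTEIN_CODING).items():
                per.setdefault(s.chrom, []).append((s.start, s.end, g))
            for lst in per.values():
                lst.sort()
            self._sorted_spans = per
        return self._sorted_spans

    def nearest_coding_flanks(
        self, span: GenomeInterval
    ) -> tuple[Optional[str], Optional[str]]:
        """Nearest protein-coding genes strictly left and strictly right of a span.

        "Strictly left" means the gene span ends at or before ``span.start``;
        symmetric on the right.  Returns gene ids (``None`` when a side has no
        gene).  Ties on distance are broken by gene id for determinism.
        A gene whose span contains the query (the host of an intronic query)
        is reported as both flanks.
        """
        spans = self.coding_spans_sorted().get(span.chrom, [])
        containing = sorted(g for s, e, g in spans if s <= span.start and span.end <= e)
        if containing:
            return containing[0], containing[0]
        left, left_d = None, None
        right, right_d = None, None
        for s, e, g in spans:
            if e <= span.start:
                d = span.start - e
                if left_d is None or d < left_d or (d == left_d and g < left):
                    left, left_d = g, d
            elif s >= span.end:
                d = s - span.end
                if right_d is None or d < right_d or (d == right_d and g < right):
                    right, right_d = g, d
        return left, right


# ---------------------------------------------------------------------------
# class codes
# ---------------------------------------------------------------------------

CLASS_U = "u"
CLASS_I = "i"
CLASS_OVERLAP = "overlap"


def assign_class_code(query: TranscriptModel, ann: GenomeAnnotation) -> str:
    """Positional class of a query transcript against a reference annotation.

    ``u`` — no exon of the query overlaps any annotated (protein-coding or
    known-lncRNA) gene span; ``i`` — the whole query span lies within a
    single intron of some protein-coding transcript (strand ignored);
    ``overlap`` otherwise.
    """
    trees = ann._annotated_gene_tree()
    tree = trees.get(query.chrom)
    if tree is None or not any(tree.overlap(e.start, e.end) for e in query.exons):
        return CLASS_U
    span = query.span
    introns = ann._coding_intron_tree().get(query.chrom)
    if introns is not None:
        for iv in introns.overlap(span.start, span.end):
            if iv.begin <= span.start and span.end <= iv.end:
                return CLASS_I
    return CLASS_OVERLAP


# ---------------------------------------------------------------------------
# locus clustering
# ---------------------------------------------------------------------------


class _DSU:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        p = self.parent.setdefault(x, x)
        if p != x:
            self.parent[x] = p = self.find(p)
        return p

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def cluster_loci(transcripts: Iterable[TranscriptModel]) -> dict[str, str]:
    """Group transcripts into loci by transitive same-strand exonic overlap.

    Two transcripts share a locus iff they are connected (directly or
    through intermediates) by >= 1 bp of exon overlap on the same strand.
    The locus id is the lexicographically smallest member transcript id.
    """
    ts = list(transcripts)
    dsu = _DSU()
    by_key: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for t in ts:
        dsu.find(t.transcript_id)
        for e in t.exons:
            by_key.setdefault((t.chrom, t.strand), []).append(
                (e.start, e.end, t.transcript_id)
            )
    for exons in by_key.values():
        exons.sort()
        cur_end = -1
        cur_tid = None
        for s, e, tid in exons:
            if cur_tid is not None and s < cur_end:
                dsu.union(cur_tid, tid)
                cur_end = max(cur_end, e)
            else:
                cur_tid, cur_end = tid, e
    roots: dict[str, list[str]] = {}
    for t in ts:
        roots.setdefault(dsu.find(t.transcript_id), []).append(t.transcript_id)
    out: dict[str, str] = {}
    for members in roots.values():
        locus = min(members)
        for tid in members:
            out[tid] = locus
    return out


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> dict[str, IntervalTree]:
    """Read a BED track (0-based half-open) into per-chromosome interval trees."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}: line {lineno}: BED needs >= 3 fields")
            trees.setdefault(f[0], IntervalTree()).addi(int(f[1]), int(f[2]))
    return trees


def _prevalidate_gtf(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GTFParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GTFParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start < 1 or end < start:
                raise GTFParseError(
                    f"{path}: line {lineno}: bad coordinate range {start}-{end}"
                )


def read_gtf(path: str | Path) -> GenomeAnnotation:
    """Read a GTF file (1-based inclusive on disk) into a GenomeAnnotation.

    Exons are grouped by ``transcript_id``; the biotype comes from the
    ``gene_biotype`` attribute, with ``lncRNA`` mapped to the known-lncRNA
    biotype.  Transcript features without any exon line are logged and
    dropped.
    """
    path = Path(path)
    _prevalidate_gtf(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    exons: dict[str, list[GenomeInterval]] = {}
    meta: dict[str, tuple[str, str]] = {}
    declared: set[str] = set()
    for f in db.all_features():
        tid = f.attributes.get("transcript_id", [None])[0]
        if f.featuretype == "transcript" and tid:
            declared.add(tid)
        if f.featuretype != "exon":
            continue
        if tid is None:
            raise GTFParseError(f"{path}: exon without transcript_id at {f.seqid}:{f.start}")
        gid = f.attributes.get("gene_id", [tid])[0]
        raw_bt = f.attributes.get("gene_biotype", [None])[0]
        if raw_bt is None:
            bt = NOVEL
        else:
            bt = _BIOTYPE_FROM_GTF.get(raw_bt, OTHER)
        exons.setdefault(tid, []).append(
            GenomeInterval(f.seqid, f.start - 1, f.end, f.strand or ".")
        )
        meta[tid] = (gid, bt)
    for tid in declared - set(exons):
        log.warning("%s: transcript %s has zero exons; record dropped", path, tid)
    ann = GenomeAnnotation()
    for tid, ex in exons.items():
        gid, bt = meta[tid]
        ann.transcripts[tid] = TranscriptModel(tid, gid, ex, bt)
    ann._invalidate()
    return ann


def write_gtf(ann: GenomeAnnotation, path: str | Path, source: str = "ovilnc",
              extra_attrs: Optional[Mapping[str, Mapping[str, str]]] = None) -> None:
    """Write an annotation as GTF (1-based inclusive), transcript + exon lines.

    ``extra_attrs`` optionally maps transcript_id -> {attr: value} for
    additional attributes (e.g. a candidate category).
    """
    ts = sorted(
        ann.transcripts.values(), key=lambda t: (t.chrom, t.span.start, t.transcript_id)
    )
    with open(path, "w") as fh:
        for t in ts:
            bt = _BIOTYPE_TO_GTF.get(t.biotype, t.biotype)
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'gene_biotype "{bt}";'
            )
            if extra_attrs and t.transcript_id in extra_attrs:
                for k, v in extra_attrs[t.transcript_id].items():
                    attrs += f' {k} "{v}";'
            span = t.span
            fh.write(
                f"{t.chrom}\t{source}\ttranscript\t{span.start + 1}\t{span.end}\t.\t"
                f"{t.strand}\t.\t{attrs}\n"
            )
            for e in t.exons:
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )
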
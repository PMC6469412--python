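"""The stepwise lncRNA filtering funnel.

Unannotated transcripts classified as intergenic ("u") or intronic ("i")
against the reference annotation are passed through a stringent sequence
of filters — structural, expression, homology, protein-domain,
coding-potential majority vote, ORF length and gene proximity — and the
survivors are reported as candidate lincRNAs (intergenic) or ilncRNAs
(intronic), together with a per-step provenance report.

All thresholds follow the strict/inclusive readings of the published
wording: "longer than 200 nt" (strict), "FPKM >= 1 in at least two
samples" (inclusive), "E-value < 1e-5" (strict), "predicted coding by at
least three of five tools", "ORF < 300 aa" kept (strict), "distance
< 1 kb" excluded (strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

from .genome import (
    CLASS_I,
    CLASS_U,
    GenomeAnnotation,
    GenomeInterval,
    PROTEIN_CODING,
    TranscriptModel,
    assign_class_code,
    gene_distance,
)

log = logging.getLogger(__name__)

FEELNC_CODING = "coding"
FEELNC_NONCODING = "noncoding"
FEELNC_MISSING = "missing"

HOMOLOGY_DATABASES = ("UniProtKB", "miRBase", "Rfam")


@dataclass
class CodingScores:
    """Scores of the five coding-potential predictors for one transcript."""

    cpc2: float
    cnci: float
    cpat: float
    plek: float
    feelnc_label: str = FEELNC_MISSING

    def __post_init__(self) -> None:
        for name in ("cpc2", "cnci", "cpat", "plek"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)):
                raise TypeError(f"{name} score must be numeric, got {v!r}")
        if self.feelnc_label not in (FEELNC_CODING, FEELNC_NONCODING, FEELNC_MISSING):
            raise ValueError(f"bad FEElnc label {self.feelnc_label!r}")


@dataclass
class EvidenceRecord:
    """Per-transcript external evidence consumed by the funnel."""

    transcript_id: str
    hits: list[tuple[str, float]] = field(default_factory=list)
    domain_hits: list[tuple[str, float]] = field(default_factory=list)
    coding_scores: Optional[CodingScores] = None
    orf_aa: int = 0


@dataclass
class FilterParams:
    """Thresholds of the funnel (defaults are the published values)."""

    min_length_nt: int = 200
    max_monoexon_length_nt: int = 10000
    min_fpkm: float = 1.0
    min_expressed_samples: int = 2
    homology_evalue_max: float = 1e-5
    domain_evalue_max: Optional[float] = None  # None: any reported hit rejects
    coding_votes_to_reject: int = 3
    orf_reject_aa: int = 300
    min_gene_distance_nt: int = 1000

    def __post_init__(self) -> None:
        if self.coding_votes_to_reject > 5:
            raise ValueError("at most five coding-potential voters exist")


@dataclass
class Decision:
    keep: bool
    reason: Optional[str] = None

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.keep


KEEP = Decision(True)


@dataclass
class FunnelStep:
    step_name: str
    input_count: int
    removed_count: int
    surviving_ids: tuple[str, ...]


@dataclass
class FunnelReport:
    """Ordered per-step accounting of the funnel."""

    steps: list[FunnelStep] = field(default_factory=list)
    #: transcript_id -> rejection reason, for transcripts removed at any step
    rejections: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, input_ids: Sequence[str], surviving: Sequence[str]) -> None:
        self.steps.append(
            FunnelStep(name, len(input_ids), len(input_ids) - len(surviving),
                       tuple(surviving))
        )

    def to_rows(self) -> list[dict]:
        return [
            {
                "step": s.step_name,
                "input": s.input_count,
                "removed": s.removed_count,
                "surviving": s.input_count - s.removed_count,
            }
            for s in self.steps
        ]


@dataclass
class LncRNACandidate:
    """A surviving transcript with its positional category."""

    transcript: TranscriptModel
    category: str  # "lincRNA" | "ilncRNA"
    class_code: str
    previously_reported: bool = False

    @property
    def transcript_id(self) -> str:
        return self.transcript.transcript_id


# ---------------------------------------------------------------------------
# individual filters
# ---------------------------------------------------------------------------


def structural_filter(
    t: TranscriptModel,
    repeats: Mapping[str, IntervalTree] | None,
    p: FilterParams,
) -> Decision:
    """Length / mono-exon / simple-repeat structural rules.

    Rejects transcripts not longer than 200 nt; single-exon transcripts
    longer than 10 kb; and single-exon transcripts overlapping a simple
    repeat by >= 1 bp.
    """
    if t.spliced_length <= p.min_length_nt:
        return Decision(False, "min_length")
    if t.exon_count == 1:
        if t.spliced_length > p.max_monoexon_length_nt:
            return Decision(False, "monoexon_too_long")
        if repeats:
            tree = repeats.get(t.chrom)
            if tree is not None and any(
                tree.overlap(e.start, e.end) for e in t.exons
            ):
                return Decision(False, "monoexon_repeat")
    return KEEP


def expression_filter(
    t_id: str, expr: "ExpressionMatrix", p: FilterParams
) -> Decision:
    """Keep transcripts with FPKM >= 1 in at least two samples (breeds pooled)."""
    if t_id not in expr.df.index:
        log.warning("expression filter: %s missing from matrix", t_id)
        return Decision(False, "missing_expression")
    n = int((expr.df.loc[t_id] >= p.min_fpkm).sum())
    if n >= p.min_expressed_samples:
        return KEEP
    return Decision(False, "low_expression")


def homology_filter(ev: EvidenceRecord, p: FilterParams) -> Decision:
    """Reject on any significant hit (E < 1e-5) in UniProtKB, miRBase or Rfam."""
    for _db, e in ev.hits:
        if e < p.homology_evalue_max:
            return Decision(False, "homology_hit")
    return KEEP


def domain_filter(ev: EvidenceRecord, p: FilterParams | None = None) -> Decision:
    """Reject on any reported protein-domain (Pfam) hit.

    No e-value threshold applies by default — any hit a domain scanner
    reported counts; an optional cutoff can be enabled through
    ``FilterParams.domain_evalue_max``.
    """
    emax = p.domain_evalue_max if p is not None else None
    for _dom, e in ev.domain_hits:
        if emax is None or e < emax:
            return Decision(False, "protein_domain")
    return KEEP


def coding_vote(scores: CodingScores) -> tuple[int, str]:
    """Majority vote of the five coding-potential predictors.

    A tool votes "coding" when CPC2 > 0.5, CNCI > 0, CPAT > 0.36,
    PLEK > 0, or FEElnc labels the transcript coding (a missing FEElnc
    label counts as a noncoding vote).  The verdict is coding iff at
    least three of the five tools vote coding.
    """
    votes = (
        int(scores.cpc2 > 0.5)
        + int(scores.cnci > 0)
        + int(scores.cpat > 0.36)
        + int(scores.plek > 0)
        + int(scores.feelnc_label == FEELNC_CODING)
    )
    return votes, ("coding" if votes >= 3 else "noncoding")


STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def find_longest_orf(seq: str) -> int:
    """Length (aa) of the longest sense-strand ORF of a transcript sequence.

    An ORF starts at ATG and runs to the first in-frame stop codon
    (length = codons before the stop) or to the end of the sequence
    (3'-partial, complete codons only).  All three sense frames are
    scanned; 0 when no ATG-initiated ORF exists.
    """
    seq = seq.upper()
    n = len(seq)
    best = 0
    for frame in range(3):
        i = frame
        orf_start: Optional[int] = None
        while i + 3 <= n:
            codon = seq[i : i + 3]
            if orf_start is None:
                if codon == "ATG":
                    orf_start = i
            elif codon in STOP_CODONS:
                best = max(best, (i - orf_start) // 3)
                orf_start = None
            i += 3
        if orf_start is not None:  # ran off the 3' end without a stop
            best = max(best, (n - orf_start) // 3)
    return best


def orf_filter(ev: EvidenceRecord, p: FilterParams) -> Decision:
    """Keep transcripts whose longest ORF is shorter than 300 aa."""
    if ev.orf_aa >= p.orf_reject_aa:
        return Decision(False, "long_orf")
    return KEEP


def proximity_filter(
    t: TranscriptModel, ann: GenomeAnnotation, p: FilterParams
) -> Decision:
    """Drop intergenic transcripts closer than 1 kb to a protein-coding gene."""
    span = t.span
    for gspan in ann.genes_of_biotype(PROTEIN_CODING).values():
        d = gene_distance(span, gspan)
        if d is None or d < p.min_gene_distance_nt:
            return Decision(False, "gene_proximity")
    return KEEP


# ---------------------------------------------------------------------------
# the funnel
# ---------------------------------------------------------------------------


class FunnelError(ValueError):
    """Inconsistent inputs to the funnel (mismatched transcript ids)."""


def run_funnel(
    assembled: GenomeAnnotation,
    ref: GenomeAnnotation,
    repeats: Mapping[str, IntervalTree] | None,
    expr: "ExpressionMatrix",
    evidence: Mapping[str, EvidenceRecord],
    params: FilterParams | None = None,
    sequences: Optional[Mapping[str, str]] = None,
    known_lnc_catalog: Optional[GenomeAnnotation] = None,
) -> tuple[list[LncRNACandidate], FunnelReport]:
    """Run the full funnel over an assembled transcript set.

    Steps, in order: positional class selection (keep ``u`` and ``i``
    only), structural, expression, homology, protein domain, coding-
    potential vote, ORF length, and — for intergenic transcripts only —
    gene proximity.  Survivors are categorized as lincRNA (``u``) or
    ilncRNA (``i``).  When ``sequences`` is supplied the ORF length is
    computed with :func:`find_longest_orf`, otherwise the value carried
    in the evidence record is used.  When a known-lncRNA catalog is
    supplied, candidates with >= 1 bp exonic overlap against it are
    flagged as previously reported.

    Returns the candidate list and a :class:`FunnelReport` with one row
    per step.
    """
    p = params or FilterParams()
    report = FunnelReport()
    rejected: dict[str, str] = {}

    ids = sorted(assembled.transcripts)
    codes = {tid: assign_class_code(assembled.transcripts[tid], ref) for tid in ids}
    surv = [tid for tid in ids if codes[tid] in (CLASS_U, CLASS_I)]
    for tid in ids:
        if tid not in surv:
            rejected[tid] = "class_overlap"
    report.add("class_code_selection", ids, surv)

    def apply(name: str, fn) -> None:
        nonlocal surv
        prev = surv
        keep = []
        for tid in prev:
            d = fn(tid)
            if d.keep:
                keep.append(tid)
            else:
                rejected[tid] = d.reason or name
        surv = keep
        report.add(name, prev, surv)

    apply("structural", lambda tid: structural_filter(assembled.transcripts[tid], repeats, p))
    apply("expression", lambda tid: expression_filter(tid, expr, p))

    missing_ev = [tid for tid in surv if tid not in evidence]
    if missing_ev:
        raise FunnelError(
            "transcripts missing from the evidence tables: " + ", ".join(missing_ev)
        )
    apply("homology", lambda tid: homology_filter(evidence[tid], p))
    apply("protein_domain", lambda tid: domain_filter(evidence[tid], p))

    def vote_fn(tid: str) -> Decision:
        scores = evidence[tid].coding_scores
        if scores is None:
            raise FunnelError(f"{tid}: no coding-potential scores")
        _votes, verdict = coding_vote(scores)
        return Decision(verdict == "noncoding", None if verdict == "noncoding" else "coding_vote")

    apply("coding_potential", vote_fn)

    def orf_fn(tid: str) -> Decision:
        ev = evidence[tid]
        if sequences is not None and tid in sequences:
            ev.orf_aa = find_longest_orf(sequences[tid])
        return orf_filter(ev, p)

    apply("orf_length", orf_fn)

    def prox_fn(tid: str) -> Decision:
        if codes[tid] != CLASS_U:
            return KEEP
        return proximity_filter(assembled.transcripts[tid], ref, p)

    apply("gene_proximity", prox_fn)

    report.rejections = dict(rejected)
    candidates = []
    for tid in surv:
        t = assembled.transcripts[tid]
        category = "lincRNA" if codes[tid] == CLASS_U else "ilncRNA"
        reported = False
        if known_lnc_catalog is not None:
            reported = _any_exonic_overlap(t, known_lnc_catalog)
        candidates.append(LncRNACandidate(t, category, codes[tid], reported))
    return candidates, report


def _any_exonic_overlap(t: TranscriptModel, catalog: GenomeAnnotation) -> bool:
    for other in catalog:
        if other.chrom != t.chrom:
            continue
        for e in t.exons:
            for oe in other.exons:
                if e.overlaps(oe):
                    return True
    return False


def rejection_table(
    assembled: GenomeAnnotation, report: FunnelReport
) -> dict[str, str]:
    """Map transcript_id -> funnel step at which it was removed."""
    out: dict[str, str] = {}
    prev: Optional[set[str]] = None
    all_ids = set(assembled.transcripts)
    for step in report.steps:
        cur = set(step.surviving_ids)
        removed = (prev if prev is not None else all_ids) - cur
        for tid in removed:
            out[tid] = step.step_name
        prev = cur
    return out
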
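"""Cross-species sequence conservation summaries and flanking-ortholog synteny.

Conservation is summarized from BLAST tabular (outfmt-6-like) hit tables
at E <= 1e-5, pooling hits from both query directions.  Synteny asks a
sequence-free question: does another species hold a lincRNA whose
nearest flanking protein-coding genes are the orthologs of the sheep
lincRNA's flanking pair?  Flank matching is unordered and orientation
blind by default (a strict-order mode is available).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .genome import GenomeAnnotation, GenomeInterval, TranscriptModel

SHEEP_AS_QUERY = "sheep_as_query"
SHEEP_AS_SUBJECT = "sheep_as_subject"

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast6(path: str | Path, species: str, direction: str) -> pd.DataFrame:
    """Read an outfmt-6 BLAST table into the internal hit schema.

    The sheep transcript id is taken from the query column when sheep was
    the query and from the subject column otherwise.
    """
    if direction not in (SHEEP_AS_QUERY, SHEEP_AS_SUBJECT):
        raise ValueError(f"bad direction {direction!r}")
    df = pd.read_csv(path, sep="\t", header=None, names=BLAST6_COLUMNS)
    sheep = df["qseqid"] if direction == SHEEP_AS_QUERY else df["sseqid"]
    other = df["sseqid"] if direction == SHEEP_AS_QUERY else df["qseqid"]
    return pd.DataFrame(
        {
            "query_id": sheep.astype(str),
            "subject_id": other.astype(str),
            "species": species,
            "e_value": df["evalue"].astype(float),
            "alignment_length": df["length"].astype(int),
            "direction": direction,
        }
    )


def conservation_summary(
    hits: pd.DataFrame,
    emax: float = 1e-5,
    transcript_to_gene: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Per-species conservation counts and mean alignment length.

    A transcript is conserved in a species iff it has any hit with
    E <= ``emax`` in either direction; a gene is conserved iff any member
    transcript is.  The mean alignment length is taken over the best hit
    (lowest E, ties broken by longest alignment) per conserved
    transcript.
    """
    sig = hits[hits["e_value"] <= emax]
    rows = []
    for species, grp in sig.groupby("species", sort=True):
        best = (
            grp.sort_values(["e_value", "alignment_length"], ascending=[True, False])
            .groupby("query_id")
            .first()
        )
        n_tr = len(best)
        n_gene = (
            len({transcript_to_gene.get(t, t) for t in best.index})
            if transcript_to_gene is not None
            else n_tr
        )
        rows.append(
            {
                "species": species,
                "conserved_transcripts": n_tr,
                "conserved_genes": n_gene,
                "mean_alignment_length": float(best["alignment_length"].mean()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["species", "conserved_transcripts", "conserved_genes",
                 "mean_alignment_length"],
    )


def conserved_ids(hits: pd.DataFrame, species: str, emax: float = 1e-5) -> set[str]:
    sig = hits[(hits["species"] == species) & (hits["e_value"] <= emax)]
    return set(sig["query_id"])


# ---------------------------------------------------------------------------
# synteny
# ---------------------------------------------------------------------------


@dataclass
class SyntenyRecord:
    lnc_id: str
    species: str
    sheep_neighbors: tuple[Optional[str], Optional[str]]
    matched_foreign_linc: Optional[str]
    conserved_synteny: bool
    flag: Optional[str] = None  # e.g. "incomplete_flank", "missing_ortholog"


def _nearest_flanks(
    span: tuple[int, int], genes: Sequence[tuple[int, int, str]]
) -> tuple[Optional[str], Optional[str]]:
    """Nearest gene strictly left / right of (start, end) among sorted spans."""
    start, end = span
    left, left_d = None, None
    right, right_d = None, None
    for s, e, g in genes:
        if e <= start:
            d = start - e
            if left_d is None or d < left_d or (d == left_d and g < left):
                left, left_d = g, d
        elif s >= end:
            d = s - end
            if right_d is None or d < right_d or (d == right_d and g < right):
                right, right_d = g, d
    return left, right


def foreign_flank_pairs(
    foreign_lincs: pd.DataFrame,
    foreign_genes: pd.DataFrame,
    ordered: bool = False,
) -> dict[frozenset | tuple, set[str]]:
    """Flanking-gene pair -> foreign lincRNA ids, from 1-based position tables.

    Both tables carry columns (id, chrom, start, end).  The pair is an
    unordered frozenset by default, or a left-to-right tuple when
    ``ordered``.
    """
    genes_by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for _, row in foreign_genes.iterrows():
        genes_by_chrom.setdefault(str(row["chrom"]), []).append(
            (int(row["start"]) - 1, int(row["end"]), str(row["id"]))
        )
    for lst in genes_by_chrom.values():
        lst.sort()
    out: dict = {}
    for _, row in foreign_lincs.iterrows():
        genes = genes_by_chrom.get(str(row["chrom"]), [])
        left, right = _nearest_flanks(
            (int(row["start"]) - 1, int(row["end"])), genes
        )
        if left is None or right is None:
            continue
        key = (left, right) if ordered else frozenset((left, right))
        out.setdefault(key, set()).add(str(row["id"]))
    return out


def synteny_conserved(
    lnc: "TranscriptModel",
    sheep_ann: GenomeAnnotation,
    species: str,
    foreign_pairs: Mapping,
    orthologs: Mapping[str, str],
    ordered: bool = False,
) -> SyntenyRecord:
    """Is a sheep lincRNA's flanking-ortholog pair realized around a foreign lincRNA?

    ``foreign_pairs`` comes from :func:`foreign_flank_pairs` for the same
    ``ordered`` setting; ``orthologs`` maps sheep gene id -> foreign gene
    id.  A missing flank or a missing ortholog makes the record
    non-conserved, with a flag saying why.
    """
    left, right = sheep_ann.nearest_coding_flanks(lnc.span)
    if left is None or right is None:
        return SyntenyRecord(
            lnc.transcript_id, species, (left, right), None, False, "incomplete_flank"
        )
    ol, orr = orthologs.get(left), orthologs.get(right)
    if ol is None or orr is None:
        return SyntenyRecord(
            lnc.transcript_id, species, (left, right), None, False, "missing_ortholog"
        )
    key = (ol, orr) if ordered else frozenset((ol, orr))
    match = foreign_pairs.get(key)
    if match:
        return SyntenyRecord(
            lnc.transcript_id, species, (left, right), sorted(match)[0], True
        )
    return SyntenyRecord(lnc.transcript_id, species, (left, right), None, False)


def synteny_venn(records: Iterable[SyntenyRecord]) -> dict:
    """Per-species conserved sets and counts for every Venn partition region.

    Returns ``{"sets": {species: set}, "partition": {tuple(species subset):
    count}}`` where each lncRNA is counted exactly once, in the region of
    the species combination it is conserved in.
    """
    sets: dict[str, set[str]] = {}
    species_seen: set[str] = set()
    for r in records:
        species_seen.add(r.species)
        if r.conserved_synteny:
            sets.setdefault(r.species, set()).add(r.lnc_id)
    species = sorted(species_seen)
    for sp in species:
        sets.setdefault(sp, set())
    membership: dict[str, tuple[str, ...]] = {}
    for lnc in set().union(*sets.values()) if sets else set():
        membership[lnc] = tuple(sp for sp in species if lnc in sets[sp])
    partition: dict[tuple[str, ...], int] = {}
    for k in range(1, len(species) + 1):
        for combo in combinations(species, k):
            partition[combo] = sum(1 for m in membership.values() if m == combo)
    return {"sets": sets, "partition": partition}


def read_positions_tsv(path: str | Path) -> pd.DataFrame:
    """Read an (id, chrom, start, end) position table (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"id", "chrom", "start", "end"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return df


def read_orthologs_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
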
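"""Co-localization of lncRNA gene loci with QTL intervals.

A lncRNA gene is annotated to a QTL iff its start *and* end lie inside
the QTL interval on the same chromosome (containment; partial overlap
does not count).  QTL tables are accepted as a 5-column TSV
(qtl_id, trait, chrom, start, end) or an AnimalQTLdb-style GFF dump;
positions on disk are 1-based inclusive, chromosome names are normalized
by stripping a "Chr." prefix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .genome import GenomeInterval


@dataclass(frozen=True)
class QTLRecord:
    qtl_id: str
    trait: str
    interval: GenomeInterval  # internal 0-based half-open

    @property
    def span_bp(self) -> int:
        """Interval span; equals (end - start + 1) of the 1-based table."""
        return self.interval.length


def _norm_chrom(c: str) -> str:
    return re.sub(r"^[Cc]hr\.?", "", str(c).strip())


def read_qtl_table(path: str | Path) -> list[QTLRecord]:
    """Read a QTL table (TSV with header, or GFF-like dump)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") or len(first.rstrip("\n").split("\t")) == 9:
        return _read_qtl_gff(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"qtl_id", "trait", "chrom", "start", "end"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            QTLRecord(
                str(row["qtl_id"]),
                str(row["trait"]),
                GenomeInterval(_norm_chrom(row["chrom"]), int(row["start"]) - 1, int(row["end"])),
            )
        )
    return out


def _read_qtl_gff(path: Path) -> list[QTLRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            qtl_id = attrs.get("QTL_ID", attrs.get("ID", f"{f[0]}:{f[3]}-{f[4]}"))
            trait = attrs.get("trait", attrs.get("Name", ""))
            out.append(
                QTLRecord(
                    str(qtl_id).strip(),
                    str(trait).strip().strip('"'),
                    GenomeInterval(_norm_chrom(f[0]), int(f[3]) - 1, int(f[4])),
                )
            )
    return out


def qtl_contains(lnc: GenomeInterval, qtl: QTLRecord) -> bool:
    """True iff the lncRNA interval lies entirely within the QTL interval."""
    return qtl.interval.contains(lnc)


def qtl_annotate(
    lncs: dict[str, GenomeInterval],
    qtls: Sequence[QTLRecord],
    trait_filter: Optional[str] = None,
    max_qtl_span: Optional[int] = None,
) -> pd.DataFrame:
    """All (lncRNA gene, QTL) containment pairs, optionally restricted.

    ``trait_filter`` keeps QTL whose trait contains the given substring
    (case-insensitive); ``max_qtl_span`` keeps QTL strictly shorter than
    the given span in bp.  Output rows: lnc_id, qtl_id, trait, qtl_span.
    """
    kept = []
    for q in qtls:
        if trait_filter is not None and trait_filter.lower() not in q.trait.lower():
            continue
        if max_qtl_span is not None and q.span_bp >= max_qtl_span:
            continue
        kept.append(q)
    rows = []
    for lnc_id in sorted(lncs):
        iv = lncs[lnc_id]
        for q in kept:
            if qtl_contains(iv, q):
                rows.append(
                    {"lnc_id": lnc_id, "qtl_id": q.qtl_id, "trait": q.trait,
                     "qtl_span": q.span_bp}
                )
    return pd.DataFrame(rows, columns=["lnc_id", "qtl_id", "trait", "qtl_span"])


def genes_per_trait(annotation: pd.DataFrame) -> pd.Series:
    """Distinct lncRNA genes per trait from a qtl_annotate table."""
    if annotation.empty:
        return pd.Series(dtype=int)
    return annotation.groupby("trait")["lnc_id"].nunique()
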
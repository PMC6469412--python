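"""Packaged worked-example tables.

Two small tables ship with the package, transcribed from the published
study of fat-tail lncRNAs in Lori-Bakhtiari vs Zel sheep:

* ``tail_fat_qtl`` — the novel lncRNAs reported inside "Tail fat
  deposition" QTL, with their genomic positions and the QTL intervals
  (1-based inclusive coordinates, sheep Oar_v3.1).
* ``de_lncrnas`` — the differentially expressed lncRNAs with per-breed
  mean FPKM (breed A = Lori-Bakhtiari, breed B = Zel) and FDR, plus
  their closest flanking mRNAs.

They serve as ready-made inputs for the QTL containment and DE
classification worked examples.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .genome import GenomeInterval
from .qtl import QTLRecord


def _read(name: str) -> pd.DataFrame:
    with resources.files("ovilnc.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str, "qtl_chrom": str})


def tail_fat_qtl() -> pd.DataFrame:
    """lncRNA / QTL coordinate pairs for the tail-fat worked example."""
    return _read("tail_fat_qtl.tsv")


def tail_fat_qtl_records() -> tuple[dict[str, GenomeInterval], list[QTLRecord], dict[str, str]]:
    """The worked example as internal objects.

    Returns (lnc gene spans, distinct QTL records, lnc -> category).
    Coordinates are converted from the table's 1-based inclusive
    convention to the internal 0-based half-open one.
    """
    df = tail_fat_qtl()
    lncs = {
        r["lnc_id"]: GenomeInterval(str(r["chrom"]), int(r["start"]) - 1, int(r["end"]))
        for _, r in df.iterrows()
    }
    qtls = []
    seen = set()
    for _, r in df.iterrows():
        qid = str(r["qtl_id"])
        if qid in seen:
            continue
        seen.add(qid)
        qtls.append(
            QTLRecord(
                qid,
                str(r["trait"]),
                GenomeInterval(str(r["qtl_chrom"]), int(r["qtl_start"]) - 1, int(r["qtl_end"])),
            )
        )
    categories = dict(zip(df["lnc_id"], df["category"]))
    return lncs, qtls, categories


def de_lncrnas() -> pd.DataFrame:
    """The DE lncRNA table (mean FPKM per breed, FDR) for the DE worked example."""
    return _read("de_lncrnas.tsv")
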
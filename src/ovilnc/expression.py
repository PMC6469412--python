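"""Expression matrices, breed-specificity, DE-table consumption and qPCR fold change.

The unit of expression throughout is FPKM.  Differential expression
itself is *consumed* from an upstream (Cuffdiff-style) table — this
module thresholds it at FDR <= 0.1 and assigns direction calls from the
per-breed means; it does not re-fit the count model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """Feature x sample FPKM matrix with a sample -> breed grouping."""

    df: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        missing = [s for s in self.df.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a breed label: {missing}")
        if (self.df.values < 0).any():
            raise ValueError("negative FPKM values")

    @property
    def breeds(self) -> list[str]:
        return sorted(set(self.groups.values()))

    def samples_of(self, breed: str) -> list[str]:
        return [s for s in self.df.columns if self.groups[s] == breed]

    @classmethod
    def from_tsv(cls, matrix_path: str | Path, groups_path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
        g = pd.read_csv(groups_path, sep="\t")
        groups = dict(zip(g.iloc[:, 0].astype(str), g.iloc[:, 1].astype(str)))
        return cls(df, groups)

    def to_tsv(self, matrix_path: str | Path, groups_path: str | Path) -> None:
        self.df.to_csv(matrix_path, sep="\t", index_label="feature_id")
        pd.DataFrame(
            {"sample": list(self.groups), "breed": list(self.groups.values())}
        ).to_csv(groups_path, sep="\t", index=False)

    def gene_level(self, transcript_to_gene: Mapping[str, str]) -> "ExpressionMatrix":
        """Sum member-transcript FPKM into gene-level rows."""
        genes = self.df.groupby(
            self.df.index.map(lambda t: transcript_to_gene.get(t, t))
        ).sum()
        return ExpressionMatrix(genes, dict(self.groups))


def breed_specific(
    feature: str,
    expr: ExpressionMatrix,
    expressed_min_fpkm: float = 1.0,
    silent_max_fpkm: float = 1.0,
) -> Optional[str]:
    """Breed-specificity call for one feature.

    Returns the breed label when the feature is expressed (FPKM >=
    ``expressed_min_fpkm``) in at least two samples of that breed and not
    expressed (FPKM < ``silent_max_fpkm``) in every sample of the other
    breed; ``None`` otherwise.  Mutually exclusive by construction for
    two breeds.
    """
    if feature not in expr.df.index:
        raise KeyError(feature)
    breeds = expr.breeds
    if len(breeds) != 2:
        raise ValueError("breed-specificity needs exactly two breeds")
    row = expr.df.loc[feature]
    for breed in breeds:
        other = breeds[0] if breed == breeds[1] else breeds[1]
        n_expr = int((row[expr.samples_of(breed)] >= expressed_min_fpkm).sum())
        all_silent = bool((row[expr.samples_of(other)] < silent_max_fpkm).all())
        if n_expr >= 2 and all_silent:
            return breed
    return None


@dataclass
class DERecord:
    """A differentially expressed feature with direction relative to breed A."""

    feature_id: str
    mean_a: float
    mean_b: float
    fdr: float
    direction: str  # "up" | "down" relative to breed A
    specific: bool  # zero-vs-nonzero expression pattern


def classify_de(
    table: pd.DataFrame,
    fdr_max: float = 0.1,
    id_col: str = "feature_id",
    mean_a_col: str = "mean_a",
    mean_b_col: str = "mean_b",
    fdr_col: str = "fdr",
) -> list[DERecord]:
    """Threshold a DE table at FDR <= ``fdr_max`` and call directions.

    Direction is "up" iff the breed-A mean exceeds the breed-B mean.
    Rows where one breed's mean is exactly zero and the other's is
    positive are additionally flagged as specifically expressed within
    the DE set.
    """
    out: list[DERecord] = []
    for _, row in table.iterrows():
        fdr = float(row[fdr_col])
        if not 0 <= fdr <= 1:
            raise ValueError(f"FDR outside [0,1]: {fdr}")
        if fdr > fdr_max:
            continue
        a, b = float(row[mean_a_col]), float(row[mean_b_col])
        direction = "up" if a > b else "down"
        specific = (a == 0) != (b == 0)
        out.append(DERecord(str(row[id_col]), a, b, fdr, direction, specific))
    return out


def ddct_fold_change(
    ct: pd.DataFrame,
    baseline: str,
    reference_gene: str,
    sample_col: str = "sample",
    gene_col: str = "gene",
    condition_col: str = "condition",
    ct_col: str = "ct",
) -> pd.DataFrame:
    """Comparative-Ct (2^-ddCt) relative expression per gene and condition.

    ``ct`` holds one row per (sample, gene) with the measured Ct and the
    sample's condition label; ``reference_gene`` is the housekeeping gene
    and must be measured in every sample.  Per sample, dCt = Ct(target) -
    Ct(reference); per condition, ddCt = mean dCt(condition) - mean
    dCt(baseline); the returned table holds 2^-ddCt per (gene,
    condition).
    """
    ref = ct[ct[gene_col] == reference_gene].set_index(sample_col)[ct_col]
    targets = ct[ct[gene_col] != reference_gene]
    missing = set(targets[sample_col]) - set(ref.index)
    if missing:
        raise ValueError(f"reference gene {reference_gene} missing in samples: {sorted(missing)}")
    d = targets.copy()
    d["dct"] = d[ct_col].values - ref.loc[d[sample_col]].values
    mean_dct = d.groupby([gene_col, condition_col])["dct"].mean().unstack(condition_col)
    if baseline not in mean_dct.columns:
        raise ValueError(f"baseline condition {baseline!r} absent")
    ddct = mean_dct.sub(mean_dct[baseline], axis=0)
    return 2.0 ** (-ddct)


def gc_fraction(seq: str) -> float:
    """(G+C) / (A+C+G+T); N and other ambiguity codes excluded."""
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        return float("nan")
    return (counts["G"] + counts["C"]) / total


def feature_stats(
    classes: Mapping[str, Sequence[str]],
    transcripts: Mapping[str, "TranscriptModel"],
    sequences: Optional[Mapping[str, str]] = None,
    expr: Optional[ExpressionMatrix] = None,
) -> pd.DataFrame:
    """Descriptive statistics per transcript class.

    ``classes`` maps a class label (e.g. "novel lincRNA") to transcript
    ids.  Reports mean spliced length, mean exon count, fraction of
    transcripts with <= 2 exons, mean GC fraction (when sequences are
    available) and mean FPKM (when an expression matrix is available).
    """
    rows = []
    for label, tids in classes.items():
        ts = [transcripts[t] for t in tids]
        row: dict[str, float | int | str] = {
            "class": label,
            "n": len(ts),
            "mean_length": float(np.mean([t.spliced_length for t in ts])) if ts else math.nan,
            "mean_exons": float(np.mean([t.exon_count for t in ts])) if ts else math.nan,
            "frac_le_2_exons": float(np.mean([t.exon_count <= 2 for t in ts])) if ts else math.nan,
        }
        if sequences is not None:
            gcs = [gc_fraction(sequences[t]) for t in tids if t in sequences]
            row["mean_gc"] = float(np.mean(gcs)) if gcs else math.nan
        if expr is not None:
            present = [t for t in tids if t in expr.df.index]
            row["mean_fpkm"] = (
                float(expr.df.loc[present].values.mean()) if present else math.nan
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("class")
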
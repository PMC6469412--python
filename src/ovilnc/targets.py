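"""Cis, host-gene and trans (co-expression) target prediction for lncRNA candidates.

Cis targets are the nearest protein-coding genes strictly left and right
of a lincRNA within a 100 kb window; an ilncRNA's target is its host
gene (the coding gene in whose intron it lies); trans targets are genes
anywhere in the genome whose expression profile correlates with the
lncRNA's at |r| > 0.99 and two-sided P < 5e-5 (a relaxed |r| > 0.95 set
feeds the network step).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .genome import (
    GenomeAnnotation,
    PROTEIN_CODING,
    TranscriptModel,
    gene_distance,
)

log = logging.getLogger(__name__)

MODE_CIS_LEFT = "cis_left"
MODE_CIS_RIGHT = "cis_right"
MODE_HOST = "host"
MODE_TRANS = "trans"


@dataclass(frozen=True)
class TargetAssignment:
    """One lncRNA -> gene regulatory hypothesis."""

    lnc_id: str
    gene_id: str
    mode: str
    distance_bp: Optional[int] = None
    r: Optional[float] = None
    p_value: Optional[float] = None


def cis_targets(
    lnc: TranscriptModel, ann: GenomeAnnotation, window: int = 100_000
) -> list[TargetAssignment]:
    """Nearest coding genes strictly left and right of a lincRNA within 100 kb.

    At most one target per side; equidistant genes on one side are all
    reported (tie).  Distances are hull-to-hull gaps.
    """
    span = lnc.span
    spans = ann.coding_spans_sorted().get(span.chrom, [])
    left: list[tuple[int, str]] = []
    right: list[tuple[int, str]] = []
    for s, e, g in spans:
        if e <= span.start:
            d = span.start - e
            if not left or d < left[0][0]:
                left = [(d, g)]
            elif d == left[0][0]:
                left.append((d, g))
        elif s >= span.end:
            d = s - span.end
            if not right or d < right[0][0]:
                right = [(d, g)]
            elif d == right[0][0]:
                right.append((d, g))
    out = []
    for d, g in sorted(left):
        if d <= window:
            out.append(TargetAssignment(lnc.transcript_id, g, MODE_CIS_LEFT, distance_bp=d))
    for d, g in sorted(right):
        if d <= window:
            out.append(TargetAssignment(lnc.transcript_id, g, MODE_CIS_RIGHT, distance_bp=d))
    return out


def host_gene(ilnc: TranscriptModel, ann: GenomeAnnotation) -> TargetAssignment:
    """The coding gene in whose intron an ilncRNA lies entirely."""
    span = ilnc.span
    tree = ann._coding_intron_tree().get(span.chrom)
    hosts = set()
    if tree is not None:
        for iv in tree.overlap(span.start, span.end):
            if iv.begin <= span.start and span.end <= iv.end:
                hosts.add(iv.data)
    if not hosts:
        raise ValueError(
            f"{ilnc.transcript_id}: no containing intron — not a valid ilncRNA"
        )
    return TargetAssignment(ilnc.transcript_id, min(hosts), MODE_HOST, distance_bp=0)


def pearson_p_value(r: float, n: int) -> float:
    """Two-sided p for a Pearson r from the exact t distribution (n-2 df)."""
    if n < 3:
        raise ValueError("need >= 3 samples")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return 2.0 * stats.t.sf(abs(t), df=n - 2)


def trans_targets(
    lnc_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    r_min: float = 0.99,
    p_max: float = 5e-5,
) -> list[TargetAssignment]:
    """All (lncRNA, mRNA) pairs with |r| > ``r_min`` and two-sided p < ``p_max``.

    Both matrices are feature x sample with identical sample columns.
    Zero-variance profiles are skipped (logged).  The correlation is the
    sample Pearson coefficient; p comes from the exact t distribution.
    """
    if list(lnc_expr.columns) != list(mrna_expr.columns):
        raise ValueError("sample columns differ between the two matrices")
    n = lnc_expr.shape[1]
    if n < 3:
        raise ValueError("need >= 3 paired samples")

    def standardize(df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        x = df.values.astype(float)
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        ok = sd[:, 0] > 0
        for f in df.index[~ok]:
            log.warning("trans targets: %s has zero variance; skipped", f)
        z = (x[ok] - mu[ok]) / sd[ok]
        return z, list(df.index[ok])

    zl, lnc_ids = standardize(lnc_expr)
    zm, mrna_ids = standardize(mrna_expr)
    if not lnc_ids or not mrna_ids:
        return []
    r = (zl @ zm.T) / n
    r = np.clip(r, -1.0, 1.0)
    out = []
    ii, jj = np.nonzero(np.abs(r) > r_min)
    for i, j in zip(ii, jj):
        rv = float(r[i, j])
        p = pearson_p_value(rv, n)
        if p < p_max:
            out.append(
                TargetAssignment(lnc_ids[i], mrna_ids[j], MODE_TRANS, r=rv, p_value=p)
            )
    out.sort(key=lambda a: (a.lnc_id, a.gene_id))
    return out


def targets_table(assignments: list[TargetAssignment]) -> pd.DataFrame:
    """Flatten assignments to a writable table."""
    return pd.DataFrame(
        [
            {
                "lnc_id": a.lnc_id,
                "gene_id": a.gene_id,
                "mode": a.mode,
                "distance_bp": a.distance_bp,
                "r": a.r,
                "p_value": a.p_value,
            }
            for a in assignments
        ],
        columns=["lnc_id", "gene_id", "mode", "distance_bp", "r", "p_value"],
    )
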
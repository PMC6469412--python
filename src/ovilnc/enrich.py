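"""Local over-representation analysis (ORA) against GMT gene-set collections.

Replaces a web enrichment service with the standard hypergeometric
upper-tail test per set and Benjamini-Hochberg adjustment across sets;
terms with FDR < 0.05 are called significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"{self.set_id}: empty gene set")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file (set id, description, members...)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: GMT line with < 3 fields: {fields[0]!r}")
            out.append(GeneSet(fields[0], fields[1], frozenset(filter(None, fields[2:]))))
    return out


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    if len(pvalues) == 0:
        return []
    for p in pvalues:
        if not 0 <= p <= 1:
            raise ValueError(f"p-value outside [0,1]: {p}")
    return list(multipletests(pvalues, method="fdr_bh")[1])


def ora(
    query: Iterable[str],
    sets: Sequence[GeneSet],
    background: Iterable[str],
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query set against each gene set.

    With population size ``|background|``, ``K = |set & background|``
    successes and ``n = |query|`` draws, p = P(X >= k) for the observed
    overlap ``k``.  The query must be a subset of the background; sets
    are intersected with the background.  FDR is BH-adjusted across all
    tested sets; ``significant`` marks FDR < ``fdr_max``.
    """
    query = set(query)
    background = set(background)
    if not query:
        raise ValueError("empty query")
    stray = query - background
    if stray:
        raise ValueError(f"query genes absent from background: {sorted(stray)[:5]}")
    M, n = len(background), len(query)
    rows = []
    for gs in sets:
        members = gs.members & background
        if not members:
            continue
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, M, len(members), n))
        rows.append(
            {"set_id": gs.set_id, "name": gs.name, "set_size": len(members),
             "overlap": k, "p_value": min(p, 1.0)}
        )
    df = pd.DataFrame(rows, columns=["set_id", "name", "set_size", "overlap", "p_value"])
    if len(df):
        df["fdr"] = bh_fdr(df["p_value"].tolist())
        df["significant"] = df["fdr"] < fdr_max
        df = df.sort_values(["fdr", "p_value", "set_id"]).reset_index(drop=True)
    else:
        df["fdr"] = []
        df["significant"] = []
    return df
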
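"""Genome-weighted COG functional profiles of screen hits.

Each gene carries at most one COG category letter (the highest-scoring
assignment). For a screen's hit list, the profile reports, per
category, the number of hits and the percentage of the genome's genes
in that category that were hit — weighting by category size so a large
category does not dominate simply by being large. Hits without an
assignment are kept in an explicit ``unassigned`` bucket.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

# one-letter functional categories of the COG system
COG_CATEGORIES = set("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
UNASSIGNED = "unassigned"


@dataclass
class CogTable:
    assignments: dict[str, str]  # gene -> single category letter
    genome_totals: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {c for c in self.assignments.values() if c not in COG_CATEGORIES}
        if bad:
            raise ValueError(f"unknown COG categories: {sorted(bad)}")
        totals: dict[str, int] = {}
        for cat in self.assignments.values():
            totals[cat] = totals.get(cat, 0) + 1
        self.genome_totals = totals


def load_cog_table(path: str | Path) -> CogTable:
    """TSV with columns gene, category (one letter). Duplicate gene rows
    with conflicting categories are an error; consistent duplicates
    collapse."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        return CogTable(assignments={})
    if not {"gene", "category"}.issubset(df.columns):
        raise ValueError("COG table needs columns 'gene' and 'category'")
    assignments: dict[str, str] = {}
    for gene, cat in df[["gene", "category"]].itertuples(index=False):
        if gene in assignments and assignments[gene] != cat:
            raise ValueError(f"conflicting COG categories for gene {gene!r}")
        assignments[gene] = cat
    return CogTable(assignments=assignments)


def write_cog_table(table: CogTable, path: str | Path) -> None:
    pd.DataFrame(
        sorted(table.assignments.items()), columns=["gene", "category"]
    ).to_csv(path, sep="\t", index=False)


def profile_hits(
    hit_lists: Mapping[str, Iterable[str]], cog: CogTable, include_union: bool = True
) -> pd.DataFrame:
    """Weighted COG profile per screen (plus a union-of-screens row set).

    Returns rows (screen, category, hits, genome_total, weighted_pct)
    with weighted_pct = 100 * hits / genome_total. Categories with no
    genome members are omitted; hits without an assignment appear under
    ``unassigned`` with an undefined (NaN) percentage.
    """
    screens = {name: set(genes) for name, genes in hit_lists.items()}
    if include_union and screens:
        screens["union"] = set().union(*screens.values())

    rows = []
    for screen, genes in screens.items():
        per_cat: dict[str, int] = {}
        for g in genes:
            cat = cog.assignments.get(g, UNASSIGNED)
            per_cat[cat] = per_cat.get(cat, 0) + 1
        for cat in sorted(cog.genome_totals) + [UNASSIGNED]:
            hits = per_cat.get(cat, 0)
            if cat == UNASSIGNED:
                if hits == 0:
                    continue
                total, pct = 0, float("nan")
            else:
                total = cog.genome_totals[cat]
                pct = 100.0 * hits / total
            rows.append(
                {
                    "screen": screen,
                    "category": cat,
                    "hits": hits,
                    "genome_total": total,
                    "weighted_pct": pct,
                }
            )
    return pd.DataFrame(rows, columns=["screen", "category", "hits", "genome_total", "weighted_pct"])
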
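"""Hit-selection filters for CRISPR-screen gene-summary tables.

These operate on MAGeCK-style per-gene summaries (robust rank aggregation
scores, log2 fold changes, and the count of concordant gRNAs) — the RRA
scoring itself is upstream and out of scope here.  Conventions: a smaller
RRA score is stronger; positive scores rank enrichment, negative scores
depletion.

Filters (thresholds literal):
- overrepresented genes: union of the top-250 positive-score genes per
  comparison, deduplicated;
- essentialome: genes depleted in every population, RRA < 0.05 and
  log2FC < -0.75;
- pairwise hits: RRA < 0.05, |log2FC| > 0.8 and goodsgrna >= 3.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import pandas as pd

#: genome-wide mouse knockout gRNA library used for the screen
#: (Yusa lab improved v2, Addgene #67988)
LIBRARY_GRNAS = 90_230
LIBRARY_GENES = 18_424

RRA_THRESHOLD = 0.05
HIT_LFC_THRESHOLD = 0.8
ESSENTIAL_LFC_THRESHOLD = -0.75
MIN_GOODSGRNA = 3
TOP_N = 250


def grnas_per_gene() -> float:
    """Average gRNAs per gene in the screening library."""
    return LIBRARY_GRNAS / LIBRARY_GENES


#: MAGeCK gene_summary column names mapped onto the normalized schema
_MAGECK_COLUMNS = {
    "id": "gene",
    "pos|score": "rra_score_pos",
    "neg|score": "rra_score_neg",
    "neg|lfc": "log2FC",
}


def read_gene_summary(
    path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a gene-summary TSV, normalizing MAGeCK column names.

    ``column_map`` overrides or extends the default mapping (original
    column -> normalized name).  goodsgrna defaults to the direction-less
    maximum of pos|goodsgrna and neg|goodsgrna when both exist.
    """
    df = pd.read_csv(path, sep="\t")
    mapping = dict(_MAGECK_COLUMNS)
    if column_map:
        mapping.update(column_map)
    df = df.rename(columns={k: v for k, v in mapping.items() if k in df.columns})
    if "goodsgrna" not in df.columns:
        pos = "pos|goodsgrna" in df.columns
        neg = "neg|goodsgrna" in df.columns
        if pos and neg:
            df["goodsgrna"] = df[["pos|goodsgrna", "neg|goodsgrna"]].max(axis=1)
        elif pos:
            df["goodsgrna"] = df["pos|goodsgrna"]
        elif neg:
            df["goodsgrna"] = df["neg|goodsgrna"]
    return df


def _score_column(table: pd.DataFrame, direction: str) -> str:
    """Pick the RRA column for a direction, falling back to a single score."""
    preferred = "rra_score_pos" if direction == "enriched" else "rra_score_neg"
    if preferred in table.columns:
        return preferred
    for fallback in ("rra_score", "score"):
        if fallback in table.columns:
            return fallback
    raise ValueError(
        f"no RRA score column for direction {direction!r}; "
        f"have {list(table.columns)}"
    )


def top_overrepresented(
    tables: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame],
    n: int = TOP_N,
) -> list[str]:
    """Unique union of each comparison's ``n`` strongest positive-score genes.

    Genes are ranked by ascending positive RRA score (smaller = stronger);
    ties at the cutoff break deterministically by gene name.  Tables
    shorter than ``n`` contribute all their genes with a warning.
    """
    if isinstance(tables, Mapping):
        items = list(tables.items())
    else:
        items = [(str(i), t) for i, t in enumerate(tables)]
    if not items:
        raise ValueError("at least one comparison table required")
    selected: set[str] = set()
    for name, table in items:
        col = _score_column(table, "enriched")
        ranked = table.sort_values([col, "gene"], kind="mergesort")
        if len(ranked) < n:
            warnings.warn(
                f"comparison {name!r} has only {len(ranked)} genes (< {n}); "
                "taking all",
                stacklevel=2,
            )
        selected.update(ranked["gene"].head(n))
    return sorted(selected)


def essential_filter(
    tables: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame],
    rra_threshold: float = RRA_THRESHOLD,
    lfc_threshold: float = ESSENTIAL_LFC_THRESHOLD,
) -> list[str]:
    """Genes depleted in every population: RRA < 0.05 and log2FC < -0.75.

    Both inequalities are strict; the result is the intersection over all
    provided population tables, sorted by gene name.
    """
    items = list(tables.values()) if isinstance(tables, Mapping) else list(tables)
    if not items:
        raise ValueError("at least one population table required")
    common: set[str] | None = None
    for table in items:
        col = _score_column(table, "depleted")
        passing = set(
            table.loc[
                (table[col] < rra_threshold) & (table["log2FC"] < lfc_threshold),
                "gene",
            ]
        )
        common = passing if common is None else common & passing
    return sorted(common or set())


def hit_filter(
    table: pd.DataFrame,
    direction: str,
    rra_threshold: float = RRA_THRESHOLD,
    lfc_threshold: float = HIT_LFC_THRESHOLD,
    min_goodsgrna: int = MIN_GOODSGRNA,
) -> list[str]:
    """Pairwise-comparison hits for one direction.

    enriched: RRA < 0.05 and log2FC > 0.8; depleted: RRA < 0.05 and
    log2FC < -0.8; both require goodsgrna >= 3 (inclusive).
    """
    if direction not in ("enriched", "depleted"):
        raise ValueError("direction must be 'enriched' or 'depleted'")
    col = _score_column(table, direction)
    if direction == "enriched":
        lfc_ok = table["log2FC"] > lfc_threshold
    else:
        lfc_ok = table["log2FC"] < -lfc_threshold
    mask = (
        (table[col] < rra_threshold)
        & lfc_ok
        & (table["goodsgrna"] >= min_goodsgrna)
    )
    return sorted(table.loc[mask, "gene"])


def hit_audit(
    table: pd.DataFrame,
    direction: str,
    rra_threshold: float = RRA_THRESHOLD,
    lfc_threshold: float = HIT_LFC_THRESHOLD,
    min_goodsgrna: int = MIN_GOODSGRNA,
) -> pd.DataFrame:
    """Per-gene pass/fail audit for each hit-filter criterion."""
    col = _score_column(table, direction)
    out = table[["gene"]].copy()
    out["rra_pass"] = table[col] < rra_threshold
    if direction == "enriched":
        out["lfc_pass"] = table["log2FC"] > lfc_threshold
    else:
        out["lfc_pass"] = table["log2FC"] < -lfc_threshold
    out["goodsgrna_pass"] = table["goodsgrna"] >= min_goodsgrna
    out["hit"] = out["rra_pass"] & out["lfc_pass"] & out["goodsgrna_pass"]
    return out
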
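"""Allele-specific expression ratios, gene classification, and scores.

In the hybrid cell line the two X chromosomes are distinguishable by
strain SNPs: the mus X carries the silenced (and reactivating) reporter,
the cas X stays active.  The allelic ratio X_mus / (X_mus + X_cas) is
near 0 for silenced genes in NPCs and rises as the mus X reactivates.
Genes are usable ("informative") only when the cas allele carries more
than 25% of the gene's expression in every population; informative genes
with an NPC ratio at or under 0.135 are classed X-reactivating, above it
escapee.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

#: core pluripotency-network genes averaged into the pluripotency score
PLURIPOTENCY_GENES = (
    "Nanog", "Zfp42", "Dppa4", "Dppa5a", "Esrrb", "Prdm14", "Sall4",
)

NPC_RATIO_THRESHOLD = 0.135     # allelic ratio at/below -> X-reactivating
MIN_CAS_FRACTION = 0.25         # strict: cas share must exceed this


def allelic_ratio(count_mus, count_cas):
    """mus / (mus + cas); NaN when both counts are zero.

    Accepts scalars or array-likes; negative counts are rejected.
    """
    mus = np.asarray(count_mus, dtype=float)
    cas = np.asarray(count_cas, dtype=float)
    if (mus < 0).any() or (cas < 0).any():
        raise ValueError("allele counts must be non-negative")
    total = mus + cas
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, mus / np.where(total > 0, total, 1.0), np.nan)
    if ratio.ndim == 0:
        return float(ratio)
    return ratio


def ratio_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Add an ``allelic_ratio`` column to a (gene, population) count table."""
    out = counts.copy()
    out["allelic_ratio"] = allelic_ratio(
        out["count_mus"].to_numpy(), out["count_cas"].to_numpy()
    )
    return out


def select_informative(
    counts: pd.DataFrame, min_cas_fraction: float = MIN_CAS_FRACTION
) -> list[str]:
    """Genes whose cas allele exceeds ``min_cas_fraction`` of the gene's
    expression in every population (strict inequality); genes with a
    zero-total population are dropped."""
    keep: list[str] = []
    for gene, sub in counts.groupby("gene", sort=True):
        total = sub["count_mus"] + sub["count_cas"]
        if (total == 0).any():
            continue
        cas_frac = sub["count_cas"] / total
        if (cas_frac > min_cas_fraction).all():
            keep.append(gene)
    return keep


def classify_genes(
    counts: pd.DataFrame,
    npc_population: str = "NPC",
    threshold: float = NPC_RATIO_THRESHOLD,
    min_cas_fraction: float = MIN_CAS_FRACTION,
) -> pd.Series:
    """reactivating / escapee / uninformative per gene.

    Informative genes (see :func:`select_informative`) are classed by
    their NPC allelic ratio: at or under ``threshold`` -> reactivating,
    above -> escapee.  All other genes are uninformative.
    """
    if npc_population not in set(counts["population"]):
        raise ValueError(f"population {npc_population!r} absent from the table")
    informative = set(select_informative(counts, min_cas_fraction))
    npc = counts[counts["population"] == npc_population].set_index("gene")
    result = {}
    for gene in sorted(counts["gene"].unique()):
        if gene not in informative or gene not in npc.index:
            result[gene] = "uninformative"
            continue
        row = npc.loc[gene]
        ratio = allelic_ratio(row["count_mus"], row["count_cas"])
        if np.isnan(ratio):
            result[gene] = "uninformative"
        elif ratio <= threshold:
            result[gene] = "reactivating"
        else:
            result[gene] = "escapee"
    return pd.Series(result, name="classification")


def pluripotency_score(
    expr: pd.DataFrame,
    esc_population: str = "ESC",
    genes: Sequence[str] = PLURIPOTENCY_GENES,
) -> pd.Series:
    """Per-sample mean of the seven pluripotency-gene ratios to ESCs.

    The ESC reference per gene is the mean expression over all ESC rows;
    each sample's score is the arithmetic mean over genes of
    expression / ESC reference.  Scores are reported per sample
    (i.e. per replicate), including the ESC samples themselves.
    """
    esc = expr[expr["population"] == esc_population]
    if esc.empty:
        raise ValueError(f"no rows for ESC reference population {esc_population!r}")
    ref = esc.groupby("gene")["expression"].mean()
    missing = [g for g in genes if g not in ref.index]
    if missing:
        raise ValueError(f"genes missing from ESC reference: {missing}")
    zero = [g for g in genes if ref[g] <= 0]
    if zero:
        raise ValueError(f"ESC reference expression is zero for: {zero}")
    scores = {}
    for sample, sub in expr.groupby("sample"):
        by_gene = sub.set_index("gene")["expression"]
        missing = [g for g in genes if g not in by_gene.index]
        if missing:
            raise ValueError(f"sample {sample!r} missing genes: {missing}")
        scores[sample] = float(np.mean([by_gene[g] / ref[g] for g in genes]))
    return pd.Series(scores, name="pluripotency_score")


def qpcr_expression(ct_gene, ct_gapdh_mean):
    """Relative expression 2^-(CT_gene - mean CT_Gapdh)."""
    ct_gene = np.asarray(ct_gene, dtype=float)
    value = 2.0 ** (-(ct_gene - ct_gapdh_mean))
    if value.ndim == 0:
        return float(value)
    return value
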
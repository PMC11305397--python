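"""Allele-specific targeted-amplicon (oxidative) bisulfite analysis.

The chain implemented here mirrors the ASTA-Seq read-classification logic:

1. assign each read to a gene by finding its PCR2 primer near the read
   start (after the 2-5 random stagger bases);
2. assign the read to the mus or cas haplotype from the base immediately
   3' of a 15-20 nt BS-converted anchor ending at the SNP;
3. call CG vs TG at each CpG from the 2-mer immediately 3' of a 15-20 nt
   BS-converted anchor ending at the CpG cytosine;
4. compute %CG per (gene, condition, chemistry, allele, CpG);
5. deconvolve: %5mC = %CG(OxBS), %5hmC = %CG(BS) - %CG(OxBS);
6. apply the negative-5hmC rules: any allele/condition cell with raw 5hmC
   below -1% discards the whole CpG; raw values in (-1, 0) clamp to 0.

Only the bisulfite-converted top strand is analysed, matching the
single-end read geometry of the assay.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .panel import (
    ALLELES,
    CHEMISTRIES,
    AmpliconSpec,
    PanelConfigError,
    bs_base,
    bs_convert,
)

log = logging.getLogger(__name__)

ANCHOR_MIN = 15
ANCHOR_MAX = 20

#: cells with fewer informative (CG+TG) reads than this are flagged
DEFAULT_MIN_COVERAGE = 100

#: raw 5hmC below this (percent) discards the whole CpG; values between
#: this and zero are clamped to zero
HMC_DISCARD_BELOW = -1.0

_C2T = str.maketrans("C", "T")


@dataclass(frozen=True)
class BsReference:
    """BS-space reference and anchors for one amplicon.

    ``bs_seq`` keeps CpG cytosines as the ambiguity mark ``Y`` (they read
    C or T depending on methylation); anchors are concrete 15-20 nt
    strings chosen to contain no CpG cytosine, ending immediately 5' of
    the SNP or CpG they tag.
    """

    spec: AmpliconSpec
    bs_seq: dict[str, str]                    # allele -> marked BS sequence
    snp_anchor: dict[str, str]                # allele -> anchor string
    snp_read_base: dict[str, str]             # allele -> BS-space SNP base
    cpg_anchor: dict[str, dict[int, str]]     # allele -> {cpg_offset: anchor}

    @property
    def gene(self) -> str:
        return self.spec.gene_name

    @property
    def primer(self) -> str:
        return self.spec.primer

    @property
    def cpg_offsets(self) -> tuple[int, ...]:
        return self.spec.cpg_offsets


def _pattern_matches(seq: str, pattern: str, start: int) -> bool:
    for j, p in enumerate(pattern):
        s = seq[start + j]
        if s == p:
            continue
        if s == "Y" and p in "CT":
            continue
        return False
    return True


def _count_occurrences(seq: str, pattern: str) -> int:
    n = 0
    for start in range(len(seq) - len(pattern) + 1):
        if _pattern_matches(seq, pattern, start):
            n += 1
    return n


def _pick_anchor(bs_seq: str, pos: int, gene: str, what: str) -> str:
    """Shortest anchor in [15, 20] nt ending at ``pos`` that avoids CpG
    cytosines and occurs exactly once in the reference."""
    if pos < ANCHOR_MIN:
        raise PanelConfigError(
            f"{gene}: {what} at offset {pos} too close to the read start for "
            f"a {ANCHOR_MIN} nt anchor"
        )
    for length in range(ANCHOR_MIN, ANCHOR_MAX + 1):
        if pos - length < 0:
            break
        window = bs_seq[pos - length : pos]
        if "Y" in window:
            raise PanelConfigError(
                f"{gene}: anchor window for {what} at offset {pos} would "
                "include a CpG cytosine"
            )
        if _count_occurrences(bs_seq, window) == 1:
            return window
    raise PanelConfigError(
        f"{gene}: no unique CpG-free anchor of length <= {ANCHOR_MAX} for "
        f"{what} at offset {pos}"
    )


def bs_convert_reference(spec: AmpliconSpec) -> BsReference:
    """In-silico BS conversion of both haplotypes plus anchor extraction."""
    bs_seq = {a: bs_convert(spec.seq(a), spec.cpg_offsets) for a in ALLELES}
    snp_read_base = {
        "mus": bs_base(spec.snp_base_mus),
        "cas": bs_base(spec.snp_base_cas),
    }
    if snp_read_base["mus"] == snp_read_base["cas"]:
        raise PanelConfigError(
            f"{spec.gene_name}: SNP indistinguishable after BS conversion"
        )
    snp_anchor = {
        a: _pick_anchor(bs_seq[a], spec.snp_offset, spec.gene_name, "SNP")
        for a in ALLELES
    }
    cpg_anchor = {
        a: {
            cpg: _pick_anchor(bs_seq[a], cpg, spec.gene_name, f"CpG {cpg}")
            for cpg in spec.cpg_offsets
        }
        for a in ALLELES
    }
    return BsReference(
        spec=spec,
        bs_seq=bs_seq,
        snp_anchor=snp_anchor,
        snp_read_base=snp_read_base,
        cpg_anchor=cpg_anchor,
    )


def build_references(panel: Sequence[AmpliconSpec]) -> list[BsReference]:
    return [bs_convert_reference(s) for s in panel]


# ---------------------------------------------------------------------------
# per-read classification
# ---------------------------------------------------------------------------

def assign_gene(read: str, refs: Sequence[BsReference]) -> str | None:
    """Gene of the unique primer found in the read's scan window, else None.

    The scan window is the first stagger_max + len(primer) bases; the
    comparison collapses C onto T because primers sit in BS space.  Reads
    matching two or more genes are left unassigned.
    """
    if not read:
        return None
    hit: str | None = None
    for ref in refs:
        smax = ref.spec.stagger_range[1]
        window = read[: smax + len(ref.primer)].translate(_C2T)
        if window.find(ref.primer) != -1:
            if hit is not None:
                return None
            hit = ref.gene
    return hit


def _find_unique(read: str, pattern: str, max_mismatch: int = 0) -> int | None:
    """Start of the unique occurrence of ``pattern`` in ``read``, or None.

    With max_mismatch=0 this is plain substring search; otherwise a scan
    tolerating up to that many mismatches.  Duplicate hits return None —
    the read cannot be anchored unambiguously.
    """
    if max_mismatch == 0:
        i = read.find(pattern)
        if i == -1 or read.find(pattern, i + 1) != -1:
            return None
        return i
    hits = []
    for start in range(len(read) - len(pattern) + 1):
        mism = 0
        for j, p in enumerate(pattern):
            if read[start + j] != p:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            hits.append(start)
            if len(hits) > 1:
                return None
    return hits[0] if len(hits) == 1 else None


def assign_allele(read: str, ref: BsReference, max_mismatch: int = 0) -> str:
    """mus, cas or ambiguous, from the base 3' of the SNP anchor."""
    candidates: set[str] = set()
    seen_anchors: set[str] = set()
    for allele in ALLELES:
        anchor = ref.snp_anchor[allele]
        if anchor in seen_anchors:
            continue
        seen_anchors.add(anchor)
        i = _find_unique(read, anchor, max_mismatch)
        if i is None:
            continue
        pos = i + len(anchor)
        if pos >= len(read):
            continue
        base = read[pos]
        for al in ALLELES:
            if base == ref.snp_read_base[al]:
                candidates.add(al)
    if len(candidates) == 1:
        return candidates.pop()
    return "ambiguous"


def call_cpg(
    read: str, ref: BsReference, cpg_offset: int, allele: str = "mus",
    max_mismatch: int = 0,
) -> str:
    """CG, TG or other for one CpG, read 3' of its upstream anchor."""
    anchor = ref.cpg_anchor[allele][cpg_offset]
    i = _find_unique(read, anchor, max_mismatch)
    if i is None:
        return "other"
    two = read[i + len(anchor) : i + len(anchor) + 2]
    if two in ("CG", "TG"):
        return two
    return "other"


# ---------------------------------------------------------------------------
# tallying
# ---------------------------------------------------------------------------

_CALL_INDEX = {"CG": 0, "TG": 1, "other": 2}


@dataclass
class CpGTally:
    """CG/TG/other counts per (gene, condition, chemistry, allele, CpG),
    with per-run and per-gene read accounting."""

    counts: dict[tuple, list[int]] = field(
        default_factory=lambda: defaultdict(lambda: [0, 0, 0])
    )
    n_total: int = 0
    n_unassigned: int = 0
    per_gene: dict[str, dict[str, int]] = field(
        default_factory=lambda: defaultdict(
            lambda: {"assigned": 0, "mus": 0, "cas": 0, "ambiguous": 0}
        )
    )

    def check_conservation(self) -> None:
        assigned = sum(g["assigned"] for g in self.per_gene.values())
        if assigned + self.n_unassigned != self.n_total:
            raise AssertionError("read accounting violated at gene level")
        for gene, g in self.per_gene.items():
            if g["mus"] + g["cas"] + g["ambiguous"] != g["assigned"]:
                raise AssertionError(f"read accounting violated for {gene}")

    def cell(self, gene, condition, chemistry, allele, cpg_offset) -> tuple[int, int, int]:
        n = self.counts.get((gene, condition, chemistry, allele, cpg_offset))
        return tuple(n) if n else (0, 0, 0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                gene=k[0], condition=k[1], chemistry=k[2], allele=k[3],
                cpg_offset=k[4], n_CG=v[0], n_TG=v[1], n_other=v[2],
            )
            for k, v in sorted(self.counts.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["gene", "condition", "chemistry", "allele", "cpg_offset",
                     "n_CG", "n_TG", "n_other"],
        )


def _normalize_samples(samples) -> list[tuple[str, str, str]]:
    if isinstance(samples, pd.DataFrame):
        required = {"fastq", "condition", "chemistry"}
        if not required <= set(samples.columns):
            raise ValueError(f"sample sheet needs columns {sorted(required)}")
        items = list(samples[["fastq", "condition", "chemistry"]].itertuples(index=False))
    else:
        items = [tuple(s) for s in samples]
    for fastq, condition, chemistry in items:
        if chemistry not in CHEMISTRIES:
            raise ValueError(
                f"unknown chemistry label {chemistry!r} for {fastq} "
                f"(expected one of {CHEMISTRIES})"
            )
    return items


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def tally(
    samples,
    refs: Sequence[BsReference],
    max_mismatch: int = 0,
) -> CpGTally:
    """Stream FASTQ files once and tally CG/TG calls per analysis cell.

    ``samples`` is an iterable of (fastq_path, condition, chemistry) or a
    DataFrame with those columns.  A read contributes to CpG counts only
    when its SNP is recoverable (allele assigned) and at least one CpG
    call is CG or TG; gene/allele accounting covers every read.
    """
    items = _normalize_samples(samples)
    t = CpGTally()
    ref_by_gene = {r.gene: r for r in refs}
    for fastq, condition, chemistry in items:
        with open(fastq) as fh:
            for _title, seq, _qual in FastqGeneralIterator(fh):
                t.n_total += 1
                gene = assign_gene(seq, refs)
                if gene is None:
                    t.n_unassigned += 1
                    continue
                acct = t.per_gene[gene]
                acct["assigned"] += 1
                ref = ref_by_gene[gene]
                allele = assign_allele(seq, ref, max_mismatch)
                acct[allele if allele != "ambiguous" else "ambiguous"] += 1
                if allele == "ambiguous":
                    continue
                calls = [
                    (cpg, call_cpg(seq, ref, cpg, allele, max_mismatch))
                    for cpg in ref.cpg_offsets
                ]
                if not any(c in ("CG", "TG") for _, c in calls):
                    continue  # needs SNP plus at least one CpG in the read
                for cpg, c in calls:
                    t.counts[(gene, condition, chemistry, allele, cpg)][
                        _CALL_INDEX[c]
                    ] += 1
    t.check_conservation()
    log.info(
        "tally: %d reads, %d unassigned (%.2f%%)",
        t.n_total, t.n_unassigned,
        100.0 * t.n_unassigned / t.n_total if t.n_total else 0.0,
    )
    return t


# ---------------------------------------------------------------------------
# estimates
# ---------------------------------------------------------------------------

def percent_cg(n_cg: int, n_tg: int) -> float:
    """100 * n_CG / (n_CG + n_TG); NaN when the denominator is zero.

    'other' calls are excluded from the denominator by construction.
    """
    denom = n_cg + n_tg
    if denom == 0:
        return math.nan
    return 100.0 * n_cg / denom


def deconvolve(pct_cg_bs: float, pct_cg_oxbs: float):
    """(%5mC, raw %5hmC) from the two chemistries.

    %5mC is the OxBS %CG directly; raw %5hmC is the BS-minus-OxBS
    difference and may be negative at this stage.
    """
    pct_cg_bs = np.asarray(pct_cg_bs, dtype=float)
    pct_cg_oxbs = np.asarray(pct_cg_oxbs, dtype=float)
    pct_5mc = pct_cg_oxbs
    pct_5hmc_raw = pct_cg_bs - pct_cg_oxbs
    if pct_5mc.ndim == 0:
        return float(pct_5mc), float(pct_5hmc_raw)
    return pct_5mc, pct_5hmc_raw


def build_estimates(
    t: CpGTally, min_coverage: int = DEFAULT_MIN_COVERAGE
) -> pd.DataFrame:
    """Per-cell %CG for both chemistries plus the 5mC/5hmC deconvolution.

    One row per (gene, condition, allele, cpg_offset).  Cells with a zero
    CG+TG denominator get NaN percentages (flagged, not zero);
    ``low_coverage`` marks cells under ``min_coverage`` informative reads
    in either chemistry.
    """
    cells = sorted({(k[0], k[1], k[3], k[4]) for k in t.counts})
    rows = []
    for gene, condition, allele, cpg in cells:
        n_bs = t.cell(gene, condition, "BS", allele, cpg)
        n_ox = t.cell(gene, condition, "OxBS", allele, cpg)
        pct_bs = percent_cg(n_bs[0], n_bs[1])
        pct_ox = percent_cg(n_ox[0], n_ox[1])
        cov_bs = n_bs[0] + n_bs[1]
        cov_ox = n_ox[0] + n_ox[1]
        pct_5mc, raw = deconvolve(pct_bs, pct_ox)
        rows.append(
            dict(
                gene=gene, condition=condition, allele=allele, cpg_offset=cpg,
                pct_CG_BS=pct_bs, pct_CG_OxBS=pct_ox,
                coverage_BS=cov_bs, coverage_OxBS=cov_ox,
                pct_5mC=pct_5mc, pct_5hmC_raw=raw,
                low_coverage=bool(min(cov_bs, cov_ox) < min_coverage),
            )
        )
    return pd.DataFrame(rows)


def apply_5hmc_filters(
    estimates: pd.DataFrame, discard_below: float = HMC_DISCARD_BELOW
) -> pd.DataFrame:
    """Negative-5hmC handling, applied per CpG across all of its cells.

    If any allele/condition cell of a CpG has raw 5hmC below
    ``discard_below`` (percent), every cell of that CpG is discarded.
    Otherwise raw values in (discard_below, 0) are clamped to 0; raw
    values >= 0 are kept unchanged.  CpGs missing any expected cell (or
    with NaN raw values) are marked missing.  Idempotent and independent
    of row order.
    """
    out = estimates.copy()
    out["pct_5hmC"] = out["pct_5hmC_raw"].astype(float)
    out["status"] = "kept"
    expected = {
        (a, c)
        for a in out["allele"].unique()
        for c in out["condition"].unique()
    }
    for (_gene, _cpg), idx in out.groupby(["gene", "cpg_offset"]).groups.items():
        sub = out.loc[idx]
        present = set(zip(sub["allele"], sub["condition"]))
        raws = sub["pct_5hmC_raw"]
        if present != expected or raws.isna().any():
            out.loc[idx, "status"] = "missing"
            out.loc[idx, "pct_5hmC"] = np.nan
            continue
        if (raws < discard_below).any():
            out.loc[idx, "status"] = "discarded"
            continue
        clamp = raws.index[(raws < 0.0)]
        out.loc[clamp, "pct_5hmC"] = 0.0
        out.loc[clamp, "status"] = "clamped"
    return out


def run_pipeline(
    panel: Sequence[AmpliconSpec],
    samples,
    max_mismatch: int = 0,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> tuple[CpGTally, pd.DataFrame]:
    """Convenience wrapper: references -> tally -> filtered estimates."""
    refs = build_references(panel)
    t = tally(samples, refs, max_mismatch=max_mismatch)
    estimates = apply_5hmc_filters(build_estimates(t, min_coverage=min_coverage))
    return t, estimates
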
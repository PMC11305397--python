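"""Synthetic-data generators for every pipeline stage.

This module fabricates inputs with the statistical structure the analyses
assume: staggered single-end amplicon reads after BS or OxBS treatment,
allele-resolved expression count tables, paired BS/OxBS array beta-value
matrices, and CRISPR-screen gene-summary tables.  Every generator is
deterministic given its seed, and every generator returns the ground truth
alongside the data so recovery can be asserted.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import (
    ALLELES,
    READ_LENGTH,
    AmpliconSpec,
    ChemistryModel,
    MethylTruth,
    PanelConfigError,
    SimManifest,
    bs_convert,
)

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_C, _T = ord("C"), ord("T")

#: default panel genes: four X-reactivating promoters and two escapee
#: promoter controls; CpG counts give nine reactivating CpGs in total.
DEFAULT_PANEL_GENES: tuple[tuple[str, int, bool], ...] = (
    ("Mtm1", 3, False),
    ("Dlg3", 2, False),
    ("Eda", 2, False),
    ("Zfp185", 2, False),
    ("Ddx3x", 2, True),
    ("Eif2s3x", 2, True),
)

_PRIMER_LEN = 10
_SNP_OFFSET = 30
_FIRST_CPG = 70
_CPG_SPACING = 30


def _random_seq_no_cpg(rng: np.random.Generator, length: int) -> list[str]:
    """Random DNA with no CpG dinucleotide (never G after C)."""
    seq: list[str] = []
    prev = ""
    for _ in range(length):
        choices = "ACT" if prev == "C" else "ACGT"
        b = choices[rng.integers(len(choices))]
        seq.append(b)
        prev = b
    return seq


def _primers_collide(primer_a: str, window_b: str, smax: int) -> bool:
    """Could primer_a match inside a read of the amplicon whose BS-space
    scan window is ``window_b``?

    Covers occurrences fully inside the window and occurrences whose first
    bases fall in the random stagger (any stagger content is possible, so
    a suffix of the primer equal to a window prefix already collides).
    """
    if primer_a in window_b:
        return True
    for k in range(1, smax + 1):
        if primer_a[k:] == window_b[: len(primer_a) - k]:
            return True
    return False


def make_default_panel(seed: int) -> tuple[list[AmpliconSpec], MethylTruth]:
    """Build the six-gene default panel and its methylation ground truth.

    Sequences are synthetic but follow the assay geometry: one A/G SNP
    early in the amplicon, CpGs spaced widely enough for clean upstream
    anchors, and a CpG-free primer prefix.  Reactivating-gene promoters get
    substantial 5mC (higher on the inactive mus allele) plus some 5hmC;
    escapee promoters (Ddx3x, Eif2s3x) get near-zero levels of both marks.
    """
    rng = np.random.default_rng(seed)
    specs: list[AmpliconSpec] = []
    truth_rows: list[dict] = []
    primers: list[str] = []
    windows: list[str] = []  # BS-space scan window (stagger_max + primer len)
    smax = 5
    win_len = smax + _PRIMER_LEN
    for gi, (gene, n_cpg, escapee) in enumerate(DEFAULT_PANEL_GENES):
        length = int(rng.integers(240, 281))
        while True:
            seq = _random_seq_no_cpg(rng, length)
            seq[_SNP_OFFSET - 1] = "T"  # keep the cas G from creating a CpG
            seq[_SNP_OFFSET] = "A"
            cpgs = tuple(_FIRST_CPG + _CPG_SPACING * k for k in range(n_cpg))
            for i in cpgs:
                seq[i] = "C"
                seq[i + 1] = "G"
            seq_mus = "".join(seq)
            seq_cas = seq_mus[:_SNP_OFFSET] + "G" + seq_mus[_SNP_OFFSET + 1 :]
            primer = bs_convert(seq_mus[:_PRIMER_LEN], ())
            window = bs_convert(seq_mus[:win_len], ())
            # primers must be mutually non-matching under the scan rule,
            # including matches that begin inside the random stagger
            if any(
                _primers_collide(primer, w, smax) or _primers_collide(p, window, smax)
                for p, w in zip(primers, windows)
            ):
                continue
            break
        primers.append(primer)
        windows.append(window)
        specs.append(
            AmpliconSpec(
                gene_name=gene,
                seq_mus=seq_mus,
                seq_cas=seq_cas,
                snp_offset=_SNP_OFFSET,
                snp_base_mus="A",
                snp_base_cas="G",
                cpg_offsets=cpgs,
                primer=primer,
            )
        )
        for allele in ALLELES:
            for cpg in cpgs:
                if escapee:
                    f_5mc = float(rng.uniform(0.0, 0.03))
                    f_5hmc = float(rng.uniform(0.0, 0.03))
                elif allele == "mus":  # inactive X: heavily methylated
                    f_5mc = float(rng.uniform(0.5, 0.8))
                    f_5hmc = float(rng.uniform(0.05, 0.15))
                else:  # active X
                    f_5mc = float(rng.uniform(0.05, 0.25))
                    f_5hmc = float(rng.uniform(0.02, 0.10))
                truth_rows.append(
                    dict(
                        gene=gene,
                        allele=allele,
                        cpg_offset=cpg,
                        f_C=1.0 - f_5mc - f_5hmc,
                        f_5mC=f_5mc,
                        f_5hmC=f_5hmc,
                    )
                )
    return specs, MethylTruth.from_records(truth_rows)


def _check_span(spec: AmpliconSpec) -> None:
    smax = spec.stagger_range[1]
    worst = max(spec.snp_offset, spec.cpg_offsets[-1] + 1)
    if smax + worst > READ_LENGTH - 1:
        raise PanelConfigError(
            f"{spec.gene_name}: SNP or CpG at offset {worst} falls beyond the "
            f"{READ_LENGTH} bp read span with stagger {smax}"
        )


def _read_bodies(
    rng: np.random.Generator,
    spec: AmpliconSpec,
    allele: str,
    truth: MethylTruth,
    model: ChemistryModel,
    chemistry: str,
    n_reads: int,
) -> np.ndarray:
    """n_reads x len(amplicon) uint8 matrix of BS-space read bodies.

    CpG cytosines read as C with probability
        BS:   f_5mC + f_5hmC + f_C * (1 - conv_rate)
        OxBS: f_5mC + f_5hmC * (1 - ox_rate) + f_C * (1 - conv_rate)
    and non-CpG cytosines convert to T with probability conv_rate.  The
    PCR2 primer (a synthetic oligo, untouched by the chemistry) overwrites
    the amplicon prefix.
    """
    seq = spec.seq(allele)
    seq_b = np.frombuffer(seq.encode(), dtype=np.uint8)
    mat = np.tile(seq_b, (n_reads, 1))
    cpg_set = set(spec.cpg_offsets)
    noncpg_c = np.array(
        [i for i, b in enumerate(seq) if b == "C" and i not in cpg_set], dtype=int
    )
    if noncpg_c.size:
        converted = rng.random((n_reads, noncpg_c.size)) < model.conv_rate
        block = np.where(converted, _T, _C).astype(np.uint8)
        mat[:, noncpg_c] = block
    for cpg in spec.cpg_offsets:
        f_c, f_5mc, f_5hmc = truth.fractions(spec.gene_name, allele, cpg)
        if chemistry == "BS":
            p_c = f_5mc + f_5hmc + f_c * (1.0 - model.conv_rate)
        else:
            p_c = f_5mc + f_5hmc * (1.0 - model.ox_rate) + f_c * (1.0 - model.conv_rate)
        mat[:, cpg] = np.where(rng.random(n_reads) < p_c, _C, _T).astype(np.uint8)
    primer_b = np.frombuffer(spec.primer.encode(), dtype=np.uint8)
    mat[:, : primer_b.size] = primer_b
    return mat


def _apply_seq_error(rng: np.random.Generator, mat: np.ndarray, seq_err: float) -> None:
    if seq_err <= 0.0:
        return
    err = rng.random(mat.shape) < seq_err
    if not err.any():
        return
    # map A/C/G/T to 0..3, shift by 1-3 mod 4, map back
    lut = np.zeros(256, dtype=np.uint8)
    lut[_BASES] = np.arange(4)
    idx = lut[mat[err]]
    shift = rng.integers(1, 4, size=idx.size)
    mat[err] = _BASES[(idx + shift) % 4]


def simulate_reads(
    panel: Sequence[AmpliconSpec],
    truth: MethylTruth,
    model: ChemistryModel,
    manifest: SimManifest,
    return_read_truth: bool = False,
) -> dict:
    """Write single-end FASTQ files for every library in the manifest.

    Each read is 2-5 random stagger bases, the gene-specific primer, and
    the chemistry-transformed amplicon body, truncated to 300 bp.  Read
    names carry only the sample name and a serial number.  Returns a
    summary dict (per-sample read counts, paths); with
    ``return_read_truth=True`` it also carries a per-read (gene, allele)
    table for simulator-vs-pipeline accuracy checks.
    """
    for spec in panel:
        _check_span(spec)
    ss = np.random.SeedSequence([model.seed])
    children = ss.spawn(len(manifest.samples))
    summary: dict = {"samples": {}, "truth_path": manifest.truth_path}
    read_truth: list[tuple[str, str, str]] = []
    for sample, child in zip(manifest.samples, children):
        rng = np.random.default_rng(child)
        path = Path(sample.fastq_path)
        path.parent.mkdir(parents=True, exist_ok=True)
        serial = 0
        with open(path, "w") as fh:
            for spec in panel:
                smin, smax = spec.stagger_range
                for allele in ALLELES:
                    n = sample.reads_per_allele_per_gene
                    bodies = _read_bodies(
                        rng, spec, allele, truth, model, sample.chemistry, n
                    )
                    stag_len = rng.integers(smin, smax + 1, size=n)
                    stag = _BASES[rng.integers(0, 4, size=(n, smax))]
                    _apply_seq_error(rng, bodies, model.seq_err)
                    _apply_seq_error(rng, stag, model.seq_err)
                    for i in range(n):
                        read = (
                            stag[i, : stag_len[i]].tobytes() + bodies[i].tobytes()
                        )[:READ_LENGTH].decode()
                        name = f"{sample.name}:{serial}"
                        serial += 1
                        fh.write(f"@{name}\n{read}\n+\n{'I' * len(read)}\n")
                        if return_read_truth:
                            read_truth.append((name, spec.gene_name, allele))
        summary["samples"][sample.name] = {
            "path": str(path),
            "condition": sample.condition,
            "chemistry": sample.chemistry,
            "n_reads": serial,
        }
        log.info("wrote %d reads to %s", serial, path)
    if manifest.truth_path:
        truth.to_tsv(manifest.truth_path)
    if return_read_truth:
        summary["read_truth"] = pd.DataFrame(
            read_truth, columns=["read_id", "gene", "allele"]
        )
    return summary


# ---------------------------------------------------------------------------
# allele-specific expression count tables
# ---------------------------------------------------------------------------

DEFAULT_POPULATIONS = ("NPC", "d2", "d5", "d7_neg", "d7_med", "d7_high", "ESC")

#: fraction of full reactivation reached per population, used for the
#: reactivating-gene trajectory (NPC silent -> ESC fully biallelic)
_REACTIVATION_PROGRESS = {
    "NPC": 0.0,
    "d2": 0.2,
    "d5": 0.5,
    "d7_neg": 0.1,
    "d7_med": 0.5,
    "d7_high": 0.9,
    "ESC": 1.0,
}


def simulate_allelic_counts(
    n_genes: int = 30,
    populations: Sequence[str] = DEFAULT_POPULATIONS,
    seed: int = 0,
    mean_total: float = 10_000.0,
    nb_dispersion: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Allele-resolved count table plus its ground-truth allelic ratios.

    Per gene and population the total count is negative-binomial
    (mean ``mean_total``, dispersion ``nb_dispersion``) and the mus count
    is binomial with the gene's true ratio.  Gene categories cycle through
    reactivating (NPC ratio well under 0.135, rising with reprogramming),
    escapee (ratio above 0.135 everywhere), uninformative (cas fraction
    under 25%), and one fully silenced gene with true ratio 0.
    """
    if not populations:
        raise ValueError("populations must be non-empty")
    rng = np.random.default_rng(seed)
    categories = ["reactivating", "escapee", "uninformative"]
    rows: list[dict] = []
    truth: list[dict] = []
    for gi in range(n_genes):
        gene = f"G{gi + 1:04d}"
        category = "silenced" if gi == 0 else categories[(gi - 1) % 3]
        for pop in populations:
            progress = _REACTIVATION_PROGRESS.get(pop, 0.5)
            if category == "silenced":
                ratio = 0.0
            elif category == "reactivating":
                base = float(rng.uniform(0.0, 0.115))
                ratio = base + (0.5 - base) * progress
            elif category == "escapee":
                ratio = float(rng.uniform(0.155, 0.45))
            else:  # uninformative: mus-skewed, cas fraction < 25%
                ratio = float(rng.uniform(0.80, 0.95))
            p = nb_dispersion / (nb_dispersion + mean_total)
            total = int(rng.negative_binomial(nb_dispersion, p)) + 1
            mus = int(rng.binomial(total, ratio))
            rows.append(
                dict(gene=gene, population=pop, count_mus=mus, count_cas=total - mus)
            )
            truth.append(
                dict(gene=gene, population=pop, true_ratio=ratio, category=category)
            )
    return pd.DataFrame(rows), pd.DataFrame(truth)


def simulate_pluripotency_expression(
    seed: int = 0,
    populations: Sequence[str] = DEFAULT_POPULATIONS,
    replicates: int = 2,
) -> pd.DataFrame:
    """FPKM-like expression of the seven pluripotency genes per population.

    Expression scales with the population's reprogramming progress relative
    to ESCs, with mild multiplicative replicate noise.
    """
    from .expression import PLURIPOTENCY_GENES

    rng = np.random.default_rng(seed)
    esc_level = {g: float(rng.uniform(20.0, 200.0)) for g in PLURIPOTENCY_GENES}
    factor = {
        "NPC": 0.01, "d2": 0.05, "d5": 0.3, "d7_neg": 0.1,
        "d7_med": 0.5, "d7_high": 0.8, "ESC": 1.0,
    }
    rows = []
    for pop in populations:
        for rep in range(1, replicates + 1):
            for g in PLURIPOTENCY_GENES:
                noise = float(rng.uniform(0.9, 1.1))
                rows.append(
                    dict(
                        gene=g,
                        sample=f"{pop}_r{rep}",
                        population=pop,
                        replicate=rep,
                        expression=esc_level[g] * factor.get(pop, 0.5) * noise,
                    )
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# BS/OxBS array beta matrices
# ---------------------------------------------------------------------------

_FEATURES = ("promoter", "gene_body", "distal")


def simulate_beta_matrix(
    n_probes: int = 1000,
    n_samples_per_arm: int = 4,
    seed: int = 0,
    noise_sd: float = 0.03,
    qc_fail_rate: float = 0.02,
    ifng_5hmc_shift: float = 0.0,
    f_5hmc_max: float = 0.1,
    chrx_fraction: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired BS/OxBS beta values per probe and sample, plus probe truth.

    Per probe, beta_BS tracks f_5mC + f_5hmC and beta_OxBS tracks f_5mC,
    each with truncated-normal noise of the given SD.  ``ifng_5hmc_shift``
    plants a 5hmC gain in the IFNg arm (added to beta_BS only).  A
    ``qc_fail_rate`` fraction of probes is given a failing intensity
    (<1000) or detection p (>0.01) in one sample to exercise probe QC.
    """
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    rng = np.random.default_rng(seed)
    probe_ids = np.array([f"cg{i + 1:07d}" for i in range(n_probes)])
    chrom = np.where(
        rng.random(n_probes) < chrx_fraction,
        "chrX",
        np.char.add("chr", rng.integers(1, 20, size=n_probes).astype(str)),
    )
    feature = np.array(_FEATURES)[rng.integers(0, len(_FEATURES), size=n_probes)]
    f_5mc = rng.uniform(0.2, 0.6, size=n_probes)
    f_5hmc = rng.uniform(0.0, f_5hmc_max, size=n_probes) if f_5hmc_max > 0 else np.zeros(n_probes)
    truth = pd.DataFrame(
        dict(
            probe_id=probe_ids,
            chromosome=chrom,
            genomic_feature=feature,
            f_5mC=f_5mc,
            f_5hmC=f_5hmc,
        )
    )
    qc_fail = rng.random(n_probes) < qc_fail_rate
    rows = []
    arms = ("control", "IFNg")
    for arm in arms:
        for k in range(1, n_samples_per_arm + 1):
            sample_id = f"{arm}_s{k}"
            shift = ifng_5hmc_shift if arm == "IFNg" else 0.0
            for chemistry in ("BS", "OxBS"):
                mean = f_5mc + (f_5hmc + shift if chemistry == "BS" else 0.0)
                beta = np.clip(mean + rng.normal(0.0, noise_sd, size=n_probes), 0.0, 1.0)
                intensity = np.clip(rng.normal(3000.0, 500.0, size=n_probes), 1.0, None)
                det_p = rng.uniform(0.0, 0.005, size=n_probes)
                rows.append(
                    pd.DataFrame(
                        dict(
                            probe_id=probe_ids,
                            chromosome=chrom,
                            genomic_feature=feature,
                            sample_id=sample_id,
                            arm=arm,
                            chemistry=chemistry,
                            beta=beta,
                            intensity=intensity,
                            detection_p=det_p,
                        )
                    )
                )
    table = pd.concat(rows, ignore_index=True)
    # plant QC failures in one fixed sample so 'any-sample' QC catches them
    if qc_fail.any():
        victim = table["sample_id"] == f"{arms[0]}_s1"
        bs_rows = victim & (table["chemistry"] == "BS")
        failing = table["probe_id"].isin(probe_ids[qc_fail]) & bs_rows
        cause = rng.random(int(qc_fail.sum())) < 0.5
        cause_by_probe = dict(zip(probe_ids[qc_fail], cause))
        fail_idx = table.index[failing]
        for idx in fail_idx:
            pid = table.at[idx, "probe_id"]
            if cause_by_probe[pid]:
                table.at[idx, "intensity"] = float(rng.uniform(100.0, 999.0))
            else:
                table.at[idx, "detection_p"] = float(rng.uniform(0.0101, 0.05))
    truth["qc_fail"] = qc_fail
    return table, truth


# ---------------------------------------------------------------------------
# CRISPR-screen gene-summary tables
# ---------------------------------------------------------------------------

def simulate_screen_tables(
    n_genes: int = 1000,
    comparisons: Sequence[str] = ("non_vs_NPC", "early_vs_NPC", "late_vs_NPC"),
    seed: int = 0,
    hit_fraction: float = 0.05,
    essential_fraction: float = 0.03,
) -> dict[str, pd.DataFrame]:
    """MAGeCK-style gene-summary tables with planted enriched/depleted hits.

    RRA scores are uniform on (0.05, 1) for null genes and (0, 0.05) for
    planted hits; planted hits get |log2FC| in (0.9, 2.5) and goodsgrna
    3-5, null genes modest fold changes and goodsgrna 0-5.  A shared
    ``essential_fraction`` of genes is depleted in every comparison,
    emulating the essentialome.
    """
    rng = np.random.default_rng(seed)
    genes = np.array([f"Gene{i + 1:05d}" for i in range(n_genes)])
    n_ess = int(round(n_genes * essential_fraction))
    essential = rng.choice(n_genes, size=n_ess, replace=False)
    out: dict[str, pd.DataFrame] = {}
    for comp in comparisons:
        n_hits = int(round(n_genes * hit_fraction))
        hit_idx = rng.choice(n_genes, size=2 * n_hits, replace=False)
        enr, dep = hit_idx[:n_hits], hit_idx[n_hits:]
        rra_pos = rng.uniform(0.05, 1.0, size=n_genes)
        rra_neg = rng.uniform(0.05, 1.0, size=n_genes)
        lfc = rng.normal(0.0, 0.4, size=n_genes)
        good = rng.integers(0, 6, size=n_genes)
        rra_pos[enr] = rng.uniform(0.0, 0.05, size=n_hits)
        lfc[enr] = rng.uniform(0.9, 2.5, size=n_hits)
        rra_neg[dep] = rng.uniform(0.0, 0.05, size=n_hits)
        lfc[dep] = -rng.uniform(0.9, 2.5, size=n_hits)
        good[np.concatenate([enr, dep])] = rng.integers(3, 6, size=2 * n_hits)
        if n_ess:
            rra_neg[essential] = rng.uniform(0.0, 0.05, size=n_ess)
            lfc[essential] = -rng.uniform(0.8, 2.0, size=n_ess)
            good[essential] = rng.integers(3, 6, size=n_ess)
        out[comp] = pd.DataFrame(
            dict(
                gene=genes,
                rra_score_pos=rra_pos,
                rra_score_neg=rra_neg,
                log2FC=lfc,
                goodsgrna=good,
            )
        )
    return out
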
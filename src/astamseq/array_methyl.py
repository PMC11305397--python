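"""BS/OxBS methylation-array processing.

Paired bisulfite (BS) and oxidative-bisulfite (OxBS) arrays measure, per
probe, beta values tracking 5mC + 5hmC and 5mC respectively.  This module
implements probe quality control, the 5mC/5hmC deconvolution
(beta_5mC = beta_OxBS, beta_5hmC = beta_BS - beta_OxBS), treatment-arm
delta-beta summaries per chromosome-class x genomic-feature stratum, and
the differentially-(hydroxy)methylated-position (DMP) threshold filter
(p < 0.01 and |logFC| >= 0.1, with logFC a difference on the beta scale).

The built-in per-probe test is a plain Welch two-sample t test; the DMP
filter itself consumes p-values from any source.  Negative beta_5hmC
values are retained here (no amplicon-style clamp).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

MIN_INTENSITY = 1000          # probes below this intensity are removed
MAX_DETECTION_P = 0.01        # probes above this detection p are removed
DMP_P_THRESHOLD = 0.01        # raw p must be strictly below
DMP_LFC_THRESHOLD = 0.1       # |logFC| must be at least this

CHROM_CLASSES = ("autosome", "chrX")
FEATURES = ("promoter", "gene_body", "distal")


def probe_qc(
    table: pd.DataFrame,
    min_intensity: float = MIN_INTENSITY,
    max_detection_p: float = MAX_DETECTION_P,
    per_sample: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Remove erratic probes; report removal counts per cause.

    Thresholds are literal: intensity strictly below ``min_intensity``
    fails (999 removed, 1000 kept) and detection p strictly above
    ``max_detection_p`` fails (0.01 kept).  By default a probe failing in
    any sample is removed everywhere; ``per_sample=True`` drops only the
    offending rows instead.
    """
    low_int = table["intensity"] < min_intensity
    high_p = table["detection_p"] > max_detection_p
    bad = low_int | high_p
    if per_sample:
        filtered = table[~bad].reset_index(drop=True)
        report = {
            "mode": "per_sample",
            "low_intensity": int(low_int.sum()),
            "high_detection_p": int(high_p.sum()),
            "removed_rows": int(bad.sum()),
        }
        return filtered, report
    probes = table["probe_id"]
    bad_int_probes = set(probes[low_int])
    bad_p_probes = set(probes[high_p])
    removed = bad_int_probes | bad_p_probes
    filtered = table[~probes.isin(removed)].reset_index(drop=True)
    report = {
        "mode": "any_sample",
        "low_intensity": len(bad_int_probes),
        "high_detection_p": len(bad_p_probes),
        "removed_probes": len(removed),
        "input_probes": int(probes.nunique()),
        "output_probes": int(filtered["probe_id"].nunique()),
    }
    return filtered, report


def deconvolve_beta(beta_bs, beta_oxbs):
    """(beta_5mC, beta_5hmC) = (beta_OxBS, beta_BS - beta_OxBS).

    No clamping: negative 5hmC values are passed through.
    """
    beta_bs = np.asarray(beta_bs, dtype=float)
    beta_oxbs = np.asarray(beta_oxbs, dtype=float)
    b5mc = beta_oxbs
    b5hmc = beta_bs - beta_oxbs
    if b5mc.ndim == 0:
        return float(b5mc), float(b5hmc)
    return b5mc, b5hmc


def deconvolve_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per (probe, sample) 5mC/5hmC betas from a long BS/OxBS beta table."""
    meta_cols = ["probe_id", "chromosome", "genomic_feature", "sample_id", "arm"]
    wide = table.pivot_table(
        index=meta_cols, columns="chemistry", values="beta", aggfunc="first"
    ).reset_index()
    if "BS" not in wide.columns or "OxBS" not in wide.columns:
        raise ValueError("table must contain both BS and OxBS chemistries")
    b5mc, b5hmc = deconvolve_beta(
        wide["BS"].to_numpy(), wide["OxBS"].to_numpy()
    )
    wide["beta_5mC"] = b5mc
    wide["beta_5hmC"] = b5hmc
    return wide.drop(columns=["BS", "OxBS"])


def delta_beta(values_treatment, values_control) -> float:
    """mean(treatment) - mean(control); NaN when a group is empty."""
    vt = np.asarray(values_treatment, dtype=float)
    vc = np.asarray(values_control, dtype=float)
    if vt.size == 0 or vc.size == 0:
        return float("nan")
    return float(vt.mean() - vc.mean())


def dmp_test(
    deconv: pd.DataFrame,
    mark: str = "5hmC",
    treatment_arm: str = "IFNg",
    control_arm: str = "control",
) -> pd.DataFrame:
    """Per-probe Welch t test of a mark between treatment arms.

    Returns probe_id, logFC (delta beta, treatment - control), p_value
    and a Benjamini-Hochberg adjusted p alongside (selection downstream
    uses the raw p).
    """
    col = f"beta_{mark}"
    if col not in deconv.columns:
        raise ValueError(f"no column {col!r}; run deconvolve_table first")
    rows = []
    for probe, sub in deconv.groupby("probe_id", sort=True):
        vt = sub.loc[sub["arm"] == treatment_arm, col].to_numpy()
        vc = sub.loc[sub["arm"] == control_arm, col].to_numpy()
        lfc = delta_beta(vt, vc)
        if vt.size >= 2 and vc.size >= 2:
            _t, p = stats.ttest_ind(vt, vc, equal_var=False)
            p = float(p)
        else:
            p = float("nan")
        rows.append(dict(probe_id=probe, logFC=lfc, p_value=p, mark=mark))
    out = pd.DataFrame(rows)
    ok = out["p_value"].notna()
    out["p_adj"] = np.nan
    if ok.any():
        out.loc[ok, "p_adj"] = multipletests(
            out.loc[ok, "p_value"], method="fdr_bh"
        )[1]
    return out


def dmp_filter(
    per_probe: pd.DataFrame,
    p_threshold: float = DMP_P_THRESHOLD,
    lfc_threshold: float = DMP_LFC_THRESHOLD,
) -> pd.DataFrame:
    """Flag DMPs: significant iff p < p_threshold and |logFC| >= lfc_threshold.

    Adds ``significant`` and a hyper/hypo ``direction`` label by logFC sign.
    """
    out = per_probe.copy()
    out["significant"] = (out["p_value"] < p_threshold) & (
        out["logFC"].abs() >= lfc_threshold
    )
    out["direction"] = np.where(out["logFC"] >= 0, "hyper", "hypo")
    return out


def stratum_summary(
    values: pd.DataFrame,
    value_col: str = "value",
    treatment_arm: str = "IFNg",
    control_arm: str = "control",
) -> pd.DataFrame:
    """Per-stratum arm means, delta beta and an unpaired Welch t test.

    Strata are chromosome class (chrX vs autosome) crossed with genomic
    feature, plus a 'global' feature row per chromosome class.  Input is a
    long table with columns chromosome, genomic_feature, arm and the value
    column.  Strata with fewer than two values in an arm report means but
    omit the test.
    """
    df = values.copy()
    df["chrom_class"] = np.where(df["chromosome"] == "chrX", "chrX", "autosome")
    rows = []
    features = ["global"] + sorted(df["genomic_feature"].unique())
    for chrom_class in sorted(df["chrom_class"].unique()):
        base = df[df["chrom_class"] == chrom_class]
        for feature in features:
            sub = base if feature == "global" else base[base["genomic_feature"] == feature]
            if sub.empty:
                continue
            vt = sub.loc[sub["arm"] == treatment_arm, value_col].to_numpy()
            vc = sub.loc[sub["arm"] == control_arm, value_col].to_numpy()
            mean_t = float(vt.mean()) if vt.size else float("nan")
            mean_c = float(vc.mean()) if vc.size else float("nan")
            if vt.size >= 2 and vc.size >= 2:
                t_stat, p = stats.ttest_ind(vt, vc, equal_var=False)
                t_stat, p = float(t_stat), float(p)
            else:
                t_stat, p = float("nan"), float("nan")
            rows.append(
                dict(
                    chrom_class=chrom_class,
                    genomic_feature=feature,
                    mean_control=mean_c,
                    mean_treatment=mean_t,
                    delta_beta=delta_beta(vt, vc),
                    t_stat=t_stat,
                    p_value=p,
                    n_control=int(vc.size),
                    n_treatment=int(vt.size),
                )
            )
    return pd.DataFrame(rows)
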
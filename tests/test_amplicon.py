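"""Read classification, %CG computation, 5mC/5hmC deconvolution and the
negative-5hmC filter rules."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from Bio.SeqIO.QualityIO import FastqGeneralIterator

import astamseq as a
from astamseq.amplicon import _find_unique, percent_cg
from astamseq.panel import PanelConfigError, bs_convert


# --- reference conversion and anchors --------------------------------------

def test_bs_convert_marks_cpg_and_converts_other_c():
    assert bs_convert("ACGTCCA", [1]) == "AYGTTTA"
    assert bs_convert("AGTTAGA", []) == "AGTTAGA"  # nothing to convert


def test_anchor_lengths_within_assay_range(refs):
    for ref in refs:
        for allele in ("mus", "cas"):
            assert 15 <= len(ref.snp_anchor[allele]) <= 20
            for anchor in ref.cpg_anchor[allele].values():
                assert 15 <= len(anchor) <= 20
                assert "Y" not in anchor


def _spec_with(seq_mus, snp=30, cpgs=(), primer_len=10):
    seq = list(seq_mus)
    seq[snp] = "A"
    seq_mus = "".join(seq)
    seq_cas = seq_mus[:snp] + "G" + seq_mus[snp + 1 :]
    return a.AmpliconSpec(
        gene_name="crafted", seq_mus=seq_mus, seq_cas=seq_cas,
        snp_offset=snp, snp_base_mus="A", snp_base_cas="G",
        cpg_offsets=tuple(cpgs), primer=bs_convert(seq_mus[:primer_len], ()),
    )


def test_anchor_too_close_to_read_start_is_rejected():
    seq = list("AT" * 110)
    seq[29] = "T"
    for i in (12,):
        seq[i], seq[i + 1] = "C", "G"
    spec = _spec_with("".join(seq), cpgs=(12,), primer_len=5)
    with pytest.raises(PanelConfigError, match="read start"):
        a.bs_convert_reference(spec)


def test_anchor_window_containing_cpg_is_rejected():
    from astamseq.simulate import _random_seq_no_cpg

    rng = np.random.default_rng(0)
    seq = _random_seq_no_cpg(rng, 220)
    seq[29] = "T"
    for i in (60, 70):  # 10 bp apart: the second CpG's window hits the first
        seq[i], seq[i + 1] = "C", "G"
    spec = _spec_with("".join(seq), cpgs=(60, 70))
    with pytest.raises(PanelConfigError, match="CpG cytosine"):
        a.bs_convert_reference(spec)


# --- per-read classification ------------------------------------------------

def test_assign_gene_finds_constructed_read(refs):
    ref = refs[0]
    read = "AAA" + ref.primer + "T" * 50
    assert a.assign_gene(read, refs) == ref.gene
    assert a.assign_gene("A" * 60, refs) is None
    assert a.assign_gene("", refs) is None


def test_simulated_reads_classify_perfectly_without_errors(ideal_run, refs):
    """With seq_err = 0, every read maps to its generating gene and allele."""
    truth = ideal_run["summary"]["read_truth"].set_index("read_id")
    ref_by_gene = {r.gene: r for r in refs}
    checked = 0
    for path, _cond, _chem in ideal_run["samples"][:2]:
        with open(path) as fh:
            for title, seq, _q in FastqGeneralIterator(fh):
                expect = truth.loc[title]
                gene = a.assign_gene(seq, refs)
                assert gene == expect["gene"]
                allele = a.assign_allele(seq, ref_by_gene[gene])
                assert allele == expect["allele"]
                checked += 1
    assert checked == 2 * 6 * 2 * ideal_run["reads_per_allele"]


def test_call_cpg_reads_two_mer_after_anchor(refs):
    ref = refs[0]
    cpg = ref.cpg_offsets[0]
    body = bs_convert(ref.spec.seq_mus, ref.spec.cpg_offsets)
    read_meth = "AA" + body.replace("Y", "C")
    read_unmeth = "AA" + body.replace("Y", "T")
    assert a.call_cpg(read_meth, ref, cpg, "mus") == "CG"
    assert a.call_cpg(read_unmeth, ref, cpg, "mus") == "TG"
    # sequencing error at the CpG guanine makes the call uninterpretable
    anchor = ref.cpg_anchor["mus"][cpg]
    i = read_meth.find(anchor) + len(anchor)
    broken = read_meth[: i + 1] + "A" + read_meth[i + 2 :]
    assert a.call_cpg(broken, ref, cpg, "mus") == "other"
    # anchor absent (truncated read) -> other / ambiguous
    assert a.call_cpg(read_meth[:20], ref, cpg, "mus") == "other"
    assert a.assign_allele(read_meth[:20], ref) == "ambiguous"


def test_find_unique_rejects_duplicate_hits():
    assert _find_unique("TTAGCTTAGC", "TTAGC") is None
    assert _find_unique("TTAGCAAAAA", "TTAGC") == 0
    assert _find_unique("GGGG", "TTAGC") is None
    assert _find_unique("TTAGG" + "A" * 6, "TTAGC", max_mismatch=1) == 0


# --- tallying ---------------------------------------------------------------

def test_tally_conserves_reads(ideal_run):
    t = ideal_run["tally"]
    t.check_conservation()
    assigned = sum(g["assigned"] for g in t.per_gene.values())
    assert assigned + t.n_unassigned == t.n_total
    # each qualifying read contributes one call (CG/TG/other) to every CpG
    df = t.to_frame()
    totals = df.assign(n=df.n_CG + df.n_TG + df.n_other).groupby(
        ["gene", "condition", "chemistry", "allele"]
    )["n"].nunique()
    assert (totals == 1).all()


def test_tally_empty_fastq_is_all_zero(tmp_path, refs):
    p = tmp_path / "empty.fastq"
    p.write_text("")
    t = a.tally([(str(p), "control", "BS")], refs)
    assert t.n_total == 0 and not t.counts


def test_tally_rejects_unknown_chemistry(tmp_path, refs):
    p = tmp_path / "x.fastq"
    p.write_text("")
    with pytest.raises(ValueError, match="chemistry"):
        a.tally([(str(p), "control", "oxidative")], refs)


def test_gene_assignment_rate_under_default_error_model(default_chem_run):
    """At a 1e-3 substitution rate, at least 99% of reads are demultiplexed."""
    t = default_chem_run["tally"]
    assert t.n_total == sum(
        s["n_reads"] for s in default_chem_run["summary"]["samples"].values()
    )
    assert t.n_total - t.n_unassigned >= 0.99 * t.n_total


# --- percentages and deconvolution ------------------------------------------

@pytest.mark.parametrize(
    "n_cg,n_tg,expected",
    [(60, 40, 60.0), (0, 40, 0.0), (1, 2, 100.0 / 3.0)],
)
def test_percent_cg(n_cg, n_tg, expected):
    assert percent_cg(n_cg, n_tg) == pytest.approx(expected, rel=1e-12)


def test_percent_cg_zero_denominator_is_missing():
    assert math.isnan(percent_cg(0, 0))


@pytest.mark.parametrize(
    "bs,ox,expected",
    [((60, 40), None, (40, 20)), ((30, 30), None, (30, 0)), ((30, 32), None, (32, -2))],
)
def test_deconvolve_formula(bs, ox, expected):
    assert a.deconvolve(*bs) == expected


# --- negative-5hmC filter rules ---------------------------------------------

def _estimates(raws):
    rows = []
    for (allele, condition), raw in raws.items():
        rows.append(
            dict(
                gene="g", condition=condition, allele=allele, cpg_offset=10,
                pct_CG_BS=50.0, pct_CG_OxBS=50.0 - raw,
                coverage_BS=1000, coverage_OxBS=1000,
                pct_5mC=50.0 - raw, pct_5hmC_raw=float(raw), low_coverage=False,
            )
        )
    return pd.DataFrame(rows)


_CELLS = [("mus", "control"), ("mus", "IFNg"), ("cas", "control"), ("cas", "IFNg")]


def test_one_negative_cell_discards_whole_cpg():
    raws = dict(zip(_CELLS, [-2.0, 5.0, 5.0, 5.0]))
    out = a.apply_5hmc_filters(_estimates(raws))
    assert (out["status"] == "discarded").all()


def test_small_negative_clamps_to_zero():
    raws = dict(zip(_CELLS, [-0.5, 5.0, 5.0, 5.0]))
    out = a.apply_5hmc_filters(_estimates(raws)).set_index(["allele", "condition"])
    assert out.loc[("mus", "control"), "status"] == "clamped"
    assert out.loc[("mus", "control"), "pct_5hmC"] == 0.0
    assert (out.drop(index=("mus", "control"))["status"] == "kept").all()


def test_nonnegative_cells_kept_unchanged():
    raws = dict(zip(_CELLS, [0.0, 5.0, 1.0, 2.0]))
    out = a.apply_5hmc_filters(_estimates(raws))
    assert (out["status"] == "kept").all()
    assert (out["pct_5hmC"] == out["pct_5hmC_raw"]).all()


def test_missing_cell_marks_cpg_missing():
    raws = dict(zip(_CELLS[:3], [1.0, 2.0, 3.0]))
    out = a.apply_5hmc_filters(_estimates(raws))
    assert (out["status"] == "missing").all()


def test_filters_idempotent_and_order_independent():
    raws = dict(zip(_CELLS, [-0.5, -2.0, 5.0, 0.5]))
    base = _estimates(raws)
    once = a.apply_5hmc_filters(base)
    twice = a.apply_5hmc_filters(once)
    pd.testing.assert_frame_equal(once, twice[once.columns])
    shuffled = base.sample(frac=1.0, random_state=0)
    out_shuffled = a.apply_5hmc_filters(shuffled).sort_index()
    pd.testing.assert_frame_equal(once, out_shuffled[once.columns])


# --- recovery properties -----------------------------------------------------

def _roundtrip_z(run):
    """z-scores of (estimate - truth) per cell and mark, truth-based SE."""
    truth = run["truth"].frame.set_index(["gene", "allele", "cpg_offset"])
    zs = []
    for r in run["estimates"].itertuples():
        t = truth.loc[(r.gene, r.allele, r.cpg_offset)]
        p_bs = t.f_5mC + t.f_5hmC
        p_ox = t.f_5mC
        se_mc = 100 * math.sqrt(max(p_ox * (1 - p_ox), 1e-12) / r.coverage_OxBS)
        se_bs = 100 * math.sqrt(max(p_bs * (1 - p_bs), 1e-12) / r.coverage_BS)
        se_hmc = math.sqrt(se_bs**2 + se_mc**2)
        zs.append((r.pct_5mC - 100 * p_ox) / se_mc)
        zs.append((r.pct_5hmC_raw - 100 * (p_bs - p_ox)) / se_hmc)
    return np.array(zs)


def test_roundtrip_recovery_tracks_binomial_error(ideal_run):
    z = _roundtrip_z(ideal_run)
    assert (np.abs(z) <= 3).mean() >= 0.95
    assert np.abs(z).max() <= 5


def test_lower_oxidation_shifts_5hmc_into_5mc(default_panel, tmp_path):
    """Incomplete oxidation leaves 5hmC reading as C in OxBS, inflating the
    5mC estimate monotonically as ox_rate drops."""
    panel, _ = default_panel
    spec = panel[0]
    truth = a.MethylTruth.from_records(
        [dict(gene=spec.gene_name, allele=al, cpg_offset=cpg,
              f_C=0.2, f_5mC=0.3, f_5hmC=0.5)
         for al in ("mus", "cas") for cpg in spec.cpg_offsets]
    )
    means = []
    for ox in (1.0, 0.95, 0.9):
        manifest = a.SimManifest.default(
            tmp_path / f"ox{ox}", reads_per_allele_per_gene=5000,
            conditions=("control",),
        )
        model = a.ChemistryModel(conv_rate=1.0, ox_rate=ox, seq_err=0.0, seed=2)
        a.simulate_reads([spec], truth, model, manifest)
        samples = [(s.fastq_path, s.condition, s.chemistry) for s in manifest.samples]
        _t, est = a.run_pipeline([spec], samples)
        means.append(est["pct_5mC"].mean())
    assert means[0] < means[1] < means[2]
    se = 100 * math.sqrt(0.3 * 0.7 / 5000) / math.sqrt(len(spec.cpg_offsets) * 2)
    assert means[0] >= 30.0 - 3 * se


def test_escapee_estimates_stay_low(default_chem_run):
    est = default_chem_run["estimates"]
    sub = est[est["gene"].isin(["Ddx3x", "Eif2s3x"])]
    assert not sub.empty
    assert (sub["pct_5mC"] <= 7.0).all()
    assert (sub["pct_5hmC"].dropna() <= 7.0).all()
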
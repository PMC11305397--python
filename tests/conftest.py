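"""Shared fixtures: simulated runs reused across test modules.

All simulations are seeded so the suite is deterministic.
"""

from __future__ import annotations

import pytest

import astamseq as a


@pytest.fixture(scope="session")
def default_panel():
    return a.make_default_panel(1)


@pytest.fixture(scope="session")
def refs(default_panel):
    panel, _truth = default_panel
    return a.build_references(panel)


def _run(panel, truth, model, outdir, reads, conditions=("control", "IFNg")):
    manifest = a.SimManifest.default(
        outdir, reads_per_allele_per_gene=reads, conditions=conditions
    )
    summary = a.simulate_reads(panel, truth, model, manifest, return_read_truth=True)
    samples = [
        (s["path"], s["condition"], s["chemistry"])
        for s in summary["samples"].values()
    ]
    tally, estimates = a.run_pipeline(panel, samples)
    return dict(
        panel=panel,
        truth=truth,
        summary=summary,
        samples=samples,
        tally=tally,
        estimates=estimates,
        reads_per_allele=reads,
    )


@pytest.fixture(scope="session")
def ideal_run(default_panel, tmp_path_factory):
    """Default panel under perfect chemistry, 2,000 reads/allele/library."""
    panel, truth = default_panel
    return _run(
        panel, truth, a.ChemistryModel.ideal(seed=1),
        tmp_path_factory.mktemp("ideal_run"), reads=2000,
    )


@pytest.fixture(scope="session")
def default_chem_run(default_panel, tmp_path_factory):
    """Default panel under the default error model (conv 0.99, ox 0.95,
    seq error 1e-3), 2,000 reads/allele/library."""
    panel, truth = default_panel
    return _run(
        panel, truth, a.ChemistryModel(seed=7),
        tmp_path_factory.mktemp("default_chem_run"), reads=2000,
    )


@pytest.fixture(scope="session")
def deep_ideal_run(default_panel, tmp_path_factory):
    """Single-condition run at 20,000 reads/allele/chemistry under ideal
    chemistry — the full-coverage round-trip setting."""
    panel, truth = default_panel
    return _run(
        panel, truth, a.ChemistryModel.ideal(seed=1),
        tmp_path_factory.mktemp("deep_ideal_run"), reads=20_000,
        conditions=("control",),
    )
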
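"""Domain types for targeted-amplicon oxidative-bisulfite panels.

An amplicon panel describes, per gene, the two haplotype sequences of a
PCR amplicon spanning one species-specific SNP (Mus musculus "mus" vs
M. castaneus "cas") and one or more CpG dinucleotides, together with the
gene-specific PCR2 primer used for demultiplexing.  The types here are
shared by the read simulator and the analysis pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

ALLELES = ("mus", "cas")
CHEMISTRIES = ("BS", "OxBS")

#: read length of the single-end sequencing run the pipeline assumes (bp)
READ_LENGTH = 300

#: amplicon length bounds enforced on every panel entry (bp)
AMPLICON_MIN_LEN = 200
AMPLICON_MAX_LEN = 500

#: permitted range for the random stagger prepended to each read
STAGGER_MIN = 2
STAGGER_MAX = 5

_DNA = set("ACGT")


class PanelConfigError(ValueError):
    """A panel definition violates an invariant the pipeline relies on."""


def bs_convert(seq: str, cpg_offsets: Iterable[int], cpg_mark: str = "Y") -> str:
    """Bisulfite-convert a reference sequence in silico (top strand).

    Every cytosine outside a CpG context is converted to T.  Cytosines at
    the given CpG offsets are methylation-dependent in real reads, so they
    are replaced by ``cpg_mark`` (default ``Y``, the IUPAC C/T ambiguity
    code) rather than a concrete base.
    """
    cpgs = set(cpg_offsets)
    out = list(seq)
    for i, b in enumerate(out):
        if b == "C":
            out[i] = cpg_mark if i in cpgs else "T"
    return "".join(out)


def bs_base(base: str) -> str:
    """BS-space identity of a single non-CpG base (C reads as T)."""
    return "T" if base == "C" else base


@dataclass(frozen=True)
class AmpliconSpec:
    """Two-haplotype geometry of one targeted amplicon.

    ``seq_mus`` and ``seq_cas`` are equal-length DNA strings differing at
    exactly ``snp_offset``.  ``cpg_offsets`` index the CpG cytosines shared
    by both haplotypes.  ``primer`` is the gene-specific PCR2 primer: a
    prefix of the BS-converted amplicon that contains no CpG cytosine and
    ends before the SNP.
    """

    gene_name: str
    seq_mus: str
    seq_cas: str
    snp_offset: int
    snp_base_mus: str
    snp_base_cas: str
    cpg_offsets: tuple[int, ...]
    primer: str
    stagger_range: tuple[int, int] = (STAGGER_MIN, STAGGER_MAX)

    def __post_init__(self) -> None:
        object.__setattr__(self, "cpg_offsets", tuple(sorted(self.cpg_offsets)))
        object.__setattr__(self, "stagger_range", tuple(self.stagger_range))
        self._validate()

    def _validate(self) -> None:
        g = self.gene_name
        n = len(self.seq_mus)
        if not (AMPLICON_MIN_LEN <= n <= AMPLICON_MAX_LEN):
            raise PanelConfigError(
                f"{g}: amplicon length {n} outside "
                f"[{AMPLICON_MIN_LEN}, {AMPLICON_MAX_LEN}]"
            )
        if len(self.seq_cas) != n:
            raise PanelConfigError(f"{g}: haplotype sequences differ in length")
        for seq, lbl in ((self.seq_mus, "mus"), (self.seq_cas, "cas")):
            if not set(seq) <= _DNA:
                raise PanelConfigError(f"{g}: non-ACGT character in seq_{lbl}")
        diffs = [i for i in range(n) if self.seq_mus[i] != self.seq_cas[i]]
        if diffs != [self.snp_offset]:
            raise PanelConfigError(
                f"{g}: haplotypes must differ at exactly snp_offset="
                f"{self.snp_offset}, found differences at {diffs}"
            )
        if self.seq_mus[self.snp_offset] != self.snp_base_mus:
            raise PanelConfigError(f"{g}: snp_base_mus does not match seq_mus")
        if self.seq_cas[self.snp_offset] != self.snp_base_cas:
            raise PanelConfigError(f"{g}: snp_base_cas does not match seq_cas")
        if self.snp_base_mus == self.snp_base_cas:
            raise PanelConfigError(f"{g}: SNP bases must be distinct")
        # A C/T SNP (or any pair that collapses after conversion) cannot be
        # read out of bisulfite-treated material on this strand.
        if bs_base(self.snp_base_mus) == bs_base(self.snp_base_cas):
            raise PanelConfigError(
                f"{g}: SNP {self.snp_base_mus}/{self.snp_base_cas} is "
                "indistinguishable after bisulfite conversion"
            )
        for i in self.cpg_offsets:
            for seq, lbl in ((self.seq_mus, "mus"), (self.seq_cas, "cas")):
                if i + 1 >= n or seq[i] != "C" or seq[i + 1] != "G":
                    raise PanelConfigError(
                        f"{g}: cpg_offset {i} is not a CpG on the {lbl} haplotype"
                    )
        if not self.cpg_offsets:
            raise PanelConfigError(f"{g}: at least one CpG offset required")
        if self.snp_offset in self.cpg_offsets:
            raise PanelConfigError(f"{g}: SNP coincides with a CpG cytosine")
        # Primer constraints: prefix of the BS-converted amplicon, free of
        # CpG cytosines, ending before the SNP.
        if len(self.primer) > self.snp_offset:
            raise PanelConfigError(f"{g}: primer covers the SNP position")
        if any(i < len(self.primer) for i in self.cpg_offsets):
            raise PanelConfigError(f"{g}: primer covers a CpG cytosine")
        expected = bs_convert(self.seq_mus[: len(self.primer)], ())
        if self.primer != expected:
            raise PanelConfigError(
                f"{g}: primer is not the BS-converted amplicon prefix"
            )
        lo, hi = self.stagger_range
        if not (STAGGER_MIN <= lo <= hi <= STAGGER_MAX):
            raise PanelConfigError(
                f"{g}: stagger_range {self.stagger_range} outside "
                f"[{STAGGER_MIN}, {STAGGER_MAX}]"
            )

    def seq(self, allele: str) -> str:
        if allele == "mus":
            return self.seq_mus
        if allele == "cas":
            return self.seq_cas
        raise KeyError(allele)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cpg_offsets"] = list(self.cpg_offsets)
        d["stagger_range"] = list(self.stagger_range)
        return d


def write_panel(panel: Sequence[AmpliconSpec], path: str | Path) -> None:
    """Serialize a panel to YAML (or JSON when the suffix is .json)."""
    path = Path(path)
    payload = {"amplicons": [s.to_dict() for s in panel]}
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def read_panel(path: str | Path) -> list[AmpliconSpec]:
    path = Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    specs = []
    for d in payload["amplicons"]:
        d = dict(d)
        d["cpg_offsets"] = tuple(d["cpg_offsets"])
        d["stagger_range"] = tuple(d.get("stagger_range", (STAGGER_MIN, STAGGER_MAX)))
        specs.append(AmpliconSpec(**d))
    return specs


class MethylTruth:
    """Ground-truth cytosine-state fractions per (gene, allele, CpG).

    Each entry gives the fractions of molecules carrying unmodified C,
    5-methylcytosine and 5-hydroxymethylcytosine at one CpG on one
    haplotype; the three fractions must sum to one.
    """

    COLUMNS = ("gene", "allele", "cpg_offset", "f_C", "f_5mC", "f_5hmC")

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"truth table missing columns: {sorted(missing)}")
        frame = frame.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        sums = frame[["f_C", "f_5mC", "f_5hmC"]].sum(axis=1)
        bad = (sums - 1.0).abs() > 1e-9
        if bad.any():
            rows = frame.loc[bad, ["gene", "allele", "cpg_offset"]]
            raise ValueError(
                "cytosine-state fractions must sum to 1; offending rows:\n"
                + rows.to_string(index=False)
            )
        if ((frame[["f_C", "f_5mC", "f_5hmC"]] < -1e-12).any().any()):
            raise ValueError("cytosine-state fractions must be non-negative")
        self.frame = frame
        self._lookup = {
            (r.gene, r.allele, int(r.cpg_offset)): (r.f_C, r.f_5mC, r.f_5hmC)
            for r in frame.itertuples()
        }

    def fractions(self, gene: str, allele: str, cpg_offset: int) -> tuple[float, float, float]:
        return self._lookup[(gene, allele, cpg_offset)]

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MethylTruth":
        return cls(pd.read_csv(path, sep="\t"))

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "MethylTruth":
        return cls(pd.DataFrame.from_records(list(records)))


@dataclass(frozen=True)
class ChemistryModel:
    """Parametric model of the BS/OxBS chemistry and the sequencer.

    conv_rate : probability that an unmodified C is converted (reads as T).
    ox_rate   : probability that a 5hmC is oxidized in the OxBS arm and
                hence reads as T; 5hmC escaping oxidation reads as C.
    seq_err   : per-base substitution error applied after chemistry.
    """

    conv_rate: float = 0.99
    ox_rate: float = 0.95
    seq_err: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("conv_rate", "ox_rate", "seq_err"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

    @classmethod
    def ideal(cls, seed: int = 0) -> "ChemistryModel":
        """Perfect conversion and oxidation, error-free sequencing."""
        return cls(conv_rate=1.0, ox_rate=1.0, seq_err=0.0, seed=seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ChemistryModel":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class SimSample:
    """One simulated sequencing library."""

    name: str
    condition: str
    chemistry: str
    reads_per_allele_per_gene: int
    fastq_path: str

    def __post_init__(self) -> None:
        if self.chemistry not in CHEMISTRIES:
            raise ValueError(f"chemistry must be one of {CHEMISTRIES}")
        if self.reads_per_allele_per_gene < 1:
            raise ValueError("reads_per_allele_per_gene must be >= 1")


@dataclass
class SimManifest:
    """The set of libraries one simulation run produces.

    Mirrors the paired mock-oxidation / oxidation design: every condition
    must contribute both a BS and an OxBS library.
    """

    samples: list[SimSample]
    truth_path: str | None = None

    def __post_init__(self) -> None:
        by_condition: dict[str, set[str]] = {}
        for s in self.samples:
            by_condition.setdefault(s.condition, set()).add(s.chemistry)
        for cond, chems in by_condition.items():
            if chems != set(CHEMISTRIES):
                raise ValueError(
                    f"condition {cond!r} must have both BS and OxBS samples, "
                    f"found {sorted(chems)}"
                )

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.condition not in seen:
                seen.append(s.condition)
        return seen

    @classmethod
    def default(
        cls,
        outdir: str | Path,
        reads_per_allele_per_gene: int = 20_000,
        conditions: Sequence[str] = ("control", "IFNg"),
    ) -> "SimManifest":
        """Control/IFNg x BS/OxBS design at the stated per-library coverage."""
        outdir = Path(outdir)
        samples = [
            SimSample(
                name=f"{cond}_{chem}",
                condition=cond,
                chemistry=chem,
                reads_per_allele_per_gene=reads_per_allele_per_gene,
                fastq_path=str(outdir / f"{cond}_{chem}.fastq"),
            )
            for cond in conditions
            for chem in CHEMISTRIES
        ]
        return cls(samples=samples, truth_path=str(outdir / "truth.tsv"))
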
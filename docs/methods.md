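# Methods

## Chemistry model

Each simulated read is drawn per CpG from the three-state truth
(f_C, f_5mC, f_5hmC), summing to 1, and pushed through a parametric
chemistry:

- `conv_rate` (default 0.99): probability an unmodified C converts and
  reads as T. Conversion failures read as C, so both chemistries' %CG
  are inflated by `(1 − conv_rate) · f_C`.
- `ox_rate` (default 0.95): probability a 5hmC is oxidized in the OxBS
  arm (then reads as T). Unoxidized 5hmC reads as C, shifting signal
  from the 5hmC estimate into the 5mC estimate — the 5mC estimate is
  monotone increasing in `1 − ox_rate`, which the tests assert.
- `seq_err` (default 10⁻³): per-base uniform substitution applied after
  chemistry, over the whole read including the stagger.

The per-read probability of reading C at a CpG is therefore

```
BS:   p_C = f_5mC + f_5hmC + f_C·(1 − conv_rate)
OxBS: p_C = f_5mC + f_5hmC·(1 − ox_rate) + f_C·(1 − conv_rate)
```

and the pipeline's %CG estimates are binomial proportions around these.
The kit's true efficiencies are not published; the defaults are
plausible working values and are configurable, not claims. Under *ideal*
chemistry (conv 1, ox 1, err 0) the round-trip is exactly binomial,
which is what the recovery tests exploit: every estimate must sit within
3 binomial SE of truth (SE from the cell's CG+TG count).

Only the bisulfite-converted top strand is simulated and analysed —
primer design for this assay targets one strand, and single-end reads
see only that strand. Non-CpG cytosine methylation is taken as zero
(the mammalian default); PCR bias, indels and paired-end geometry are
out of scope.

## Default panel

Six amplicons (240–280 bp): four X-reactivating promoters (Mtm1 with 3
CpGs, Dlg3, Eda, Zfp185 with 2 each — nine reactivating CpGs) and two
escapee controls (Ddx3x, Eif2s3x, 2 CpGs each). Sequences are synthetic:
random DNA generated CpG-free, with CpGs planted at offsets 70/100/130,
an A(mus)/G(cas) SNP at offset 30, and the first 10 BS-converted bases
as the PCR2 primer. Escapee truth draws f_5mC, f_5hmC ≤ 0.03; the
reactivating genes draw high 5mC on the mus (inactive) allele
(0.5–0.8) and lower on cas (0.05–0.25), with 5hmC up to 0.15. Panel
generation rejects primer sets that could cross-match under the scan
rule, including matches that begin inside the random stagger — this
makes gene demultiplexing exact when sequencing is error-free.

Primer length 10 was chosen so that demultiplexing stays above 99% at
the default 10⁻³ error rate (a substitution anywhere in the primer match
window is the dominant loss mode; the C/T-collapsed comparison forgives
T→C errors).

## Read classification

- **Gene**: exact (C/T-collapsed) primer search in the first
  stagger_max + primer-length bases; multi-gene matches are unassigned.
- **Allele**: the shortest unique CpG-free BS-converted anchor of length
  15–20 ending at the SNP is located in the read (exact substring by
  default; `max_mismatch` is configurable); the next base decides
  mus/cas, anything else — including duplicate anchor hits or a
  truncated read — is ambiguous and excluded.
- **CpG call**: same anchor logic per CpG; the following 2-mer must be
  CG or TG, anything else is "other" and excluded from the %CG
  denominator.
- A read contributes to CpG tallies only if its allele is recoverable
  and at least one CpG call is informative; read accounting
  (classified + ambiguous + unassigned = input) is checked after every
  tally.

Anchor windows must avoid CpG cytosines — otherwise the anchor match
would depend on methylation state. Amplicons whose geometry cannot
satisfy this (CpG within 15 bp of the read start, CpGs closer than an
anchor length, repetitive context breaking uniqueness) are rejected at
reference-building time with the gene and offset named.

## Negative-5hmC rules

The BS-minus-OxBS subtraction can go negative by sampling noise. Per
CpG, across all allele × condition cells present: any raw value below
−1% discards the whole CpG; raw values in (−1, 0)% clamp to 0; the rule
set is idempotent and row-order independent. With condition sets other
than control/IFNγ, "any of the conditions" generalizes to all cells
present. Cells with fewer than 100 informative reads are flagged
low-coverage (real runs of this assay are far deeper; the floor is
plumbing, configurable).

## Allelic expression

Ratios are computed on raw allele-resolved counts — library
normalization cancels in X_mus/(X_mus+X_cas). The informative filter is
strict (cas share **over** 25% in every population) and the NPC cutoff
inclusive (ratio **at or under** 0.135 → reactivating), both read
literally. The pluripotency score is the arithmetic mean over the seven
genes of sample/ESC expression ratios, with the ESC reference averaged
over ESC replicates; arithmetic rather than geometric because the score
is defined as the average of the normalized values. Whether a gene is
protein-coding and X-linked is the input table's responsibility — the
operations are annotation-agnostic, avoiding any gene-model dependency.

The count simulator draws totals from a negative binomial (mean 10,000,
dispersion 10) and mus counts binomially at the gene's true ratio. Gene
categories are engineered to exercise both thresholds: reactivating
genes with NPC ratio ≤ 0.115, escapees ≥ 0.155 (both ≥ 0.02 from the
cutoff), mus-skewed uninformative genes (cas share < 25%), and one
fully silenced gene (ratio exactly 0).

## Arrays

The 5hmC direction is β_BS − β_OxBS everywhere, forced by the
chemistry: 5hmC reads methylated in BS and unmethylated in OxBS, so
BS ≥ OxBS in expectation. Probe QC removes a probe that fails intensity
(<1000) or detection p (>0.01) in **any** sample; a per-sample mode is
available behind a flag. Negative β_5hmC values are retained — the
array workflow defines no clamp. The built-in per-probe test is a Welch
two-sample t test (the original workflow used a moderated test with
batch correction, which is out of scope; the DMP filter consumes
p-values from any source). Benjamini–Hochberg adjusted p-values are
reported alongside, but selection follows the raw p < 0.01 rule. The
simulator adds truncated-normal noise (default SD 0.03; 0.05 in the
shift-recovery setting) to β_BS ≈ f_5mC + f_5hmC and β_OxBS ≈ f_5mC,
with f_5mC in 0.2–0.6 so clipping at the [0, 1] bounds is negligible.

## Screen filters

Pure row filters over gene-summary tables; the rank-aggregation scoring
that produces them is upstream and not reimplemented. Depleted-direction
filters use the negative-score column when present, falling back to a
single score column. Ties at rank 250 break by gene name so the top-N
selection is deterministic. The simulator plants per-comparison
enriched/depleted hits plus a shared essential set so the intersection
filter has a non-trivial answer.

## Problem sizes and numerical choices

The test suite runs the default panel at 2,000 reads/allele/library for
routine checks and 20,000 (single condition) for the full-coverage
round-trip; the demo default is 4,000. These sizes put binomial SEs well
below the effect sizes being asserted while keeping the whole suite in
tens of seconds. All randomness flows from `numpy.random.default_rng`
seeded per run (per-sample streams spawned via `SeedSequence`), so
simulation outputs are byte-identical across reruns of the same seed;
TSV output uses a fixed float format for the same reason. Statistical
assertions use 3·SE bands (≈0.3% two-sided tail per cell); where many
cells are checked at routine coverage the tests assert the within-3SE
fraction rather than every cell, and the strict every-cell check runs at
full coverage.

## What the simulations do and do not show

Passing tests demonstrate that the implementation recovers what the
generators encode: binomial read sampling around the stated chemistry,
independent CpGs, uniform sequencing error, normal array noise, and
threshold-respecting screen tables. Real data add PCR amplification
bias, strand and fragment effects, correlated CpGs, batch structure and
alignment artifacts that these generators deliberately omit — results
here validate the arithmetic and the rule semantics, not robustness to
those effects.
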
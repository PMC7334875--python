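# Methods

## Scope and model overview

`cropmap` covers the computational arc of an expression CROP-seq screen:
guide design against candidate eSNPs, construction of the guide-detection
reference, simulation of the pooled screen, guide-to-cell assignment,
expression QC/normalization, per-eSNP association testing, and
screen-level statistics. Read alignment and UMI counting are out of
scope — the package consumes (or simulates) the cell×feature count matrix
a 10x-style counter emits.

## Guide design

Candidate protospacers are every 19-mer immediately 5′ of an NGG PAM on
either strand of the SNP's flanking window. Conventions:

- **Cut site.** SpCas9 cuts bluntly 3 bp 5′ of the PAM; the reported
  `cut_pos` is the 1-based plus-strand coordinate of the protospacer base
  immediately 3′ of the cut (for a plus-strand guide with PAM starting at
  g, `cut_pos = g − 3`). The guide chosen for a SNP minimizes
  |cut_pos − SNP|, with ties broken to the lexicographically smallest
  protospacer so selection is deterministic.
- **Filters.** GC fraction within [0.40, 0.80] inclusive; exactly one
  perfect genomic match of protospacer+NGG (PAM N wildcarded, both
  strands, overlaps counted). Off-target risk is handled by this
  exact-match uniqueness count — a reproducible, dependency-free
  criterion — rather than a scored prediction model; `max_snp_distance`
  (default 10) is a descriptive guideline, not a hard filter, since a
  slightly more distant cut can still delete the SNP.
- **Coordinates.** 1-based inclusive externally (dbSNP convention);
  0-based offsets internally. Windows containing N are skipped, not
  errored.

## Guide-detection reference

Each guide becomes a 530-bp artificial chromosome: 241-bp U6 promoter,
8-bp gap, 20-bp guide (19-nt designs are left-padded with the
conventional U6 transcription-start G), 261-bp backbone. The shipped
U6/gap/backbone contents are deterministic *synthetic* stand-ins of the
correct lengths — segment lengths, not content, drive detection
geometry — and are replaceable via `ConstructSpec`. Each chromosome is
annotated as one single-exon protein-coding-style gene spanning 1..530 so
downstream counters attribute guide UMIs to a gene-like feature.

## The synthetic screen generator

The generator is first-class, tested code; its defaults are the study
conditions everything downstream is validated under.

**Library.** 67 guides: 57 candidate eSNPs across three loci (CISD1 20,
PARK7 19, DAP 18, each with adjacent control genes — IPMK/UBE2D1, ERRFI1,
ANKRD33B), plus 5 positive controls in essential genes (TUBB, RUNX1),
3 non-targeting negatives, and 2 non-SNP controls (the fixture rounds out the usual 5 positive + 3 negative +
1 non-SNP controls with a second non-SNP control to reach an even 10). Two candidate guides are causal by default:
one CISD1 eSNP at the nominal effect size and one PARK7 eSNP at 3× —
mirroring a screen in which one locus shows a far larger shift.

**Uptake.** Integrations per cell are zero-truncated Poisson(λ = `moi`,
default 0.5): puromycin selection removes unguided cells, so zero-guide
cells in the matrix arise only from detection dropout (default 0.05 per
integrated guide). The pre-selection zero count is recorded (drawn as
NegativeBinomial(n_cells, 1−e^−λ), the exact law of interleaved zero
cells), which lets `estimate_moi = −ln f₀` be validated against truth.
Guide identities are sampled per cell *without replacement*
(Gumbel-top-k weighted sampling): with replacement, duplicate
integrations of one guide would blur the detected-multiplicity law;
without it, detected multiplicity is exactly ZTP composed with binomial
thinning, which the tests verify by chi-square goodness of fit.

**Editing outcomes.** For a cell's first-drawn targeting guide:
P(≥1 edited allele) = 0.92; among edited cells P(single allele) = 0.29;
P(edit disrupts the SNP) = 0.67. These match deep sequencing of edited
single-cell clones. Editing states are per cell, not per clonal lineage.

**Expression.** Gene UMIs are negative binomial (inverse-dispersion
r = 10, var = μ + μ²/r) with per-cell depth log-normal around the
geometric mean of the 2000–7000 UMI range (σ = 0.17, so realized totals
concentrate inside the QC window). The default panel is 250 background
genes (log-normal means, median ~8 UMIs), the target/adjacent/essential
genes at fixed moderate means, and 13 MT- pseudo-genes holding 8% of
counts in expectation.

**Cis effects.** For cells whose causal guide *disrupted* its SNP, the
target gene's NB mean is multiplied by a factor f < 1 calibrated
numerically (exact NB moments + Brent root-finding at the reference
depth) so the expected normalized log2 expression drops by `effect_sd`
baseline SDs (default 0.5). Because only
p_edit·p_disrupt ≈ 62% of guide-carrying cells are disrupted, the
*observable* group shift is ≈0.31 SD — this dilution is the biologically
faithful behavior and drives the power arithmetic below. An `effect_sd`
too large for any f ∈ (0,1] raises a calibration error.

**Extras.** Plasmid-pool DNA reads are multinomial over `guide_probs`
(default uniform, 500k reads). `essential_survival` < 1 removes a
fraction of cells carrying positive-control guides after uptake,
emulating essential-gene dropout for the depletion test. All randomness
flows from one `numpy` Generator seeded by `SimParams.seed`; identical
seeds give byte-identical MTX output.

**What the generator does not emulate:** ambient RNA, doublets, clonal
structure, batch effects beyond replicate seeds, read-level artifacts,
or guide-specific editing efficiencies. Passing tests therefore show the
pipeline is calibrated and powered under a clean generative model, not
that real screens are free of those confounders.

## Assignment, QC, normalization

Assignment binarizes guide UMIs at count > 0 (an optional `min_umi`
exists for noisier data but the literal >0 rule is the default); only
single-guide cells enter association testing. QC applies, in order:
drop cells expressing <200 genes (strict); drop genes detected in <6
cells (guides exempt); keep cells with 2000–7000 total gene UMIs
(read as inclusive bounds — the prose "between" is ambiguous); keep
cells with mitochondrial fraction strictly <25%. Because the gene filter
runs before the UMI/mito filters, re-running QC on its own output can
cascade (a removed cell may strand a gene below 6 supporters); this is
by construction and tested. Guide features never enter gene filters or
cell totals, so guide abundance cannot perturb normalization.
Normalization is x → log2(1 + 10000·x/total) per cell; the +1
pseudocount (applied after scaling) is required by zeros and is the
dominant convention; consequently Σ(2^v − 1) = 10000 exactly per cell.

## Association testing

OLS of normalized expression on the guide indicator over kept cells,
implemented by explicit linear algebra; β equals the group-mean
difference and its slope t-test is numerically identical to the pooled
two-sample t-test (asserted to 1e-10 against an independent
implementation). The comparison group is all other single-guide cells by
default (an option restricts to negative-control cells for sensitivity
analysis). Each locus's tests share the Bonferroni-adjusted critical
value α/tests_per_locus = 0.05/20 = 0.0025; the divisor stays 20
regardless of the exact candidate count per locus (19 or 18), matching
the screen's fixed gene-wise budget. Adjacent genes are tested per
candidate guide as negative controls. Covariates (cell cycle, depth) are
deliberately excluded — the simplest model is reported — though the
code accepts a restricted comparison group as the one sensitivity hook.
Degenerate cases: zero-variance expression gives β = 0, p = 1; groups
with <2 cells are flagged untestable rather than propagating NaN. Hits
require significance in both replicates.

## Screen statistics

- **Representation/depletion.** Per-guide DNA (plasmid reads) and RNA
  (assigned cells) fractions and their log2 ratio (zero counts flagged,
  never ±inf). The depletion test is an exact two-sided binomial test of
  each guide's cell count against Binomial(total cells, DNA fraction),
  Bonferroni-corrected over guides. Exact binomial p-values are discrete
  and mildly conservative at small per-guide counts; the uniformity
  check in the acceptance suite runs at ~1000 cells/guide where the
  discrete null law is close to uniform.
- **Effect-size conversion.** Under the standard additive eQTL model
  with unit phenotype variance, PVE = 2p(1−p)β² with β = δ (monoallelic
  disruption) or δ/2 (biallelic). A δ = 0.5 SD shift reaches 5–10% PVE
  over plausible allele frequencies; PVE is maximized at p = 0.5.
- **Power.** Two-sided pooled t-test power from the noncentral t with
  ncp = δ·sqrt(n₁n₀/(n₁+n₀)). With the ~62% disruption dilution, a
  0.5-SD effect needs ≈300 cells on the guide for ~99% per-replicate
  power at the 0.0025 threshold; at ~90 cells per guide power is ~45%,
  which is why the default-depth worked example replicates only the 3×
  effect.
- **qPCR.** 2^−ΔΔCt with arithmetic-mean reference-gene Cts and
  control-sample ΔCts.
- **Peak overlap.** BED intervals are 0-based half-open; a SNP at
  1-based pos overlaps [start, end) iff start ≤ pos−1 < end (interval
  tree lookup, verified against a naive scan).

## Problem sizes in the test suite

Monte-Carlo calibration suites use a reduced 40-gene background panel
with the minimum-expressed-genes QC threshold scaled to the panel (its
absolute default is only meaningful at transcriptome scale); type-I
calibration runs 200 null screens at ~150 kept cells/guide, and the
replication-power suite runs 100 two-replicate studies sized at ~370
kept cells/guide from the power analysis above. Editing-outcome and MOI
checks use 10,000–50,000 cells with a minimal gene panel, since those
quantities do not depend on expression.

## Known limitations

- Exact-match uniqueness is a crude off-target proxy; no CFD/MIT-style
  scoring.
- The t-test on log-normalized counts ignores count noise structure
  (no NB GLM or resampling-calibrated alternative) — adequate at these
  depths, as the type-I suite shows, but not guaranteed for very lowly
  expressed genes.
- MOI estimation from detected guides (rather than pre-selection truth)
  is biased downward by detection dropout; the CLI labels it
  accordingly.
- The simulator's editing truth attaches to a cell's first targeting
  guide only; multi-guide cells are excluded from analysis anyway.
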
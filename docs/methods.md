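# Methods

This note documents the statistical procedures implemented in `gmscreen`,
the choices made where the underlying assay conventions leave the design
open, and what the synthetic-data generators do and do not emulate.

## Rare-variant burden shortlisting

A gene enters the shortlist when, across the cohort, it carries at least
one truncating variant (nonsense or frameshift) and at least one missense
variant, after removing variants with population allele frequency
strictly greater than 1% (`af_max = 0.01`; a variant at exactly 1% is
kept, reading "greater than 1% excluded" literally).  Counting is
cohort-wide — the qualifying variant classes need not co-occur in one
patient — with a `per_patient` mode for the stricter reading.  Missing
allele frequencies are treated as 0 (absence from population databases is
what "rare" usually means in this setting); a `missing_af="drop"` mode
discards them instead.  When positional columns are present, the same
physical variant observed in several patients counts once toward the
burden.  Synonymous and other consequences never contribute.

## QIBC gating

The imaging platform's positivity cutoffs are vendor-software settings
that are not portable, so the package derives thresholds from each
plate's negative-control cells: mean + 2 SD by default, or a control
percentile (95th) — both per plate and per channel, requiring ≥ 100
control cells (otherwise the plate fails QC; nothing is imputed).  A cell
is positive when its value is *strictly* above the threshold, so a
zero-variance control well reads 0% positive.  Micronucleus positivity is
`count ≥ 1` and needs no threshold.

Cell-cycle gating follows flow-cytometry convention on the two QIBC
channels: EdU-high cells are S phase regardless of DNA content; among
EdU-negative cells the total-DAPI distribution is split at the density
valley between its 2n and 4n modes (G1 below, G2 at or above).  Both
splits derive from a Gaussian-KDE mode search on log intensity; a
distribution whose two top modes are not separated by a valley deeper
than 80% of the smaller mode is declared degenerate (unimodal) and fails
QC rather than being gated arbitrarily.  Explicit split values can be
supplied to override either estimate.

Two scalar normalizations support the orthogonal validation assays:
relative HR efficiency = GFP⁺ fraction of the sample over the control
(control ≡ 1), and qPCR relative expression = 2^(−ΔΔCt) with
ΔΔCt = (Ct_target − Ct_ref)_sample − (Ct_target − Ct_ref)_control.

## Screen scoring

Each readout (marker × cell line) is scored independently:

* **Normalization.** Each well's % positive is divided by the median of
  same-plate negative-control wells, removing multiplicative plate bias.
  A plate whose control median is zero cannot be scaled and falls back to
  additive centering, with a warning and a flag — never silently.
* **z-score.** The gene-level raw score X is the unweighted mean over the
  gene's (three) siRNA wells; z = (X − μ)/σ with μ and σ the mean and
  *population* (÷N) standard deviation over all genes in the readout,
  matching the convention of standardizing against "the population".
  Sample-SD and per-siRNA variants are available as options.
* **SSMD.** Method-of-moments: (mean_gene − mean_control) /
  √(var_gene + var_control) with sample variances.  Both variances zero
  yields 0 for equal means and a signed-infinity sentinel otherwise.
* **Significance.** The assay convention does not name a test; a
  one-sided Welch t of the gene's wells against the readout's
  negative-control wells was chosen (the screen looks for *elevated*
  γH2AX/micronuclei), with a permutation test as an alternative.  A gene
  scores in a readout when p < α (0.05) **and** z ≥ 2; the z-gate keeps
  single-readout noise from propagating into the consensus.  No multiple
  testing correction is applied by default (raw p-values are reported);
  per-readout Benjamini–Hochberg is available behind a flag.
* **Consensus.** A gene is a hit when it scores in ≥ 3 of the 4 readouts
  (`min_readouts` configurable; output ordered by number of significant
  readouts, ties broken by gene name).

## CRISPR-Select-TIME fitness

Reads are assigned to {variant, WT′, other} by exact match of the
diagnostic motif at a declared 0-based offset.  A mismatch-tolerance mode
forgives substitutions *outside* the positions that discriminate the two
motifs — the discriminating bases must always match exactly, so sequencing
errors can never convert one allele into the other.  Reverse-complement
scanning is off by default.

With early and late counts (a, c) and (b, d) for (variant, WT′):

* FC = (b/d)/(a/c); a Haldane–Anscombe pseudocount of 0.5 is added to all
  four cells only when some cell is zero;
* s = ln(FC)/Δt is the per-day selection coefficient (the variant lineage
  is modelled as exp(s·t) against the neutral WT′ internal control);
* SE(ln FC) = √(1/a + 1/b + 1/c + 1/d); 95% Wald intervals on s;
* p is a two-sided Fisher exact test on the raw 2×2 table;
* classification: depleted (FC < 1, p < α), enriched (FC > 1, p < α),
  else neutral.

Replicates are combined by fixed-effect inverse-variance weighting of
ln FC (no random-effects model; replicate counts are small by design).

The two-sided Fisher p is computed in-package by enumerating the
hypergeometric support of a margin class once and summing the
probabilities not exceeding that of the observed table.  The pmf uses the
betaln identity (scipy.special); two pmf values are treated as tied when
they agree within `total × 1e-14` relative — the gate scales with the
table total because the log-factorial cancellation loses precision
linearly in the magnitude of the terms, while mathematically distinct pmf
ratios in a margin class are never that close to 1.  A table whose pmf
ties the modal pmf has p = 1.  This per-class vectorization makes
exhaustive verification over all small tables practical; the test suite
checks it against `scipy.stats.fisher_exact` on random tables and against
exact integer-arithmetic enumeration on the full grid of tables with
total ≤ 200.

## Multi-omic classification

Per gene, independently: deficient iff (pathogenic germline or somatic
variant AND GISTIC −1) OR GISTIC −2; BRCA1 additionally via methylation
β ≥ 0.25 AND expression z ≤ −2.  Missing methylation or expression never
triggers a call (conservative labelling).  Dual-deficient patients carry
both labels.  Expression groups partition z at ±2 with both boundaries
inclusive on the extreme sides; receptor flags (ER⁺, HER2⁻,
triple-negative) are non-exclusive, and a missing IHC field blocks only
the flags that need it.  Pathogenicity booleans and GISTIC calls are
upstream annotations consumed as inputs.

## Synthetic-data generators

The generators produce the statistical structure the analysis assumes,
with a machine-readable truth manifest; all randomness flows through one
seeded `numpy.random.Generator`, so outputs are bit-identical per seed.

* **Screen** — default design: 3 siRNAs/gene, four readouts (γH2AX and
  micronuclei in U2OS and MCF10A), 2,000 cells/well, 40 genes + 16
  negative-control wells per plate.  Marker intensity is a two-component
  lognormal mixture whose weight is the planted positive fraction
  (components separated by ~9 SDs, so control-derived thresholds recover
  the weight to well under binomial error); micronucleus counts are
  Poisson with P(≥1) equal to the planted fraction; DNA content is a
  2n/4n lognormal pair (60/25/15 G1/S/G2) with S cells spread between and
  EdU-high.  Hits raise the positive fraction by `hit_effect` (0.25)
  scaled by a per-siRNA knockdown efficiency drawn uniformly from
  (0.6, 0.9); plate bias acts multiplicatively on the fraction (SD 0.05
  on the log scale).  The effect size of a knockdown on % positive cells
  is not something the assay literature pins down; the default was chosen
  once as a realistic strong-hit effect and is a parameter, not a claim.
* **Variant cohort** — per-gene composition (counts of rare truncating /
  missense / other and common variants) either supplied or drawn;
  rare AFs log-uniform in [1e-4, 1e-2], common in (0.011, 0.2); the
  manifest lists exactly the genes whose rare composition satisfies the
  burden rule.
* **Amplicon** — knock-in fractions 0.10/0.10 (variant/WT′, "similar
  frequencies" by assay design), sampling at days 2 and 12, depth 5,000
  reads/timepoint; the variant lineage changes deterministically as
  exp(s·day) and reads are drawn multinomially.  FASTQ mode plants the
  diagnostic motifs in a fixed random template and applies uniform
  substitution errors; with error rate 0 the counts round-trip exactly.
* **Omics** — mechanism mix defaults to a few percent deficient per gene,
  as in large sporadic cohorts; planted fields are constructed to satisfy
  (or, for intact patients with decoy lesions, to fail) the classifier's
  rules, with patients pinned exactly at the β = 0.25 / z = ±2
  boundaries.

What the generators do **not** emulate: pixel-level imaging (features
only), spatial plate artifacts (positions are assumed randomized, as in
the screened library), cell-to-cell correlation within wells, sequencing
error structure beyond uniform substitution, indels, and correlated
multi-omic noise.  Passing tests therefore demonstrate correctness of the
statistical chain under its own assumptions, not robustness to every
real-data pathology.

## Problem sizes and numerical choices

The test suite and acceptance script use trimmed problem sizes chosen as
comfortable for routine runs: simulated screens use 200 genes at 400
cells/well (effect sizes and all rates at their defaults; binomial noise
at 400 cells/well is already far below the planted effects), fitness
recovery uses 1,000 replicates at depth 5,000, classifier checks use
10,000 patients, and the Fisher grid check enumerates all tables with
total ≤ 200.  Degenerate inputs (zero-variance wells, empty wells,
unimodal DAPI, zero control medians, zero allele counts) fail loudly or
are flagged, never silently imputed.  Well exclusion reasons propagate as
QC flags; ordering ties break lexicographically by gene.
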
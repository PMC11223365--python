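# Methods

## Genotype model and quality control

The pipeline reads exactly two sites from a VCF, located by
chromosome/position/alleles as declared in a `LocusSpec` pair: the c.261
single-base deletion (matched by its left-aligned indel representation, no
re-normalisation) and the c.802 G>A substitution. A call is *valid* when
DP ≥ 9 and GQ ≥ 20; heterozygotes additionally require at least 3 reads on
**each** observed allele — the ambiguous "allele depth ≥ 3" convention is
resolved conservatively as `min(AD_ref, AD_alt) ≥ 3`. Missing FORMAT
subfields (e.g. `GQ=.`) fail QC rather than defaulting; in multiallelic
records only the configured ref/alt pair is interpreted and any genotype
touching another allele is treated as missing. QC failure is a state, not
an error: such samples are excluded from frequency estimation and receive a
`missing` blood type, mirroring how cohort members failing ABO-locus
sequencing are excluded rather than defaulted to non-O.

## Haplotype frequencies and phase

With two biallelic sites the nine possible two-locus genotypes are phase
deterministic except for the double heterozygote, so the haplotype
frequency likelihood is an explicit multinomial under Hardy–Weinberg
equilibrium and the classical gene-counting EM is its exact maximiser.
This replaces population-scale HMM phasing (Shapeit) by design: the
downstream logic needs only the two-locus diplotype, and the EM removes an
external binary while solving the same estimation problem exactly. Every
report TSV carries a header line flagging the substitution.

* Initialisation: the product of observed allele frequencies (linkage
  equilibrium), floored at 1e-6 to stay strictly positive.
* Convergence: max absolute frequency change < 1e-8 (default), cap 1000
  iterations; the log-likelihood is asserted non-decreasing.
* Determinism: no randomness anywhere in the EM.
* Known degeneracy: a cohort of only double heterozygotes is
  unidentifiable (cis/trans exchangeable); the EM then returns its starting
  point. This is reported, not resolved.

Per-individual phase: `P(cis) ∝ 2·f(ref,ref)·f(alt,alt)` versus
`P(trans) ∝ 2·f(ref,alt)·f(alt,ref)`; if both products vanish the
posterior falls back to 0.5/0.5 with a logged warning.

An independent oracle, `grid_search_frequencies`, maximises the same
likelihood by direct scan. The full 0.001-step lattice of the 4-frequency
simplex has ~1.7×10⁸ points, so the scan is hierarchical: exhaustive at
step 0.01 globally, then exhaustive at step 0.001 within one coarse step of
the coarse optimum. For generic genotype counts the likelihood is unimodal
in the interior, so the refinement loses nothing; the oracle shares no code
path with the EM beyond the cell-probability table.

## Blood-type calls

Haplotype → allele class: deletion present ⇒ deletional O (the frameshift
dominates a co-occurring c.802A, a combination the typing rules do not
otherwise cover); c.802A alone ⇒ nondeletional O; neither ⇒ non-O. A
configuration types as O iff both haplotypes are O-class; the reported type
is that of the maximum-probability configuration and the reported posterior
is the summed probability of configurations sharing that type. Calls are
hard by default (`--min-call-posterior 0`), with the posterior retained so
contingency stages can filter.

## Association statistics

* χ² of independence, no continuity correction (the omnibus df = 4 use on
  the subtype table; 2×2 tables also uncorrected by default, `--yates`
  available). Zero expected cells raise an error instructing category
  collapse.
* Row percentages round half-up to 2 dp, matching printed-table formatting.
* Odds ratios: ad/bc with Woolf log-method 95% CI; any zero cell triggers
  the Haldane–Anscombe +0.5 on all four cells.
* Wilcoxon rank-sum: midranks for ties; for min(n) < 20 the p-value is the
  exact permutation enumeration (two-sided as twice the smaller tail,
  capped at 1); otherwise the normal approximation with tie correction and
  continuity correction. Identical constant data across both groups gives
  p = 1 by convention.
* Cohort arithmetic: total − sequencing failures − TIA = ischaemic-stroke
  cohort; minus prior-stroke = first-ever subset.
* No multiplicity adjustment across baseline variables by default (raw
  p-values are the convention for such tables); `bh=True` appends
  Benjamini–Hochberg q-values. Missing biomarker values are deleted
  pairwise per variable.

A calibration caveat found while validating: resampling the published
subtype multinomials at n = 9,542 gives a noncentral χ²(4) with λ ≈ 27,
which exceeds the α = 1e-4 critical value (23.5) only ~72% of the time.
The power check therefore asserts what the effect actually supports —
near-certain rejection at α = 0.05 and a resampled median p below 1e-4 —
rather than a high-probability rejection at 1e-4 itself.

## Proteomics

Zeros are imputed with half the per-protein minimum positive intensity,
then everything runs on log2 intensities. The per-protein test is Welch's
two-sample t (unequal variances — the safer default where only "t test" is
specified; a pooled-variance flag exists). log2FC is mean(O) − mean(non-O).
The volcano rule is the literal reading |log2FC| > 1.2 with p < 0.05;
`fc_scale="linear"` switches the threshold to |FC| > 1.2, i.e.
|log2FC| > log2 1.2 — both are exposed because the published up/down counts
cannot arbitrate the reading without raw data. Proteins constant in both
groups have undefined p and are flagged not-significant.

ORA: hypergeometric upper tail P(X ≥ k) per term after intersecting term
sets with the background (all detected proteins); terms with intersection
< 3 are skipped; Benjamini–Hochberg q across tested terms with q < 0.05
significance. BH is used rather than a Storey-type estimator because it is
deterministic and parameter-free. Term sets travel as GMT files;
enrichment can be run on the up set, the down set, or both jointly.

## Assay calculators

Efflux % = 100·FI_medium/(FI_medium + FI_lysate), per replicate, then
averaged over replicates (not efflux of summed fluorescence). An optional
blank is subtracted from both compartments before the ratio; background
subtraction is otherwise not modelled because no blank readings are
published. Relative expression = 2^−ΔΔCt with ΔCt = Ct_target − Ct_GAPDH
averaged within group; Ct values are validated to (0, 45) cycles. Percent
change reports increases as negative reductions.

## Synthetic data

The generator provides every input with ground truth:

* **Genotypes** — haplotype pairs drawn iid from the configured
  frequencies (HWE). Defaults (f_GG = 0.4565, f_GA = 0.06,
  f_delG = 0.48, f_delA = 0.0035) put the total O-allele frequency at
  0.5435, so the O-genotype fraction is 0.5435² ≈ 0.2954, the cohort's O
  prevalence. Reads: depth ~ Poisson(60), per-read error 0.5%, alt reads
  binomial; the genotype call is the maximum-likelihood diploid genotype
  under that error model and GQ is the phred-scaled likelihood ratio to
  the runner-up, capped at 99. The error model is invented plumbing,
  parameterised so depth 60 yields <0.1% miscalls while lowering depth
  probes QC behaviour. Output is a real VCF plus a truth table.
* **Cohort labels** — subtype from blood-type-conditional multinomials
  whose defaults are the published row proportions; LDL-C log-normal
  (σ_log = 0.42 from the printed IQR shape) with a +0.043 log-location
  excess in non-O (the printed 2.3 vs 2.4 mmol/L medians); CRP as a null
  biomarker. Biomarker medians are not reproduction targets.
* **Proteome** — 974 proteins, 59 planted effects (17 up / 42 down as a
  profile template, not a reproduction target), |log2FC| = 2, σ = 0.5 in
  log2 space, 30 samples per group. The GMT map holds one term enriched
  3-fold for planted proteins — built deterministically as exactly
  round(3·(59/974)·80) planted members of an 80-protein term — among 20
  random decoy terms of size 30–100; the sizes were fixed a priori from a
  hypergeometric power argument (expected overlap ≈ 15 against a null mean
  of ≈ 4.9).

All randomness flows from one seed; identical configs give byte-identical
files. What the simulations do *not* emulate: linkage with flanking
markers, reference-panel structure, batch effects, missing-at-random
proteomic dropout beyond zeros, or peak-level mass-spectrometry noise — so
passing tests certify the inference machinery, not robustness to those
real-data pathologies.

## Problem sizes

The validation metrics run at: EM-vs-grid on 200 samples; typing accuracy
on 20 seeds × 1,000 samples at 60× depth; calibration on 2,000 null
simulations (n = 500 cohorts; 30 + 30 rank-sum); DE recovery on 10 seeds
and enrichment ranking on 100 seeds at the default proteome profile.
These sizes make the whole reproduction run in seconds while keeping
Monte-Carlo error well inside the asserted bands.

## Known limitations

* O sub-alleles not tagged by the two markers (rare O variants) type as
  non-O; A/B/AB sub-typing is out of scope.
* The EM assumes Hardy–Weinberg; strong inbreeding or population structure
  would bias the cis/trans split for double heterozygotes.
* The published protein counts (17 up / 42 down), biomarker medians, and
  healthy-control blood-type split depend on unreleased raw data and are
  deliberately not asserted anywhere; the suites assert the machinery on
  synthetic truth instead.
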
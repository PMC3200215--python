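# Methods

## The quantification model

Each protein is analyzed separately on quantile-normalized log2 intensities
rolled up from its peptides (unweighted mean of the peptides present in an
injection). The model is a two-level nested ANOVA

    log2(intensity)_{g s r} = mu + alpha_g + b_{s(g)} + e_{s r}

with `g` the treatment group (case/control), `b_{s(g)} ~ N(0, sigma_s^2)` a
random effect of biological sample nested in group, and
`e ~ N(0, sigma_e^2)` replicate (injection-level) noise. With a balanced
replicate structure — every sample injected `r` times — the fit uses
expected mean squares:

- `F = MS_group / MS_sample(group)` on `(1, N_samples - 2)` degrees of
  freedom. Testing against the sample stratum (not the residual) is what
  distinguishes this from a naive ANOVA: biological replication, not
  injection replication, carries the inference.
- `sigma_e^2 = MS_rep`, `sigma_s^2 = max(0, (MS_sample - MS_rep) / r)`
  (negative estimates truncated at zero).
- With `r = 1` the model collapses to a one-way ANOVA on sample means, which
  is exactly the squared pooled two-sample t-test. Unbalanced replicate
  counts are first collapsed to per-sample means: this keeps the group test
  exact at the cost of the replicate variance component, and avoids the
  need for REML on data this small.

Degenerate inputs: a protein whose values are constant (which happens to
rank-locked features after quantile normalization, see below) reports
p = 1; genuinely zero sample-level variance with a nonzero group difference
(the noise-free limit) reports p = 0 with a warning. The boundary between
the two is scale-aware (`1e-12 · max(1, grand_mean²)`) because constant
data leave rounding residue of order 1e-29 in the sums of squares.

Group differences are back-transformed to signed fold-changes
(`2^d` if ≥ 1, else `-2^{-d}`), p-values adjusted by Benjamini–Hochberg
(via statsmodels), and a protein is called significant when `q < 0.05` and
`|fold-change| >= 1.3`. Both thresholds are configurable.

## Normalization

Intensities are log2-transformed, then quantile-normalized per injection:
each column is sorted, each rank replaced by the across-column mean of that
rank, and the order restored. Ties receive the mean of the reference values
at the tied ranks. Missing cells are excluded from ranking; a column with
missing cells has its empirical quantiles interpolated onto the reference
distribution built from complete rows. This preserves the
identical-distribution contract without imputing values.

Two properties worth knowing:

- **Idempotence** holds exactly for tie-free matrices. With ties across
  columns, tie-group averaging perturbs the reference on a second pass, so
  idempotence is only approximate.
- **Effect attenuation.** Quantile normalization assumes the column
  distributions are equal up to technical variation. Features that truly
  change violate this: their rank displacement transfers a small part of
  the effect onto neighboring features and attenuates their own. In the
  noise-free limit the distortion is total — ranks are identical in every
  column, so normalization maps case and control columns onto the same
  reference and erases the group effect entirely. Exact noise-free
  recovery of fold-changes is therefore a property of the
  log2 → roll-up → ANOVA chain, not of the chain including quantile
  normalization; with realistic noise the attenuation is small (recovery
  bias on the order of 0.01–0.03 log2 units per dataset, zero-mean across
  datasets) but it correlates the errors of all proteins within one
  dataset. Calibration claims about the mean recovery error are therefore
  evaluated across replicate simulated studies with a between-dataset
  standard error, not within one study.

## Feature alignment

Peaks are matched across runs only when all four criteria hold: |Δm/z| ≤
0.5 Th (unit-resolution ion-trap default), equal charge, fragment-fingerprint
cosine ≥ 0.7 over 0.5-Th presence bins, and |ΔRT| ≤ 1.0 min after shift
correction. The RT correction is a single global shift per run — the median
RT difference over mutual-nearest m/z+charge anchor pairs — which is
sufficient for the windowed-matching contract at desk scale; no LOWESS/DTW
warping is attempted. Matching is greedy in descending peak area with
deterministic tie-breaks (ascending m/z, then run id), so the output is
invariant to input ordering. Unmatched observations become singleton
groups. Peak areas are trapezoidal integrals of the trace.

## Synthetic data

The generator emulates what the analysis assumes: lognormal raw
intensities, i.e. Gaussian log2 values

    baseline_i + offset_ij + delta_i·I(case) + b_s + e_sr

with protein baselines `N(22, 2)` log2 units (a wide, realistic LC/MS
dynamic range), peptide offsets `N(0, 0.5)` drawn once per peptide,
uniform-random peptide counts of 1–4 per protein (so both priority classes
arise), identification confidences uniform on [90, 100], 8 case and
5 control samples with 2 replicate injections each, 10 % of proteins
changed by ±log2(1.5) with random sign, and a constant spike-in protein
(`delta = 0`) appended to every dataset. Missingness is completely at
random by default; an intensity-dependent mode exists behind a flag but is
off because the modelled study does not describe its missingness.

Noise defaults are back-solved from the modelled study's median
coefficients of variation using the lognormal identity
`sd_log2 = sqrt(ln(1 + CV²)) / ln 2`: replicate %CV 11.97 → σ_e = 0.1721,
replicate+sample %CV 19.16 → total 0.2739 → σ_s = 0.2131. Two caveats: the
printed medians are protein-level, while these σ are applied per peptide
cell, so multi-peptide roll-up deflates the emergent protein-level CVs;
and a sample sd estimated from r = 2 replicates is biased low (factor
≈ 0.80), so the measured peptide-level median replicate %CV of a simulated
study lands near 9.3 rather than 12. Neither bias affects inference; they
affect only the descriptive %CV columns.

The per-sample effect `b_s` is drawn once per sample and shared by all
proteins, mimicking global handling/loading variation — which is exactly
the variation quantile normalization removes. Features of real data the
generator does not emulate: correlated peptide ionization efficiencies,
intensity-dependent variance, chromatographic tailing, isotope envelopes,
and interference. Passing tests therefore demonstrate correctness of the
computations under the stated model, not robustness to everything real
data do.

Feature runs for the alignment stage place one feature per peptide at
random m/z (400–1200 Th, charge 2–3) and RT (10–140 min), apply uniform
m/z/RT jitter and a per-run global RT shift, and emit symmetric triangular
peak traces whose trapezoidal area equals the intended intensity exactly.

## Biomarker panels

The discriminant is Fisher's: `w = (S + λI)^{-1}(m_case − m_control)` with
pooled within-class covariance `S` and ridge `λ = 1e-3·trace(S)/p`. The
ridge matters: the modelled design feeds 13 candidate proteins to 13
samples, where `S` is singular. The decision threshold is the midpoint of
the projected class means shifted by the log prior odds (priors
proportional to class sizes, 8:5); a score exactly at the threshold goes
to the control class. "Fewest proteins with best discrimination" is
operationalized as greedy forward selection on the leave-one-out
misclassification count, stopping at zero errors or when no addition
improves; ties prefer the larger standardized projected margin, then
lexicographic accession. Selection is deterministic.

## MRM assay arithmetic

Precursor m/z is `(Σ residues + water + z·proton)/z`; y/b fragment m/z
follow the standard suffix/prefix rules (pyteomics supplies the masses).
Average masses are the default for precursors when validating against the
modelled study's printed assay (its precursor column matches average
masses), monoisotopic for products. Cysteines can carry the fixed
ethanolyl modification (+44.0262 Da) introduced by 2-iodoethanol
alkylation during sample preparation; the printed Cys-containing
transitions reconcile only with this modification applied, so the packaged
assay fixture flags them. Collision energies are the charge-specific
linear calibrations `0.05·(m/z) + 8` (2+) and `0.044·(m/z) + 8` (3+);
declustering potential is fixed at 100 V and dwell times at 25 ms within
the instrument's 20–30 ms range. Relative quantification averages
transition AUCs per peptide and sample, takes group differences on the
log2 scale, and averages peptides' *signed fold-changes* per protein (the
two scales differ; the signed scale is what the modelled study reports).
Proteins with no usable transitions are reported as not-detected rather
than failing the run.

## Problem sizes and numerical choices

Simulation-based checks run at 500 proteins (≈ 1 250 peptide features,
26 injections), five replicate datasets for recovery-bias estimation, 120
proteins × 5 runs (≈ 300 features/run) for alignment recovery, and 30
proteins for panel selection — sizes at which every documented behavior is
measurable with comfortable Monte-Carlo margins while a full test run
stays fast. Tolerances: normalized columns must agree to 1e-9; BH
monotonicity and the ANOVA oracle to 1e-6; printed product m/z to 0.2 Th
and precursors to 0.7 Th (average mass).

## Known limitations

- No REML/shrinkage variance estimation; single-replicate designs lose the
  technical variance component.
- Quantile normalization's effect attenuation grows with the changed
  fraction and effect size; with many strong asymmetric changes the
  observed FDR at q < 0.05 can exceed its nominal level (we observe
  0.06–0.15 at 10 % changed features). This is a property of the
  normalization strategy itself, shared with any pipeline built on it.
- Protein inference is name-based: no parsimony/grouping of shared
  peptides (an optional flag restricts counting to protein-unique
  peptides).
- The alignment model is a global RT shift; gradient drift within a run is
  out of scope.
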
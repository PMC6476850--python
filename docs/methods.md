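# Methods

This note documents the models, the synthetic-data generator, the numerical
conventions, and the design choices that were genuinely open.

## The experiment being modelled

A split-plot field trial: five nitrogen doses (0, 50, 100, 150, 200 kg N
ha⁻¹) on main plots within three replicate blocks, four winter oat
varieties on sub-plots, giving 60 plots. Groats from each plot are profiled
by short-gradient UHPLC-MS in positive and negative ESI; the deconvolved
output is a feature table of integrated peak areas for RT–m/z pairs.
A pooled QA extract (equal parts of every sample) is injected repeatedly to
measure analytical repeatability, blanks measure background, and an
internal standard (reserpine in positive mode, morin in negative) is spiked
into every extract.

## Preprocessing

Applied strictly in the order trim → blank filter → IS normalization →
imputation → QA-RSD filter, with a provenance log of every removal:

| step | rule | default |
|---|---|---|
| RT trim | keep `void ≤ rt ≤ run − tail` | void 0.3 min, tail 4 min, run 15 min |
| blank filter | drop iff max(blank) **strictly** > k × max(biological), missing = 0 | k = 2 |
| IS normalization | divide each biological/QA cell by that sample's IS area; IS row leaves the analyte set | IS per polarity |
| imputation | missing ← f × global minimum observed ratio | f = 1/3 |
| QA RSD | drop iff 100·sd/mean over QA columns **strictly** > cut | 25 % |

Boundary cases are strict inequalities, reading the filtering rules
literally (a feature at exactly 2× blank intensity or exactly 25 % RSD is
retained). RSD uses the sample (n−1) standard deviation — unbiased at the
small QA counts involved — and excludes column-conditioning QA injections,
which the design table flags. The RSD is computed on normalized ratios
(matching the order in which the steps are described); a switch computes it
on raw areas instead. Blank comparison uses raw areas because blanks have
no biological IS context.

Missing cells are NaN, never zero: zero is a legal measured area, and the
imputation rule must distinguish the two.

## Ion annotation

Grouping is single-linkage over the graph joining feature pairs with
|ΔRT| ≤ 5 s and Pearson r > 0.8. The "moving RT window" is implemented as
this symmetric pairwise constraint, which makes grouping independent of
feature order. Correlations use biological samples only (QA injections are
near-replicates of the grand mean and would inflate every correlation) and
are computed over pairwise-complete *observed* cells: imputed constants at
mismatched samples would otherwise destroy genuine parent–satellite
correlation, so the unimputed ratio matrix feeds this step.

Within a group, every pairwise m/z difference is matched against the rule
table (pass if within 0.015 Da absolute **or** 5 ppm of the larger m/z —
the two tolerances the upstream annotation tools print). The parent is the
member from which the most other members are explainable as rule-shifted
ions; ties break toward higher summed intensity. A single annotator
replaces the original two-tool consensus, which is a documented deviation —
the conflict-resolution procedure of that consensus is not described
anywhere and is not guessed at. Unmatched members stay grouped but
unassigned (possible in-source fragments).

Neutral mass is mz ∓ 1.007276 Da for [M+H]⁺/[M−H]⁻ parents; library
matching is by relative error ≤ 5 ppm, ranked by |ppm|. MSI level 2 needs a
candidate previously reported in oats (library flag), level 3 any
candidate, level 4 none. Redundancy collapse keeps one row per group — the
parent, else the most intense member — and never alters retained values.

## Chemometrics

All models mean-center only. No unit-variance scaling is applied: the data
are internal-standard ratios on a log₁₀ scale, already comparable across
features, and the original analysis chain makes no mention of autoscaling.
The log transform itself is this package's choice (the noise model is
multiplicative, so log ratios are the scale on which effects are additive);
it is applied by the pipeline layer, not hidden inside the models.

**ASCA.** The column-centered biological matrix is decomposed into
factor-level-mean effect matrices plus residual; the interaction is pooled
into the residual by default with a flag to separate it. Each effect matrix
is analysed by SVD; score plots add the residual projected onto the effect
loadings (the common convention for visualising sample scatter around
effect levels), with the pure projection also retained. The reconstruction
identity (centered = Σ effects + residual) holds to machine precision on
every input, and on the balanced design the sums of squares partition
orthogonally. Factor significance: the tested factor's labels are permuted
within the strata of the other factor (respecting the two-factor design),
the statistic is the factor's effect SSQ, and p = (1 + #{perm ≥ obs}) /
(n_perm + 1) with 1000 permutations by default.

**Structured-response PLS.** Y packs the whole design into one block: a
variety indicator matrix (one column per variety) and a standardized
numeric dose column — dose is treated as continuous because the validation
statistic of interest is a regression Q². The fit is NIPALS PLS2 (verified
against an independent PLS1 implementation in the degenerate single-column
case, coefficient agreement to 1e-8). Prediction decodes variety by arg-max
over the indicator block and dose by de-standardizing the numeric column.
The component count is fixed at 5 by default — three variety contrasts, the
dose direction, one spare — with an inner-CV selector available.

**Bootstrap validation.** Each of n_boot resamples draws n samples with
replacement, fits on the in-bag set and evaluates out-of-bag: variety
classification accuracy and dose Q² = 1 − PRESS/TSS with TSS about the
in-bag mean. Empty out-of-bag sets are redrawn and counted.

**RFE.** Each round refits the PLS-S on the survivors and eliminates the
least important 10 % (at least one feature). Importance is the
sd-weighted absolute dose-column coefficient: the weighting is required
because the model is unscaled (a raw coefficient's magnitude is confounded
with its feature's variance), and the dose-only default targets what the
elimination is for — features responding to nitrogen regardless of variety.
Adding the variety-block coefficients is available as an option but lets
variety-discriminant features flood the top ranks. Features eliminated
together share a rank (one plus the number still surviving; final survivors
rank 1); within-batch order is preserved through the stored
elimination-time importances.

## Univariate screening and consensus

The Friedman test runs per feature with treatments = nitrogen levels and
blocks = variety × replicate (12 blocks of 5, each plot entering directly);
for the variety factor the blocking is nitrogen × replicate. Mid-ranks
handle ties without the tie-correction factor (the classical statistic),
with the correction available by flag. For k = 3 treatments the χ²
approximation is coarse, so p-values come from exact enumeration of the
(3!)ᵇ equally likely per-block rankings (dynamic programming over rank-sum
states, b ≤ 10). BH-FDR is the standard step-up construction at 5 %.

The monotone screen reports, per variety, the Spearman correlation of
replicate-mean ratios against the dose index with a strict-monotonicity
flag; constant features are flagged non-responsive.

Consensus selection unions four evidence lists — top 1 % |PC1 loading|,
top 1 % |ASCA nitrogen SC1 loading|, best 5 % RFE ranks, Friedman top 100 —
then deduplicates by feature id and by ion-group membership, folding
evidence flags onto the group parent. The top-1 %/5 % cuts are package
defaults where the original report gives no numeric cut-offs; the "99.9 %
significance" loading cut is interpreted through the RFE rank list, since
no null distribution for loading significance is defined anywhere.

## Phenotype statistics

The split-plot ANOVA computes two error strata from group means on the
balanced layout: nitrogen is tested against the block × nitrogen
interaction (df = 8 at 5 × 3), variety and variety × nitrogen against the
sub-plot residual (df = 30 at 4 × 5 × 3). Unbalanced layouts fall back to
Type-II least squares with a single stratum and a warning. Fisher's LSD,
t₁₋α/2,df·√(2·MSe/n), is *protected* — letters are emitted only when the
omnibus F is significant — and the compact-letter display uses the
insert-and-absorb construction on the sorted means, so two means share a
letter iff their difference is within the LSD. Plot-level trait
correlations use all 60 plots; factor-mean correlations are computed and
labelled separately, because the two are different quantities.

The published factor means of the trial (5 nitrogen levels × 11 traits,
4 varieties × 11 traits) ship with the package as the worked-example
fixture; e.g. the grain-yield means give +130 % from the zero-N control to
200 kg N ha⁻¹, and the β-glucan means with a whole-plot error MS of 0.0326
reproduce the printed letter pattern a/ab/ab/bc/c (any error MS giving an
LSD in [0.14, 0.21) yields that pattern; 0.0326 places the LSD at 0.17).

## The synthetic-data generator

Intensities are log-normal: ln area = baseline + variety offset + slope ×
dose-index + ε, with ε ~ N(0, σ²), σ = √ln(1 + cv²), so measurement noise
has constant CV — the assumption under RSD-based QC. Defaults (the study
conditions of the package's own experiments, chosen once):

- `n_features` 500 base features; baselines ~ N(ln 1e5, 1).
- `frac_nitrogen_responsive` 0.10, slope ±0.6 per dose step: a strong but
  plausible 4–5-fold response over the dose range, large enough that the
  nitrogen gradient dominates PC1 as in the real data.
- `frac_variety_discriminant` 0.10 with offsets of sd 0.8, zero-mean across
  varieties; the Mascani/Tardis pair shares offsets up to a residual scale
  of 0.4, making them by far the closest pair (as observed in the field
  data) while still separable — the regime in which the original varieties
  were classified perfectly.
- `noise_cv` 0.15: a realistic post-QC repeatability CV, and one that keeps
  the QA-RSD sampling distribution at 8 injections clear of the 25 % cut.
- `missing_rate` 0.02: cells below a global detection threshold (the
  missing-rate quantile) drop out with probability 0.8. Censoring applies
  to biological *and* QA cells, so near-detection-limit features show
  erratic QA values and are removed by the RSD filter exactly as in a real
  run; low missingness reflects that upstream alignment already drops
  features undetected in half the samples. This censoring model is what
  makes the global ⅓-minimum imputation self-consistent (the filled value
  really is "just below detection").
- `adduct_satellite_rate` 0.2: satellites are a fixed U(0.1, 0.5) multiple
  of the parent's per-sample area with σ/4 extra noise, at the rule-shifted
  m/z within ±2 s, and inherit all biological effects — so redundancy
  collapse can be validated by effect-recovery equivalence.
- Blank contaminants (2 %) appear at 3× the feature's biological maximum in
  blanks; other features have at most trace (0.02×) blank signal, so blank
  filtering has an exact expected outcome.
- QA cells are the arithmetic (pooling) mean of the biological areas under
  the same multiplicative noise; the internal standard is present in every
  injection with σ/2 noise.

What the generator does **not** emulate: retention-time or intensity drift,
batch effects, correlated (compound-class) noise, in-source fragments,
isotope-pattern intensities, or any real metabolite identities (m/z values
are uniform random, so library matching on synthetic data yields MSI-4
unknowns by construction). Passing recovery tests therefore demonstrates
that the algorithms recover the structure they are designed for under an
idealised noise model — not pipeline performance on real chromatography.

## Numerical conventions and degenerate inputs

- RT is stored in minutes; the ±5 s window converts through one constant.
- Pearson/Spearman on constant vectors are undefined: such features are
  never linked in grouping and are flagged non-responsive in screens.
- The strict-monotonicity flag uses |ρ| > 1 − 1e-12.
- NIPALS stops a component early if X or Y deflates to zero; requesting
  more components than the rank bound raises.
- Permutation p-values can never be 0 (the +1 convention); n_perm ≥ 1.
- An all-missing matrix cannot be imputed (error); a table with no blank
  injections passes the blank filter with a warning.
- Bootstrap resamples with an empty out-of-bag set are redrawn and counted.

## Problem sizes used in the shipped experiments

The analysis scripts and acceptance checks run the default trial (60
biological samples, 500 base features), 1000 ASCA permutations, 200
bootstrap resamples, 200 pure-null trials at 40 features for permutation
calibration, and 100–200 null trials at 100 features for FDR calibration —
sizes at which every documented property is measurable with comfortable
statistical margin while the whole suite completes in well under a minute.

## Known limitations

- One annotator replaces the original two-tool annotation consensus.
- Negative-mode processing is symmetric to positive mode and exercised only
  through the IS/rule tables, not a full second pipeline run.
- The shipped metabolite library is a small stand-in; no attempt is made to
  reproduce the original library's contents.
- Dim features near the detection limit can survive QC with several imputed
  cells and genuinely degraded effective signal; their recovery by RFE is
  correspondingly weaker than that of bright features.
- The real study's headline feature counts depend on its deposited raw data
  and deconvolution settings and are out of scope here.
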
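# Methods

This note records the statistical model the package implements, the
conventions chosen where several are defensible, what the simulator does
and does not emulate, and the numerical details that matter for
reproducing its output.

## Traits

HMF and HF are per-plot proportions expressed in percent.  The
denominator defaults to the number of haploid plants recorded at anthesis
(`n_at_anthesis`), the count actually scored in the field; it can be
switched to planted kernels (`n_planted`), which folds field survival
into the trait.  A plot with zero denominator yields a missing value —
never zero, which would be a biological claim the data cannot support.
HF > HMF on a plot (seed without recorded tassel fertility) is flagged
with a warning but accepted, since field books can contain it; the
simulator, by construction, cannot produce it.  Percentages are carried
at full float precision; reports round to 2 decimals.

## Stage one: plot-level ANOVA and BLUEs

The combined-environment model is the fixed-effects specification
y = μ + genotype + env + genotype×env + rep(env) + error, fitted by
ordinary least squares.  Sums of squares are sequential (Type I) in the
order Env, Rep(Env), Genotype, Genotype×Env; with balanced data this
equals Type III and the textbook between-group sums, which is what the
unit tests assert against an explicit projection oracle.  Denominators
for F: Env against Rep(Env); everything else against the pooled error.
The incomplete-block (alpha-lattice) field layout is deliberately *not*
modelled — the analysis model is replicate-within-environment, and no
lattice adjustment or REML fit is attempted.

Entry BLUEs come from the additive model entry + env + rep(env): each
BLUE is the model prediction averaged over the observed env × rep grid,
so balanced data give plain means exactly and missing plots give
least-squares adjusted means.  Missing plots are handled by least
squares, never imputed; an entry with no plots at all is a design error.

## Griffing Method 1, Model I

Effects use the standard closed forms (see README).  Two properties are
load-bearing and are enforced by tests: the decomposition is saturated
(1 + (p−1) + p(p−1)/2 + p(p−1)/2 = p² df, so fitted cells equal observed
cells exactly), and the five components — GCA, SCA, reciprocal, with
reciprocal split into maternal and nonmaternal — are mutually orthogonal
over the p² cells.  Orthogonality makes the component sums of squares
plain quadratic forms of the estimates (e.g. SS_GCA = 2p Σ ĝ², on the
entry-mean basis), and guarantees SS(GCA) + SS(SCA) + SS(Reciprocal) =
SS(Genotype) and SS(Maternal) + SS(NonMaternal) = SS(Reciprocal).

Component × environment interaction SS are obtained by applying the same
partition within each environment (scaled by replicates), summing, and
subtracting the across-environment component SS.  In the two-environment
analysis each main component is F-tested against its own ×Env mean
square, and the ×Env rows against the pooled error; with a single
environment the components are tested against the pooled error directly
(a documented fallback, not the design of record).

Standard errors of individual effects are exact: every estimator is a
linear functional of the p² independent cell means (each with variance
MS_error/(reps × envs)), so the coefficient vectors are built
programmatically by pushing the p² basis tables through the closed forms
and the variance is the coefficient sum of squares times the mean-basis
error variance.  This reproduces the textbook per-effect variance
formulas — the tests check SE(ĝ_i) = √((p−1)/(2p²)·σ²) — without
transcribing each of them.  t tests are two-sided on the pooled error df;
stars use * p < 0.05, ** p < 0.01; no multiple-testing adjustment is
applied.  Percent traits are analyzed untransformed; no arcsine option in
this version.

## Variance components and ratios

Model I treats the parents as the population of interest, so "variance
components" here are descriptive summaries, quoted because breeders use
them.  The default estimator chain operates on entry-mean-basis mean
squares:

    σ²_GCA = (MS_GCA − MS_SCA) / 2p
    σ²_SCA = MS_SCA − MS_e
    σ²_REC = (MS_REC − MS_e) / 2

with σ²_A = 2σ²_GCA and σ²_D = σ²_SCA.  Software packages differ in these
divisors, so they are configurable arguments; the derived *ratios* —
Baker's ratio σ²_A/(σ²_A + σ²_D), the GCA/SCA variance ratio, h² and H² —
are identities in σ²_A, σ²_D, σ²_P and do not depend on that choice,
which is why they are the quantities of record.  The phenotypic variance
defaults to σ²_A + σ²_D + σ²_REC + σ²_e and both σ²_P and its composition
can be supplied explicitly.  Negative raw component estimates are clamped
to zero, recorded in a `clamped` list and warned about — never silently.

## Hybrid prediction

MPV = (P_i + P_j)/2 from parent per se means, and the GCA-sum predictor
g_i + g_j.  Pearson correlations with observed F1 performance are
computed over the unordered crosses with parents excluded (28 for p = 8)
— the only definition reproducible from combined-reciprocal hybrid
tables; at least 3 hybrids and nonzero variance are required, otherwise
the correlation is refused rather than returned as NaN.  Hybrid group
summaries (High × High … Low × Low) use the parent classification
supplied by the caller; for the packaged experiments the shipped
classification and the printed group labels are used verbatim.

## Simulator

The generator emulates the field design the analysis targets: p = 8
parents (configurable, ≥ 3), all p² cells including selfs and reciprocals,
2 environments × 2 replicates, 100 kernels per plot.  A latent percent
for each plot is μ + g_i + g_j + s_ij + (m_i − m_j + n_ij, crosses only)
+ env + G×E + rep + plot noise, with all effect vectors drawn normal and
centred (the symmetric SCA matrix is double-centred so its rows sum to
zero; G×E is additionally centred across environments per cell).  The
latent percent is clamped to [0.5, 99.5] (clamp events are counted in the
truth object) and becomes the tassel-fertility probability; a logit link
is available for boundary-heavy material.  Counts are binomial:
tassel-fertile out of plants at anthesis, then seed-set out of
tassel-fertile at a conditional rate (default 0.5, matching the roughly
2:1 HMF:HF ratio of real lines), so count conservation holds by
construction.  Default variance magnitudes (σ²_GCA = 85, σ²_SCA = 60,
maternal/nonmaternal 3, env 10, G×E 10, rep 3, plot 100, μ = 25, percent²
throughout) were chosen once to match the scale of a high-variance
male-fertility trait in tropical material.

Per-plot randomness is keyed on (root seed, environment, replicate,
female, male) through independent seed sequences, so draws never depend
on record order and a seed reproduces a byte-identical trial.  The
`paperlike` variant pins the diagonal of the latent grid to the published
parent per se means and sets each hybrid cell to the mid-parent value
plus drawn SCA/reciprocal deviations.

What the simulator does *not* emulate: overdispersion beyond binomial
(beta-binomial would be the natural extension), field survival
(`n_at_anthesis` equals `n_planted`), spatial/lattice structure, haploid
misclassification, and any marker-level architecture.  Passing
parameter-recovery tests therefore demonstrate correctness of the
estimators under the stated generative model, not robustness to those
real-data features.

## Numerical conventions and edge cases

* Parent order is lexicographic unless supplied; all matrices share it.
* Entry-mean tables must be complete for Method 1; missing cells raise a
  design error rather than being imputed.
* Zero-sum constraints hold to ~1e-10 absolute; saturated reconstruction
  to ~1e-9 on well-scaled percent data.
* Problem sizes in the test-suite simulation studies: 200 replicates of
  the 256-plot study-sized trial for variance recovery and GCA-ordering
  recovery, 12-seed averages for the Baker-ratio monotonicity and
  maternal-variance checks, and 1000 random tables for the structural
  invariants.

## Known limitations

* Fixed-model (Model I) variance components are descriptive; no REML /
  Model II estimation is offered.
* Only Method 1 (full diallel with reciprocals) is implemented; Methods
  2–4 and Hayman's graphical analysis are out of scope.
* The single-environment fallback tests components against the pooled
  error, which is anti-conservative if G×E exists but is unobservable.
* Published effect tables for the two shipped experiments cannot be
  recomputed end-to-end because the underlying plot data and the full
  reciprocal mean tables were never released; they are exercised through
  the prediction correlations and ratio identities instead.
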
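# Methods

## The assay statistic

The unit of observation is one culture well: 20–30 isolated Stage-10B
follicles matured overnight and binned into four stage buckets (S10B, S11,
S12, S13/14). A follicle reaching S12 or S13/14 has completed nurse cell
dumping. For one genotype in one experiment, with paired vehicle and
aspirin wells,

    f_t        = (n_S12 + n_S13/14) / n_total            (dumping fraction, treatment t)
    DI         = f_aspirin / f_vehicle                    (dumping index)
    NDI        = DI_genotype − DI_control                 (normalized dumping index)

where the control is the wild-type (*yw*) pair run inside the same
experiment. Fractions are always formed from raw integer counts; percent
displays are formatting only, so the ratio is never double-rounded. `DI` is
undefined (an error, never 0 or ∞) when no vehicle follicle matured.

Quality control operates on the control only: an experiment whose control
DI is below 0.4 or above 0.6 is excluded along with all its genotype scores.
Exclusion is phrased strictly, so ties at 0.4 and 0.6 pass. Experimental
genotypes never trigger exclusion.

Replicate aggregation takes the mean and sample (n−1) SD of DI and NDI over
the QC-passing experiments of each genotype; n counts those passing
replicates. A genotype with a single usable replicate is reported with a
missing SD (not 0) and flagged provisional.

## Classification bands

The band scale σ is the sample SD of the pooled, QC-passing,
*non-normalized* control DIs across the whole screen (the normalized control
values are identically zero and carry no spread). Calls on the mean NDI:

    |mean NDI| <  σ        non-interactor
    σ ≤ |mean NDI| < 3σ    weak interactor
    |mean NDI| ≥ 3σ        strong interactor

with direction from the sign (negative = enhancer of drug sensitivity,
positive = suppressor). Boundary handling is a deliberate choice where the
verbal rule is ambiguous ("greater than" vs "equal to or greater than"):
the strong band is inclusive at 3σ and the non-interactor band exclusive at
σ, which makes the partition exhaustive. With σ = 0 (identical controls)
the spec is degenerate: any nonzero effect is strong, and a warning is
logged. σ may also be supplied externally (e.g. a published aggregate value
such as 0.054, giving bands ±0.054 and ±0.162) to reproduce fixed bands on
new data; reports always state whether σ was computed or supplied.

A subtlety worth recording: published per-genotype means are conditioned on
QC passing, and QC truncation biases the passing controls' mean DI slightly
below the unconditional expectation. Printed aggregate differences are
therefore only approximations of the per-experiment normalized means the
classification actually uses; this package always classifies from
per-experiment NDIs.

## Inference

Tests run on per-experiment dumping indices — the replicate unit — not on
per-follicle outcomes. All tests accept raw samples or summary statistics
(n, mean, sample SD); the raw path reduces to summary form first, so the
two are algebraically identical.

- **One-way ANOVA**: F = (SSB/(k−1))/(SSW/(N−k)); F = 0 and p = 1 when
  both sums of squares vanish.
- **Dunnett many-to-one**: pooled within-group variance over all k+1
  groups (df = N−k−1); per-treatment statistics
  t_i = (m_i − m_0) / (s_p √(1/n_i + 1/n_0)). Family-adjusted p-values come
  from P(max_j |T_j| ≥ |t_i|) under the equicorrelated multivariate-t null
  with corr(T_i, T_j) = λ_i λ_j, λ_i = √(n_i/(n_i+n_0)), evaluated by
  deterministic numerical integration: 80-node Gauss–Hermite over the shared
  normal factor and adaptive quadrature over the scaled-chi pooled-SD mixing
  variable. Accuracy is well below 1e-4 on the adjusted p (cross-checked in
  the tests against an independent implementation and a 200,000-draw
  Monte-Carlo max-|t| null). With one treatment the procedure reduces
  exactly to the pooled two-sample t-test, and adjusted p ≥ raw p always.
  The family is all genotypes analyzed in one report invocation versus the
  pooled control — a design choice, since family composition is otherwise
  unconstrained by the assay.
- **Welch t**: Satterthwaite df; **Student t**: pooled variance,
  n_a+n_b−2 df. Zero-variance edge cases return t = 0, p = 1 when the
  means agree.

## The synthetic screen generator

The generator emulates the assay's generative structure, with defaults set
to the study conditions: control vehicle maturation probability 0.92,
aspirin dose calibrated so the control matures at 0.50 under drug (log-odds
shift β_control = logit 0.92 − logit 0.50), wells drawn uniformly from
20–30 follicles, one paired wild-type control per experiment. A genotype's
sensitivity is an additive log-odds shift applied only under aspirin:

    p_aspirin = logistic(logit(p_vehicle) − β_control − direction·β + δ_e)

with δ_e ~ N(0, τ) drawn once per experiment and shared by all of its wells
— the batch structure that makes within-experiment normalization
meaningful. Dumped counts are binomial; stage buckets are filled by
cosmetic split probabilities (default 0.5) that never affect the score.
Probabilities pushed outside (0,1) by extreme shifts are clamped to
[1e-6, 1−1e-6] with a warning. The logit-additive link is a modelling
choice; any monotone link would serve, and the link enters only through the
configuration.

**Variance accounting.** At 20–30 follicles the binomial sampling SD of a
single control DI is ≈ 0.115 — but the screen's aggregate control SD is
computed over *QC-passing* controls, and truncation to [0.4, 0.6] caps that
spread at ≈ 0.055–0.06. The observed aggregate control SD of such screens
(≈ 0.054) is therefore reproduced by counting statistics plus QC truncation
alone, and the generator's default τ is 0. `calibrate_tau` makes this
explicit: it bisects τ against the simulated QC-passing aggregate SD, with
the τ = 0 value as the irreducible floor (targets below it raise an error
naming the binomial floor) and the truncation ceiling as the upper limit
(targets above it raise an error naming the QC cap). Because the achievable
window is narrow, calibration to ≈ 0.054 legitimately returns τ ≈ 0; τ
still matters through the QC exclusion rate, which rises monotonically
with it.

**Included replicates.** Reported per-genotype n counts usable (QC-passing)
experiments — an experimentalist repeats failed batches. The recovery
harness therefore simulates experiments until n pass QC
(`simulate_included_screen`), then runs the full score → threshold →
classify pipeline per repetition, deriving σ from each simulated screen's
own pooled controls. A planted strong enhancer is parameterised directly by
its post-QC observable (its expected dumping index, e.g. 0.192 against a
control near 0.5), matching how such effects are reported.

Problem sizes used in the validation suite — 500 repetitions for recovery
and false-call rates, 1,000–2,000 simulated experiments for expectation and
calibration checks, 200,000 draws for the Dunnett Monte-Carlo oracle — were
chosen so Monte-Carlo error is several times smaller than the tolerance
being checked.

**What the generator does not model**: pharmacokinetic drug decay over the
culture (jitter is one scalar per experiment), correlation between
follicles within a well, dose–response across aspirin concentrations (the
screen is single-dose), or genotype-specific vehicle-arm defects beyond the
configurable p_vehicle. Passing recovery tests show the pipeline is correct
and well-calibrated *under binomial well sampling with batch-level potency
jitter*; they cannot certify robustness to overdispersed wells or
experimenter-correlated scoring drift in real data.

## Image quantification

Membrane intensity is the mean of bilinear-interpolated samples along a
polyline probe, sampled at arc-length spacing ≤ 0.5 px (probe width 1 px by
default; wider probes average parallel offset lines 1 px apart). The
cytoplasm reference is the mean over a polygon (or mask) region of the same
cell, and the corrected value is membrane − cytoplasm; negative corrected
values are retained and flagged, never clipped, so downstream t-tests stay
valid. Adding any constant to the image leaves the corrected value
unchanged — the stated purpose of the subtraction. Maximum projection takes
the elementwise max over a 2–4-slice interval (a count outside that range
only warns). Bilinear interpolation and the 0.5 px spacing are
implementation choices (a manual ImageJ workflow leaves them unspecified);
they are tolerance-tested at 2 AU on analytic fixtures. The membrane probe
length is a required input with no default, since the protocol fixes only
that the *same* length is used across images.

The synthetic follicle fixture renders a polygonal cell boundary as a
Gaussian ridge (σ = 1.5 px) over a uniform interior, using the exact
distance to the boundary polyline rather than a drawn-then-blurred mask, so
the crest value equals the nominal membrane intensity and the ground-truth
corrected value is exact. The reference probe sits on an axis-aligned
integer-row edge, where bilinear interpolation is exact along the crest.
Per-slice Gaussian noise is clipped at zero (negligible at the default
intensities); the maximum-projection noise bias is common to membrane and
cytoplasm and cancels in the corrected value.

Densitometry follows the standard two-step normalization: band / loading
control per lane, then division by the mean normalized value of the
designated control lanes; relative values are invariant to rescaling all
lanes by a common factor.

## Known limitations

- Dunnett's procedure assumes equal within-group variances; per-genotype DI
  variances in this assay grow with effect size (smaller f_aspirin means a
  larger coefficient of variation), so adjusted p-values for strong
  enhancers are conservative approximations.
- The QC band induces a selection bias (~+0.03 on null genotypes' mean NDI
  at the default calibration) that is faithful to the screening rule but
  means all-null false calls are asymmetric between the suppressor and
  enhancer directions.
- `thresholds_from_controls` treats pooled control DIs as exchangeable
  across experiments; a screen with strong batch structure in its controls
  would need a hierarchical σ estimate, which is out of scope.
- The image pipeline quantifies probes it is given; it does not segment
  membranes or detect gel bands.
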
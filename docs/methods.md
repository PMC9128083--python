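# Methods

## The model

A CHIP clone is a hematopoietic stem-cell lineage carrying one driver
mutation. Under neutral-to-moderate selection its cell fraction changes
approximately exponentially with age, so for a heterozygous mutation the
variant allele fraction obeys

    log10(VAF) = C + β · age,

with `C` the (extrapolated) log10 VAF at age 0 and `β` the per-year slope.
`chipdyn` fits this line to each driver mutation's longitudinal VAF series by
weighted least squares and interprets the fit:

- **weights** — each observation is weighted by √(read depth). VAF
  measurement error is binomial, with standard deviation ∝ 1/√depth on the
  natural scale; √depth is a deliberately mild, monotone precision weight
  rather than a full inverse-variance weight, and is what the fit contract
  here specifies.
- **zero VAFs** — a driver undetected at a well-covered timepoint is
  informative absence. Zeros are floored at 10⁻⁴ (a conservative limit of
  detection for a ~3000× UMI-corrected assay) before the log transform.
- **classification** — two-sided t-test of β = 0 on n−2 degrees of freedom:
  *growing* (β > 0, P < 0.5), *shrinking* (β ≤ 0, P < 0.5), *static*
  (P ≥ 0.5). The 0.5 cut-off is deliberately permissive — it asks only
  whether the direction of change is better supported than not — and is
  exposed as `p_threshold` rather than hard-coded. With 3–6 points per
  series a conventional 0.05 threshold would label nearly everything static.
- **degenerate fits** — exactly collinear points have zero residual
  variance; their P is defined as 0 so synthetic noise-free inputs classify
  by the sign of β. Two-point series have no residual degrees of freedom;
  they get P = NaN, no three-way label, and are summarized only as growing
  vs non-growing by the sign of Δlog₁₀(VAF).
- **doubling period** — under the exponential model a growing clone's VAF
  doubles every log₁₀(2)/β years.

Eligibility for trajectory analysis mirrors the underlying longitudinal
study design: subjects sequenced at ≥3 timepoints with at least one driver
above 1% VAF somewhere; observations with alternate count < 2 or depth < 200
excluded (alt < 2 at depth ≥ 200 is recorded as VAF 0; depth < 200 drops the
timepoint as unassayed); clones whose first retained VAF exceeds 10%
excluded, since exponential growth may not hold for large clones
approaching the heterozygous ceiling. "Starting VAF" is the first *retained*
observation, zeros included — a literal reading of "starting".

The **dominant clone** of a subject is the trajectory with the highest VAF at
any timepoint; ties break toward the larger final VAF, then lexicographic
variant id (a deterministic, content-based rule). Competition candidates are
non-growing clones that nevertheless reached the 2% CHIP threshold while a
growing clone co-occurred in the same subject.

Gene-group growth comparisons use the Mann-Whitney U test on β (exact
enumeration when the pooled sample is ≤ 20 without ties, otherwise the
normal approximation with tie correction); "rate of growth" could equally be
compared on doubling periods, which is available via `value=
"doubling_period"` and gives identical p-values by rank reversal when all β
are positive. Per-gene growth odds use the 2×2 Fisher test with the
Haldane–Anscombe 0.5 correction for zero cells; a logistic route is provided
for covariate-adjusted versions.

## Variant processing

Raw UMI-tagged reads are collapsed per (probe, 9-mer UMI) group to one
molecule by majority vote over the group's observed alleles; exact ties drop
the group — conservative, order-independent, and deterministic. Malformed
UMIs are rejected read-by-read with a logged count.

The stand-in somatic caller is a one-sided exact binomial test of the
alternate count against Binomial(depth, error rate), candidate at p < 10⁻⁶.
It preserves the downstream contract (calls with p-values) at desk scale;
externally produced VCFs can be supplied instead. Post-call filters are
applied with inclusive boundaries exactly as stated: depth ≥ 40, alternate
reads ≥ 5, VAF ≥ 0.1%; variants at VAF in the closed window [1%, 10%] in
≥ 5% of samples are flagged as recurrent artifacts in *all* samples. The
artifact rule counts samples by default (subjects optionally): note that in
small cohorts (< ~120 samples) a genuine private clone observed at up to six
timepoints of one subject can cross the 5% sample fraction; at the scale the
rule was designed for (hundreds of samples) it cannot.

## Assay-validation statistics

- **Expected mixture VAF** for a variant in a defined multi-line gDNA
  mixture: Σᵢ pᵢ·dᵢ/2 over lines with proportions pᵢ and genotype dosages
  dᵢ ∈ {0,1,2}. For the five-line control mixture (78.75/16/4/1/0.25% — the
  dominant line is the complement of the spiked lines) the attainable range
  is 0.125% (one het copy in the rarest line) to 100%.
- **Error rate** — pooled: total non-reference reads over total reads at
  invariant sites, matching the aggregate "1 in N bp" framing and invariant
  to how reads are partitioned across sites. A mean of per-site rates would
  weight shallow sites up.
- **ICC** — one-way random-effects ICC(1) = (MS_B − MS_W)/(MS_B +
  (k−1)·MS_W), the form for interchangeable replicates of the same variant;
  k is the mean replicate count (equal to the column count for balanced
  matrices). The confidence interval uses the F-distribution bounds on
  MS_B/MS_W. Negative estimates are reported as computed.
- **Concordance** — Pearson correlation on untransformed VAFs (a log-scale
  option exists), overall and stratified at expected VAF ≤ 2% vs > 2%;
  replicate measurements are averaged per variant before correlating.

## The simulator

The generator emulates the study conditions the analysis assumes: subjects
enrolled at ages 50–78 with a baseline visit, annual visits at +1/+3/+6/+9
years, and a long-term visit 14–19 years after enrollment (1–6 visits per
subject); clones per subject ~ Poisson(1.2); gene assignment from the
15-gene panel's relative driver frequencies; per-clone β from a mixture of a
point mass at 0 (probability 0.25) and Normal(0.02, 0.04) per year —
**illustrative values**, since no population distribution of clone growth
rates is assumed known; initial VAFs log-uniform on [0.2%, 8%]; VAF capped
at 0.5 (heterozygous ceiling); depths lognormal with median 2803 and
σ = 0.97 (mean ≈ 4480, the assay's scale); substitution errors at 0.045%
per base, uniform over the three non-reference bases, so the probability a
read reports a specific alternate allele is
v(1−e) + (1−v)·e/3. Covariates (BMI, smoking, race/ethnicity) are
independent draws from plausible marginals with an optional linear BMI
effect on baseline log-VAF to exercise the association stage.

What the simulator does **not** emulate: indels and multi-nucleotide
variants (the data model passes them through untested), context-dependent
or strand-biased error, UMI collisions between distinct molecules, probe
dropout, batch effects, age-dependent clone acquisition, clone–clone
interference within a subject, and correlated covariates. Passing recovery
tests therefore demonstrate correctness of the *estimators* under the
binomial noise model, not robustness to every artifact of real sequencing
data.

`simulate_site_reads` counts one specific alternate base (rate e/3 at an
invariant site); error-rate estimation needs the *total* non-reference count
(rate e), which `simulate_invariant_sites` emits directly.

## Numerical choices and problem sizes

- WLS via statsmodels; tests verify the closed-form weighted normal
  equations independently to 1e-10.
- Perfect-fit detection: weighted residual sum of squares ≤ 1e-20 × the
  weighted response scale.
- Binomial test, Mann-Whitney, Fisher exact from scipy; logistic/linear
  covariate models from statsmodels with patsy dummy coding (reference level
  = first level alphabetically; estimates are row-order invariant).
- Rank-deficient designs and constant covariates raise a `ModelError`
  naming the culprit term; missing covariates are excluded row-wise with
  logged counts.
- Default analysis scales: 40-subject simulated cohorts for pipeline runs,
  a 152-variant × 27-replicate mixture matrix for validation surrogates,
  500 clones for direction-recovery checks, 1000 invariant sites for
  error-rate recovery — small enough to run in seconds while leaving
  Monte-Carlo error well inside the tested margins.

## Known limitations

- The caller is a calibrated stand-in, not a realignment-aware somatic
  caller; it shares none of LoFreq-class quality modeling.
- Functional annotation is consumed as an input table; no consequence
  prediction is performed, and protein changes match by exact string.
- The whitelist ships with the 15 panel genes and documented rule kinds as
  an editable config; it is not a curated census of every reported CHIP
  mutation.
- The trajectory model is log-linear by construction; logistic or
  decelerating growth near fixation is out of scope (clones starting above
  10% are excluded for this reason).
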
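# chipdyn

Longitudinal analysis of **clonal hematopoiesis of indeterminate potential
(CHIP)** — the age-related expansion of hematopoietic stem-cell clones
carrying cancer-associated somatic mutations (classically in *DNMT3A*,
*TET2*, *ASXL1*, *JAK2*). Deep targeted sequencing with unique molecular
identifiers (UMIs) can measure a clone's variant allele fraction (VAF) down
to ~0.1%, so sampling the same subjects over many years reveals whether each
clone is growing, shrinking, or static.

`chipdyn` implements that analysis as a tested, reusable Python library:

- **Synthetic cohorts** (`chipdyn.simulate`) — longitudinal subjects with 1–6
  visits over ~16 years, per-clone exponential VAF dynamics, binomial read
  sampling at smMIPS-like depths (median ~2803×) with a 0.045% per-base
  substitution error, 9-mer-UMI-tagged raw reads, and the five-cell-line
  validation mixture (78.75/16/4/1/0.25%), with ground truth for recovery
  tests.
- **Variant processing** (`chipdyn.variants`) — UMI deduplication by
  majority-vote consensus per (probe, UMI) group; a one-sided exact binomial
  stand-in caller against the error rate; the post-call filters (coverage
  ≥ 40, alternate reads ≥ 5, VAF ≥ 0.1%, and removal of variants at VAF
  1–10% in ≥ 5% of samples as recurrent artifacts).
- **CHIP calling** (`chipdyn.chip`) — a configurable 15-gene driver whitelist
  (hotspot / truncating / missense rule kinds, population-frequency germline
  exclusion), per-subject CHIP status at the 2% and 10% VAF thresholds, and
  prevalence by age.
- **Trajectory dynamics** (`chipdyn.trajectories`) — the weighted log-linear
  growth model

  $$\log_{10}(\mathrm{VAF}) = C + \beta \cdot \mathrm{age}$$

  fitted by WLS with weights $\sqrt{\text{depth}}$ and zero VAFs floored at
  $10^{-4}$; classification into growing ($\beta > 0$, $P < 0.5$), shrinking
  ($\beta \le 0$, $P < 0.5$) or static ($P \ge 0.5$); doubling period
  $\log_{10}(2)/\beta$; dominant-clone selection; clone-competition flags;
  Mann-Whitney and odds-ratio gene-group comparisons.
- **Assay validation** (`chipdyn.validation`) — expected mixture VAF
  $\sum_i p_i d_i / 2$, pooled error-rate estimation at invariant sites,
  one-way random-effects ICC(1) with F-based confidence interval, and
  observed-vs-expected / cross-platform concordance.
- **Associations** (`chipdyn.association`) — cross-sectional logistic/linear
  models of CHIP prevalence and VAF, and the longitudinal model of the
  dominant clone's Δlog₁₀(VAF), on age, race/ethnicity, smoking, BMI and
  first-visit year.

A thin CLI (`chipdyn simulate|process|chip-call|trajectories|validate|
associate|run-all`) wraps the library for shell use; `examples/` contains
short narrative scripts, one per capability.

## Worked example

```python
from chipdyn import (Trajectory, TrajectoryObservation, classify_trajectory,
                     fit_trajectory)

traj = Trajectory("S0001", "TET2", "4:106155100:C:T", observations=[
    TrajectoryObservation(age=60.0, vaf=0.010, depth=2803, alt_count=28),
    TrajectoryObservation(age=65.0, vaf=0.020, depth=2803, alt_count=56),
    TrajectoryObservation(age=70.0, vaf=0.040, depth=2803, alt_count=112),
])
fit = fit_trajectory(traj, vaf_floor=1e-4)
print(f"beta = {fit.beta:.5f}/yr, doubling every {fit.doubling_period:.2f} yr,"
      f" label = {classify_trajectory(fit)}")
```

prints

```
beta = 0.06021/yr, doubling every 5.00 yr, label = growing
```

— the VAF doubles every five years (β = log₁₀(2)/5), the points are exactly
log-linear so the fit is perfect (P treated as 0), and the clone is labeled
growing. Running `python examples/02_assay_validation.py` similarly prints
the simulated control-mixture summary (observed-vs-expected Pearson
r = 1.0000, ICC(1) = 0.9995, pooled error rate 0.0448% ≈ 1/2232 bp), and
`examples/04_full_pipeline.py` runs every stage on a simulated 40-subject
cohort and prints per-stage record counts plus the CHIP prevalence-by-age
table.

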
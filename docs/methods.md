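# Methods

## Model and assumptions

The estimand is, per age/sex stratum, the central 95% range of serum
creatinine in the *healthy* pediatric population, derived indirectly from
hospital data. Three assumptions carry the method:

1. **Repeat measurement marks disease.** Children measured more than once
   in the study window are assumed enriched for AKI/CKD (serial follow-up),
   so the reference population is restricted to single-measurement
   individuals. This is an exclusion by individual, not by draw.
2. **Residual contamination is high-valued and sparse.** Sick children
   measured only once slip through; a one-sided Tukey fence
   (> Q3 + 1.5·IQR, single pass, per stratum) removes them. Low values are
   never trimmed — hypo-creatininemia is not the disease signal being
   guarded against.
3. **Within-stratum normality.** After the two filters, creatinine within
   a narrow age/sex stratum is treated as Gaussian, so the limits are the
   parametric mean ± 1.96·SD (sample SD, n−1). The conventional 1.96 is
   used, not the exact normal quantile. Empirical P2.5/P97.5 order
   statistics are computed alongside; parametric limits are the default
   display.

Strata: per sex, one infant bin [30 days, 1 year) and seventeen 1-year
bins with edges at 365.25-day multiples, half-open, tiling
[30 days, 18 years) — 36 strata. Ages are exact calendar-day differences;
the lower bound of each window is inclusive (an exact 14th birthday in
365.25-day terms belongs to the 14–15 bin).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `fence_multiplier` | 1.5 | Tukey fence factor k in Q3 + k·IQR |
| `z_value` | 1.96 | normal multiplier for the central-95% limits |
| `min_group_n` | 120 | adequacy floor per stratum (IFCC-style minimum) |
| `rounding_decimals` | 2 | reported precision, mg/dL |
| `quantile_method` | `linear` | h = (n−1)p interpolation (spreadsheet default); any numpy rule or Tukey `hinges` selectable |
| `age_lower_days` / `age_upper_years` | 30 / 18 | eligibility window |
| `multiplicity_scope` | `study_window` | repeat counting spans all draws in the window, even age-ineligible ones |
| `outlier_floor_n` | 4 | below this stratum size the fence is skipped and flagged |

The linear (h = (n−1)p) quantile rule is the default because the original
analyses of this kind are spreadsheet work; the choice is exposed for
sensitivity analyses. Rounding is half away from zero ("ordinary" decimal
rounding), applied only at reporting time — all internal arithmetic is
unrounded.

## Synthetic cohort: what it emulates, what it does not

The generator produces an EHR-shaped table with known truth. Defaults
emulate the structure of the large hospital study the package's worked
examples are anchored to: 44,197 individuals; stratum membership weighted
by that study's per-stratum counts (so default stratum sizes land at
≈370–2,230 single-measured children); 35.3% of individuals
repeat-measured, with a shifted-geometric draw count of mean 7.9 (total
≈152k draws); 20% of repeat-measured individuals carry a persistent
elevated-creatinine state, multiplicative 1 + log-normal with median
factor 2; 2.1% of single-measurement individuals carry a kidney/urinary
diagnosis flag *independent of their value*; healthy values are stratum-
wise normal truncated at 0.01 mg/dL; draw dates are uniform over a fixed
2011–2018 window with birth dates back-computed, and repeat draws are
spaced 3–28 days apart, following the stratum the child has aged into.

Deliberately not emulated: real age-distribution skew of hospital
attendance, assay drift and batch effects, within-child biological
correlation beyond the shared elevation state, seasonal patterns,
diagnosis flags that correlate with creatinine among single-measured
children, and any lower-tail pathology. Passing recovery tests therefore
shows the *pipeline arithmetic* is correct under the method's own
assumptions — not that those assumptions hold in any particular hospital.

## Numerical choices and degenerate inputs

- Quartiles/percentiles delegate to `numpy.quantile`; Tukey hinges are
  implemented directly (median-of-halves, median shared when n is odd).
- The fence is strict (`>`): values exactly on the fence survive. Constant
  data give IQR 0 and remove nothing. The fence is single-pass by
  contract; re-applying it to the kept values may remove more, and the
  tests document rather than prevent this.
- Empty strata are omitted with a warning; a stratum of one yields an
  undefined (NaN) SD and collapses its parametric limits to the mean;
  strata below `outlier_floor_n` skip the fence and are flagged.
- Rounding uses `decimal.Decimal` on the float's shortest repr, avoiding
  binary-float surprises at the half-cent boundary.
- Reader validation rejects and reports invalid rows (one row-numbered
  diagnostic per bad row) instead of aborting; `strict=True` turns the
  report into an error. When both a birth-date and an age column are
  mapped, the birth date wins with a logged warning.
- Same-day duplicate draws count as repeat measurement by default (they
  signal monitoring); `collapse_same_day` collapses them first.

## Recovery tolerance

Parameter-recovery checks compare pipeline limits against the generator's
true mean ± 1.96·SD at study-scale stratum sizes. The sampling SE of
x̄ + 1.96·s at n ≈ 500 and σ ≈ 0.08 mg/dL is ≈ 0.006–0.008 mg/dL, so exact
agreement of 2-decimal rounded limits is not a meaningful target; the
package's recovery criterion is agreement within **0.02 mg/dL** per limit,
which the clean pipeline meets in ≥ 34/36 strata (median over seeds) and
which contamination confined to repeat-measured individuals does not
degrade — the single-measurement exclusion is doing exactly the work the
design assigns it. The per-stratum fence on clean normal data trims the
top ≈ 0.3–0.4% and biases the URL down by ≈ 0.02·σ (≈ 0.002 mg/dL),
well inside that tolerance.

Recomputing published limits from *printed* (already rounded) means and
SDs carries a double-rounding drift of up to 0.005 + 1.96·0.005 ≈ 0.015
mg/dL, i.e. up to two printed cents; the worked-example tests assert
exactness only for self-consistent rows and the two-cent bound elsewhere.

## Known limitations

- Adjacent strata whose true URLs are nearly tied (e.g. late-adolescent
  males, where growth plateaus) can show spurious one-cent reversions in
  finite samples; the reversion report flags them without judging cause.
- The sensitivity comparison expects both estimate sets to cover the same
  strata; on very small cohorts a stratum can empty out after excluding
  flagged individuals, and the comparison is then skipped with a warning.
- Multiplicity counting happens within whatever records are supplied; if
  an extract is already deduplicated or truncated, the single-measurement
  exclusion silently weakens. The flow summary's retrieved-counts stage
  exists to make such upstream filtering visible.
- mg/dL only; µmol/L conversion is deliberately not provided.
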
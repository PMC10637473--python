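# Methods

## Counting model

The unit of counting is the distinct case report. Rows or records sharing a
`case_id` are merged before analysis: drug and reaction mentions are
unioned (no mention is ever lost), and conflicting non-unknown sex values
collapse to `unknown` with a warning — a conservative rule, since the
alternative (picking one sex) would silently move a report between strata.
A report mentioning a reaction twice counts once.

For a pair (drug D, reaction R) in stratum s the sufficient statistics are
`N_observed`, `N_drug`, `N_reaction`, `N_total`, all restricted to reports
of that stratum. Stratified analyses are *fully within-stratum*: this is
the standard subgroup disproportionality design and the only one under
which the male and female estimates are independent comparisons.
Sex-unknown reports are excluded from the male and female strata but
contribute to `all`. The 2×2 cells a = N_observed, b = N_drug − a,
c = N_reaction − a, d = N_total − N_drug − N_reaction + a always sum to
N_total with d ≥ 0 on report-derived counts.

## Information component

    IC    = log₂((N_observed + 0.5) / (N_expected + 0.5)),
    N_expected = N_drug · N_reaction / N_total.

The ±0.5 shrinkage pulls sparse pairs toward IC = 0, which is what makes
the measure usable at the very low expected counts typical of large
spontaneous-reporting databases. IC is exactly 0 when observed equals
expected and strictly monotone (increasing in N_observed, decreasing in
N_expected); scaling both counts by k → ∞ recovers the unshrunken
log₂(N_observed/N_expected).

Credibility bounds: the relative reporting rate λ is given the posterior
Gamma(shape = N_observed + 0.5, rate = N_expected + 0.5), whose mean
reproduces the shrunken point ratio; IC025 and IC975 are log₂ of the exact
2.5% and 97.5% gamma quantiles (`scipy.stats.gamma.ppf`). A normal
approximation on the log scale (mean digamma(shape) − log(rate), variance
trigamma(shape)) is available via `interval_method="normal"` for
comparison; it agrees with the exact quantiles to well under 0.01 IC units
once counts reach a few hundred. The signal criterion is IC025 > 0.

The gamma-quantile path is validated against an *independent* Monte-Carlo
oracle (empirical quantiles of 10⁶ posterior draws) on a 12-point grid
n_obs ∈ {1, 5, 40, 500} × N_exp ∈ {0.5, 8, 100}. At n_obs = 1 the oracle's
own quantile standard error is ≈ 0.006 IC units — the same order as the
0.01 comparison band — so the check allows the band plus three
batch-estimated oracle standard errors; the excess is oracle noise, not
implementation error.

NA convention: a stratum with zero observed reports for the pair carries
NaN IC fields and renders as the literal `NA` (matching the convention of
publication tables where a pair unreported in one sex shows a whole-row
NA); an entirely empty stratum likewise renders NA in comparison tables.

## ROR and PRR

ROR = (a·d)/(b·c) and PRR = (a/N_drug)/(c/(N_total − N_drug)) with
log-normal Wald 95% intervals. A zero cell (ROR) or zero a/c (PRR)
triggers the Haldane–Anscombe +0.5 correction on all four cells, flagged in
the output. PRR is undefined when the drug accounts for the whole stratum.
On large tables with the drug a small share of the database, ROR, PRR and
2^IC estimate the same relative reporting rate and agree within a few
percent; they diverge exactly where shrinkage or the odds/risk distinction
matters (small expected counts, non-rare drug share).

## Sex-pattern classification

The operational definition of "stronger in one sex" is interval
separation: signal in that sex and either no signal in the other or the
first sex's IC025 above the other's IC975. This is deliberately
conservative — overlapping credibility intervals with signals in both
sexes classify as `both_equal`, not as a difference. `male_only` /
`female_only` require the pair to be entirely unreported (NA) in the other
sex. The classifier is antisymmetric by construction and total: every row
gets exactly one label.

## Synthetic data generator

The generator emulates the structure of a global spontaneous-reporting
database: per report, a sex from (male, female, unknown) =
(0.45, 0.51, 0.04) — a slight female reporting excess with a few percent
missing sex, as seen in real pharmacovigilance data —, exactly one primary
suspect drug from a 20-drug catalog in which the drug of interest holds a
1% share, and k reactions, k ~ Geometric(mean 2.5) truncated to the
catalog size, drawn without replacement from a 40-PT catalog with a
common-head/rare-tail weight profile (≈ 2.5 reactions per report matches
the ratio of ADR mentions to distinct reports in large published
analyses). Weighted sampling without replacement uses the exponential-race
construction (sort Exp(1)/w_j, take the first k), equivalent to successive
sampling proportional to remaining weights.

Planted signals are multiplicative: for reports carrying the signal drug in
the given sex stratum, the signal PT's inclusion probability becomes
clamp(ρ · q), where q is the PT's background inclusion probability. q has
no closed form under the race scheme, so it is calibrated once per
(weights, mean) by a 200,000-draw Monte Carlo with a fixed internal seed
(cached; dataset generation remains a deterministic function of the config
seed). Clamped inclusions are counted and logged. ρ = 0 removes all
co-occurrences; a report left reaction-less by such thinning is backfilled
with the most common non-excluded background PT so the non-empty-reactions
invariant holds.

Under this model the IC's asymptotic target for a planted pair is
log₂ ρ up to a contamination factor 1 + f_drug(ρ − 1) entering
N_reaction (the drug's own inflated reports), i.e. a downward bias of
≈ 0.10 IC units at ρ = 8 with f_drug = 0.01 — the reason the default
catalog keeps the drug of interest at a 1% share. `true_ic` returns the
uncontaminated log₂ ρ; recovery checks use a 0.3 IC-unit band that
comfortably covers bias plus sampling noise at 200,000 reports with
expected pair counts ≥ 50. Reports with unknown sex receive no signal
injection (ρ is defined per sex stratum).

What the generator does *not* emulate: reporting-delay dynamics, country
and reporter effects, age strata, polypharmacy (one suspect drug per
report), drug-name variants, and masking/competition between signals.
Passing tests therefore show the statistics and classifier are correct
under the stated generative model, not that real-data biases (duplicate
reporting beyond the simple duplication knob, stimulated reporting,
confounding by indication) are handled.

## Problem sizes and calibration checks

The validation suite runs the pipeline at study-like sizes chosen to make
the statistical checks sharp while keeping a laptop run short: type-I
calibration on ten null databases of 100,000 reports (pooled
P(IC025 > 0) ≈ 0.015 — below the nominal one-sided 2.5% because count
discreteness makes the gamma criterion conservative at small expected
counts); planted-ρ recovery on twenty databases of 200,000 reports with
ρ ∈ {2, 8} and a male-specific ρ_m = 8 / ρ_f = 1 signal for pattern
classification.

## Numerical and interface choices

- Display rounding is 2 decimals for comparison tables (1 decimal for
  percentages, 2 for the female:male ratio); all internal computation is
  full precision, and displayed values are recomputed from stored counts.
- Summary statistics store the sexed count separately from the per-sex
  counts: report-level counting gives n_with_sex = n_female + n_male, but
  entity-level published summaries can have overlapping per-sex counts.
- CSV outputs are UTF-8, comma-separated, "." decimal, literal `NA` for
  missing statistics; column orders are fixed. Provenance records omit
  timestamps so reruns are byte-identical.
- Sex vocabulary accepted on input: {M, F, male, female, 1, 2, "", NA}
  case-insensitively; anything else maps to unknown with a warning.
- The PT→SOC map is a two-level mono-hierarchy; the bundled 40-term CSV is
  a mock covering common atopic-therapy ADRs (the licensed MedDRA
  dictionary cannot ship). Unmapped PTs resolve to an `UNMAPPED` sentinel,
  never dropped.

## Known limitations

- The multiplicative injection model keeps true IC = log₂ ρ only while
  ρ · q ≤ 1 and the signal drug's share is small; both are logged/checked
  rather than silently violated.
- No multiple-comparison adjustment across reactions is applied (standard
  practice for IC-based screening, which treats flags as hypotheses, not
  confirmations).
- Drug names are matched exactly; no normalization of salts, brands or
  spelling variants.
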
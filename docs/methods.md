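# Methods

## Design

`otcscan` analyses an observational case-control cohort in which the
exposure record is a retail loyalty-card transaction log: dated item-level
purchases in retailer-defined categories (pain, indigestion, and other
health/beauty/grocery categories). Cases are participants diagnosed with
ovarian cancer; the diagnosis month anchors all time axes. The analysis asks
whether purchases of symptom-relief categories rise in cases before
diagnosis, and how early that rise is detectable.

### Matching and alignment

Each case is matched to `ratio` (default 2) controls drawn from the exact
loyalty-card stratum (HSR1 only / HSR2 only / both — "both" is its own
stratum, not a superset), choosing the controls nearest in age. Matching is
with replacement: a control may serve several cases, and each appearance is
an independent stratum member downstream. There is no age caliper by
default; matched-pair age gaps of a few tenths of a year are typical at
realistic pool sizes, and a caliper option exists for sparser pools. Ties in
age distance break on the smaller participant id and cases are processed in
id order; with replacement, per-case nearest selection is already globally
optimal, so the processing order does not change the result — the rule
exists purely for determinism and is recorded in the match report.

Relative months run −24…−1; the diagnosis month itself is excluded. A
control contributes the case's calendar window when its data availability
covers it entirely, otherwise its own latest 24 available months; the rule
applied is stored per control per set. Controls with under 24 months of data
are an error unless truncation is explicitly enabled.

### Enrichment scan

Counts are summed on a sliding 3-month window, centred (m−1, m, m+1) and
truncated at the −24/−1 boundaries (trailing windows are an option). At each
month the 2×2 table pools purchase events over members: rows case/control,
columns target-category purchases vs all other purchases. The target is the
union of the pain and indigestion categories by default; a strict
co-occurrence variant (counting only member-months where both categories
were purchased) approximates "bought together" when receipt-level data are
absent — basket composition is not modelled, so same-transaction
co-purchase cannot be expressed. A per-participant table variant
(purchaser yes/no) is available because pooled-event and per-participant
constructions answer subtly different questions; pooled events are the
default since the scan compares *all purchases* with target purchases.

The odds ratio is the conditional maximum-likelihood estimate of the
noncentral hypergeometric ψ (scipy's exact machinery), with the exact
test-inversion 95% CI; a sample ad/bc odds ratio with Woolf CI is a flag.
Zero cells yield ψ̂ ∈ {0, ∞} and are reported as such, flagged degenerate.
No multiple-testing correction is applied across the 24 months by default
(a Bonferroni column is optional) — the scan is descriptive, reporting the
month of maximum discrimination.

**Calibration caveat.** Under with-replacement matching a reused control's
purchases enter the pooled table once per appearance. The per-month exact
test then sees duplicated pseudo-observations, and the scan is mildly
anti-conservative under the null even with Poisson purchases (for which the
exact test would otherwise be exactly valid). The null-calibration
experiment in the acceptance script quantifies this: per-month rejection
rates stay within binomial error of the nominal 5% at the replicate counts
used, but the aggregate rate runs a couple of points above nominal. The
conditional logistic regression does not share this problem — each
appearance is its own stratum, which the conditional likelihood handles
correctly.

### Conditional logistic regression

For a stratum s with one case among m+1 members, the conditional likelihood
contribution is exp(x_case·β) / Σ_{j∈s} exp(x_j·β); the model maximises
ℓ(β) = Σ_s [x_case·β − log Σ_j exp(x_j·β)] with analytic gradient and
Hessian, log-sum-exp stabilisation, Newton–Raphson with step-halving from
β = 0, convergence at max |∇ℓ| < 1e-8 (or relative ℓ-change < 1e-10 with
the gradient below 1e-6), capped at 50 iterations. Standard errors come
from the inverse observed information; CIs are Wald on the log scale,
exponentiated (profile CIs are not implemented). Covariates constant within
every stratum cancel from the likelihood; they are detected (within-stratum
deviation < 1e-12), pinned at 0 and flagged rather than fitted. Complete
separation is flagged when a coefficient passes 15 on the log-OR scale
during iteration or when the conditional likelihood approaches its
supremum of 0 (the case predicted perfectly in every stratum); flagged fits
carry no standard errors.

The month-wise scan uses the 3-month-window count of the chosen categories
as the exposure (matching the Fisher scan's smoothing; single-month and
binary any-purchase exposures are flags), plus cumulative fits of mean
monthly purchases over the last 6/12/24 months. Adjustment covariates:
OC ever-use, household size, GP visits, any-symptom indicator, season of
the member's own window month (4-level, winter baseline — each member's
calendar window may differ), a COVID-era indicator (window month ≥
March 2020), and the additive risk score. Missing adjustment values are
median-filled inside the scan; impute upstream (kNN) for anything better.

### Risk score and imputation

The additive score is Σ_f coef[stratum][f] × value_f over 16 risk factors
(aspirin use, BMI, breastfeeding ever and months, endometriosis, family
histories, hysterectomy without HRT, pregnancy and menarche timing
variables, menopausal status, OC use and duration, tubal ligation), with
coefficients per age stratum (<50 / ≥50). The per-unit median log odds
ratios are **not** derivable from this package — the shipped defaults are
illustrative placeholders with plausible signs; supply calibrated values
via YAML for real use.

Missing factors are imputed by kNN (k = 5) under the Gower distance: mean
per-field dissimilarity over fields observed in both records, |Δ|/range for
numeric and 0/1 for categorical fields. Donors must observe the target
field; numeric cells take the donor median, categorical cells the donor
mode with mode ties resolved by the nearest donor; distance ties break on
row order, so imputation is deterministic. A record pair sharing no
observed field gets distance 1 (maximally dissimilar) rather than being
excluded, so fully missing records remain imputable. k, the distance and
the aggregation rule are conventions of this implementation (the upstream
study names only the imputation package it used, not its settings) and are
configurable.

Tertile groups use the 1/3 and 2/3 empirical quantiles (linear
interpolation) of the **controls'** scores, with intervals (−∞, q1],
(q1, q2], (q2, ∞). The quantile definition matters near cutpoints and is
therefore fixed and documented.

### ROC scans

The score at month m is the cumulative category count from −24 through m
(the tightening of discrimination toward diagnosis under accumulating
exposure motivates this default; single-month and window scores are flags).
Analyses restrict to members who purchased the category at all in the
24-month window. AUC is Mann–Whitney with midranks — P(case > control) +
½ P(tie) — and the 95% CI uses the DeLong structural-component variance
with normal approximation, truncated to [0, 1]; degenerate variance (all
ties or perfect separation) collapses the CI and is flagged, and a seeded
stratified bootstrap is the fallback. Stage stratification subsets cases
only (stages 1–2 early, 3–4 late) against the identical restricted control
pool; controls carry no stage.

## Synthetic data

The generator emulates: per-arm age distributions (defaults: cases mean
64.7 SD 10.9 years, controls 51.6 SD 13.7 — the published cohort's
characteristics); loyalty-card ownership shares per arm; a questionnaire
with correlated risk factors (parity cluster, OC pair, age-linked
menopause); stage at diagnosis (defaults weighted to late stage, as
observed clinically); monthly purchase counts per category that are Poisson
by default (negative binomial via the `dispersion` parameter) with a
sinusoidal seasonal factor (amplitude 0.2, peak January — cold/flu season),
a household-size rate multiplier (1.15 per additional member), and an
injected pain/indigestion elevation in cases covering the `signal_onset`
(default 8) months before diagnosis at `signal_ratio` (default 3). The
signal is flat over that interval by default (`signal_shape="constant"`,
which makes the injected rate ratio directly interpretable); the
`"peaked"` shape instead decays linearly from the full ratio at the onset
month toward diagnosis, emulating a discrimination hump whose timing a scan
can meaningfully recover — under a flat signal every fully-covered window
is equally enriched and the argmax month is noise. Baseline purchase
frequencies are illustrative (about 8.7 items/month across six categories,
dominated by a generic "other" category): real retailer category rates are
not public and nothing here is calibrated to them.

Not emulated: item-level SKUs, prices, basket/receipt composition,
retailer-specific category taxonomies, card non-use (all purchases are
observed), behavioural feedback (e.g. reduced self-medication after
presenting to primary care), and recruitment logistics. Passing recovery
tests therefore show that the analysis machinery detects the signal it was
given under the stated count model — not that real purchase data carry
such a signal.

Missingness is MCAR by default with a MAR-by-age option. All randomness
flows from one root seed through named substreams; identical seeds give
byte-identical CSVs.

## Problem sizes

The calibration and recovery experiments are sized for a single CPU: the
CLR simulation uses 500 strata × 200 replicates (bias and coverage
estimates with Monte-Carlo SE ≈ 0.003 and 1.5 points respectively); the
enrichment-scan recovery uses 100 cohorts of 150 cases + 300 controls and
the null calibration 60 cohorts; DeLong coverage uses 500 binormal
simulations at 60 + 80 scores; the exact-test enumeration covers every 2×2
table up to total 24–30 depending on the check, with conditional-MLE
root-finding on the denser sub-grid where it dominates the cost.

## Known limitations

- The Fisher scan's pooled-event table treats reused controls as
  independent (see the calibration caveat above); interpret the scan as
  descriptive and lean on the CLR for inference.
- Wald CIs can misbehave near separation; separation is flagged but no
  penalised (Firth-type) fallback is provided.
- The risk-score coefficients are placeholders; tertile labels on default
  coefficients order participants sensibly but carry no absolute meaning.
- "Bought together" is approximated at month granularity; receipt-level
  co-purchase is out of reach of the data model.
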
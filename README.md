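# otcscan

Pre-diagnostic signal detection in over-the-counter (OTC) medication
purchase histories, for epidemiologists studying whether routinely collected
retail loyalty-card data can flag cancers — here ovarian cancer — months
before clinical diagnosis.

Women later diagnosed with ovarian cancer often self-medicate nonspecific
symptoms (abdominal pain, bloating, indigestion) long before presenting to
primary care. `otcscan` implements the analytical pipeline of a matched
case-control design over per-category monthly purchase counts, together with
a synthetic transaction generator that stands in for the confidential
retailer data such studies run on:

1. **Cohort assembly** — eligibility exclusions with CONSORT-style flow
   accounting; 2:1 nearest-age matching *with replacement* within exact
   loyalty-card strata; alignment of each member's purchases onto relative
   months −24…−1 before the case's diagnosis (controls use the case's
   calendar window when their data cover it, else their own latest
   24 months).
2. **Enrichment scan** — purchases summed on a sliding 3-month window; at
   each month a 2×2 table (case/control × target/other purchases) is tested
   with Fisher's exact test. The odds ratio is the conditional
   maximum-likelihood estimate ψ̂ of the noncentral hypergeometric model,
   with test-inversion 95% CI.
3. **Conditional logistic regression (CLR)** — for 1:2 matched strata the
   conditional likelihood
   ℓ(β) = Σ_s [x_case·β − log Σ_{j∈s} exp(x_j·β)]
   is maximised by Newton–Raphson (implemented here from scratch, with
   identifiability and separation diagnostics). Month-wise scans use the
   window purchase count as exposure, with adjustment sets for OC use,
   household size, season, COVID era, GP attendance, symptoms, and the risk
   score.
4. **Risk score** — additive score Σ_f (median log OR_f) × value_f over 16
   ovarian-cancer risk factors, age-stratified at 50, with mixed-type
   Gower-distance kNN imputation of missing factors and low/medium/high
   groups cut at control-only tertiles.
5. **ROC scans** — month-wise Mann–Whitney AUC of cumulative purchase
   counts among purchasers, with DeLong 95% CIs and stage stratification
   (stages 1–2 early vs 3–4 late).

The generator draws Poisson (or negative-binomial) monthly counts per
category with seasonality, household-size effects, and an injected elevation
of pain/indigestion purchase rates in cases starting a configurable number
of months before diagnosis, plus full ground truth for recovery experiments.

## Worked example

```python
import otcscan as o

cfg = o.PipelineConfig(
    sim=o.SimConfig(n_cases=60, n_controls=180, seed=7,
                    signal_shape="peaked"),   # hump peaking 8 months out
    seed=7, out_dir="demo")
res = o.run_pipeline(cfg)
print(res["summary"])
```

prints

```
otcscan pipeline summary
==============================
eligible: 51 cases, 164 controls
matched sets: 51 (102 control slots, 50 unique controls); median age diff 0.2 y (IQR -0.4 to 0.9)
maximum discrimination at month -7: OR 2.75 (95% CI 2.35-3.23), p=9.64e-38
months with p<0.05: 13/24; after Bonferroni: 9/24
CLR combined: earliest month with CI>1: -24
CLR pain: earliest month with CI>1: -9
CLR indigestion: earliest month with CI>1: -24
ROC scan (cumulative score, purchaser-restricted)
  all: max AUC 0.678 (95% CI 0.585-0.771) at month -2
  ...
```

Reading this: of the 60 simulated cases, 51 survive the eligibility
exclusions; each is matched to the two nearest-age controls holding the same
loyalty cards (controls may repeat, hence 102 slots from 50 unique
individuals). The injected pain/indigestion elevation — a three-fold rate
ratio peaking 8 months before diagnosis — is picked up by the Fisher scan as
maximum discrimination at month −7 (the 3-month window centred there covers
months −8…−6, where the injected elevation is strongest), and by the
purchaser-restricted ROC scan as AUCs well above 0.5 in the final year. The
first three rows of `res["enrichment"].table` are the per-month 2×2 cells
with ψ̂, CI and exact p:

```
 month   a    b   c    d       or    ci_lo    ci_hi        p
   -24 106  977 164 2018 1.334900 1.023056 1.736196 0.030648
   -23 158 1451 258 3065 1.293531 1.043939 1.599097 0.016173
   -22 173 1497 261 3194 1.414126 1.148651 1.737790 0.000890
```

The same pipeline runs from the shell:

```bash
otcscan simulate --out demo --seed 7
otcscan match --roster demo/roster.csv --out demo
otcscan scan --transactions demo/transactions.csv --matched demo/matched_sets.csv
otcscan run --config pipeline.yaml
```

Every run writes `roster.csv`, `transactions.csv`, `matched_sets.csv`,
`flow_report.json`, `enrichment_scan.csv`, `clr_scan.csv`, `roc_scan.csv`,
`risk_scores.csv`, `risk_table.csv` and a `run_manifest.json` recording the
seed, config hash and every analysis flag. Results objects expose
`.summary()` and `.plot()`.

See `docs/methods.md` for the statistical model, default parameters, and
what the synthetic data do and do not emulate.

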
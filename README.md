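# disweights

Derivation of **disability weights** — the 0-to-1 severity values that turn
disease prevalence into years lived with disability (YLD) in burden-of-disease
studies — from **paired-comparison** health-state valuation surveys, as done in
national disability-weight measurement studies such as the Dutch one.

In a paired-comparison survey each respondent sees two hypothetical persons
with different health states and indicates which one they regard as healthier.
Under Thurstone's law of comparative judgment, state *i* carries a latent
severity β<sub>i</sub> and the first-listed state is judged healthier with
probability

&nbsp;&nbsp;&nbsp;&nbsp;P(first healthier) = Φ(β<sub>second</sub> − β<sub>first</sub>),

which is a probit regression on a signed incidence design (+1 for the
first-listed state, −1 for the second, one reference state fixed at 0).  The
fitted β are on an arbitrary latent scale; they are *anchored* onto the 0-to-1
disability-weight scale by a loess regression of logit-transformed reference
weights (from the GBD 2013 disability-weight study) on β over the anchor
states, followed by an inverse-logit back-transform.  95% uncertainty
intervals come from a parametric bootstrap: each state's coefficient is
redrawn from Normal(β̂, SE), the loess is refitted, and the 2.5th/97.5th
percentiles of the back-transformed replicate weights are reported.

The package provides, as importable modules and a thin `disweights` CLI:

- `data_model` — domain types, CSV interchange, and a packaged transcription
  of the published Dutch weight table (203 states, 0.007–0.741);
- `synthetic_data` — a survey simulator with the study's exact design
  (18 tasks, the 2nd pair repeated at the 15th in same/reverse order,
  demographics at the study sample's marginals, choice noise calibrated to
  the observed test-retest consistency);
- `probit_engine` — the signed design, Newton probit MLE with
  observed-information standard errors, response-probability heatmap matrix;
- `anchoring` — loess anchor, bootstrap, uncertainty-interval summaries;
- `reliability` — test-retest consistency probabilities and Cohen's κ;
- `cohort_analytics` — subgroup homogeneity (Spearman correlations of
  per-level probit coefficients) and cross-study weight-set comparison.

## Worked example

Simulate a 500-respondent survey over the packaged catalog (published
weights as ground truth), estimate anchored weights, and inspect them:

```python
import disweights as dw

catalog = dw.table2_catalog()
config = dw.SimulationConfig(n_respondents=500, seed=42)
respondents, responses = dw.simulate_survey(catalog, config)

report = dw.test_retest_report(responses)
print(f"same-order consistency {report.p_consistent_same:.3f} "
      f"(kappa {report.kappa_same:.3f}, {report.agreement_same})")

design = dw.build_design(responses, states=[s.state_id for s in catalog])
fit = dw.fit_probit(design)
model = dw.fit_anchor(fit, catalog)
ensemble = dw.bootstrap_weights(fit, model, n_replicates=1000, seed=1)
estimates = {e.state_id: e for e in dw.summarize_weights(ensemble)}
for sid in ("distance_vision_mild_impairment", "neck_pain_moderate",
            "intensive_care_unit_admission"):
    e = estimates[sid]
    print(f"{sid}: {e.dw:.3f} (95%UI {e.ui_low:.3f}-{e.ui_high:.3f})")
```

which prints:

```
same-order consistency 0.734 (kappa 0.469, moderate agreement)
distance_vision_mild_impairment: 0.005 (95%UI 0.003-0.009)
neck_pain_moderate: 0.135 (95%UI 0.082-0.217)
intensive_care_unit_admission: 0.734 (95%UI 0.567-0.847)
```

With only 500 respondents the recovered weights already sit close to the
generating values (0.007, 0.146 and 0.741 respectively); at the full study
size of 3994 respondents the rank correlation with the truth exceeds 0.99.
The same pipeline is available from the shell:

```sh
disweights simulate --seed 42 --n-respondents 500 --out-dir survey/
disweights estimate --catalog survey/catalog.csv \
    --responses survey/responses.csv --out-dir results/
disweights reliability --responses survey/responses.csv --out retest.csv
```

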
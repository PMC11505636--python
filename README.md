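# icrkit

Pediatric caries-risk scoring and instrument comparison.

Caries risk assessment (CRA) tools help dentists identify children at high
risk of developing dental caries. The established Cariogram software is
effective but needs salivary sampling and a computer model; the **Index of
Caries Risk (ICR)** is a simpler questionnaire-based instrument for
children aged 6–12. `icrkit` implements the ICR scoring engine, the
conversion of external Cariogram outputs onto a common risk scale, the
concordance statistics used to compare the two instruments, and a seeded
synthetic-cohort simulator so the entire comparison pipeline runs without
real patient data. It is aimed at dental epidemiologists and
methodologists who want to score cohorts, run method-comparison analyses,
or simulate study designs.

## The instrument and the statistics

The ICR scores eight ordinal items — diet content, diet frequency, oral
hygiene habits, fluoride program, family susceptibility, caries
experience, oral hygiene status, and a salivary pH litmus test — each at
one of four levels (0 = lowest risk). The total is the sum of the item
points,

&nbsp;&nbsp;&nbsp;&nbsp;ICR = Σⱼ sⱼ ,  sⱼ ∈ {0, 1, 2, 3},

binned as Low (0–5), Moderate (6–10), High (11–15) or Very High (16–max).
The Cariogram reports a "chance of avoiding caries" percentage *c*; for
comparison it is mapped to the risk value 100 − *c* and binned
High (0–25), Moderate (26–75), Low (76–100) on the chance scale.

Concordance between instruments is quantified with Pearson's *r* (exact
*t*-based p-value, Fisher-z confidence interval), Cohen's κ (unweighted,
linear or quadratic weights, delta-method or bootstrap CI), category
cross-tabulations, and the Fisher-z sample-size formula for detecting a
target correlation. The simulator draws a latent risk factor per child
and thresholds loaded Gaussian variables at probit cuts so every item
matches a configured marginal distribution (a one-factor Gaussian
copula); the Cariogram value is a monotone noisy transform of the same
latent factor, with the coupling calibrated by bisection to hit a target
score–risk correlation.

## Worked example

Simulate a study-sized cohort (69 enrolled, 14 lost to follow-up), then
compare the two instruments:

```bash
icr simulate --config sim.yaml --out cohort.csv --dropout
icr compare --in cohort.csv
```

with `sim.yaml` holding a `CohortConfig` (here seed 17 and a fixed
coupling slope of 0.95). The comparison prints:

```
Cohort comparison (N = 55)

ICR total score: M = 12.7 (SD = 4.4), range 5-24
Cariogram risk value: M = 48.9% (SD = 26.1%), range 1%-100%

Caries risk by Cariogram (N = 55)
Risk             n       %
Low             11      20
Moderate        34      62
High            10      18
Total           55

Caries risk by ICR (N = 55)
Risk             n       %
Low              3       5
Moderate        15      27
High            25      45
Very High       12      22
Total           55

Caries risk assessed merged (rows: ICR, columns: Cariogram)
                   Low  Moderate      High     Total
Low                  3         0         0         3
Moderate             5        10         0        15
High                 3        20         2        25
Very High            0         4         8        12
Total               11        34        10        55

Pearson correlation (ICR total vs Cariogram risk): R = 0.83 (p = 6.75e-15, 95% CI 0.72-0.90, n = 55)
```

Fifty-five children remain after dropout; each one-way table gives the
category counts and rounded percentages; the merged table cross-tabulates
the two instruments' categories (its margins reproduce the one-way
counts); and the correlation row measures how strongly the ICR total
tracks the Cariogram risk value — here R = 0.83 at n = 55, scattered
around the coupling the simulator was given.

The same pipeline is available as library calls:

```python
from icrkit import CohortConfig, emulate_study
report = emulate_study(CohortConfig(seed=17, cariogram_slope=0.95, target_corr=None))
print(report.correlation.r, report.n)
```

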
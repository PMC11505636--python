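# Methods

## The scoring model

The ICR instrument is a deterministic sum score. Each of the eight items
(`diet_content`, `diet_frequency`, `hygiene_habits`, `fluoride_program`,
`family_susceptibility`, `caries_experience`, `oral_hygiene_status`,
`ph_test`) has four ordered levels; level 0 always awards 0 points and
points are non-decreasing in level. The shipped default scheme awards
0, 1, 2, 3 uniformly, giving a theoretical maximum of 24. The published
category bins (Low 0–5, Moderate 6–10, High 11–15, Very High 16–21)
quote a maximum of 21, which is inconsistent with eight four-level items
under any uniform points map; the instrument's original per-item point
values are not public. We therefore keep the uniform 0–3 default, extend
the Very High bin to the scheme maximum (16–24), and make both the points
map and the bins overridable via a YAML scheme file — a custom scheme
with a published points map reproduces any instrument variant exactly.
Records missing any item are rejected, never imputed: the instrument is
defined on complete questionnaires.

### Raw-measurement binning

Where a cohort file carries raw measurements instead of pre-coded levels,
the defaults are: mean daily sugar exposures ≤1 / ≤3 / ≤5 / >5 → levels
0–3; meals per day ≤3 / ≤5 / ≤7 / >7; combined caries + restoration +
missing-tooth count 0 / 1–2 / 3–4 / ≥5 (the published level descriptions
overlap at 2 and 4; we resolve the overlap in favour of the lower level);
salivary pH >7 → 0, 7 ± 0.25 → 1 (litmus-strip resolution; this also
covers the otherwise-unassigned (6.5, 7) gap down to 6.75), [5.5, 6.75) →
2, <5.5 → 3. Parent caries status pairs are treated as an unordered
multiset ordered by severity (− < + < ++): (−,−) → 0, worst parent + → 1,
worst parent ++ → 2 unless both are ++ → 3; unlisted combinations map to
the highest listed pattern they dominate. All edges live in
`MeasurementRules` and are configurable; these gaps and overlaps are
instrument ambiguities, not modelling claims.

## Cariogram interoperability

The Cariogram algorithm itself is out of scope; its "chance of avoiding
caries" percentage is an input. The risk value is the complement
100 − chance. Two category boundary conventions circulate: closed integer
bins on the chance scale (High 0–25, Moderate 26–75, Low 76–100) and open
boundaries (<25 / 25–75 / >75). The default is the closed-bin form, which
is the one used to tabulate results in practice, extended to non-integer
values as [0, 25.5) / [25.5, 75.5) / [75.5, 100] — consistent with
rounding to the nearest integer first. The open-boundary form is
available via `convention="strict"`; which convention a given study used
is generally unknowable from its tables, so neither is asserted as "the"
truth and the two differ only at chance values 25, 75 and the
fractional boundary neighbourhoods.

## Concordance statistics

* **Descriptives** are sample mean, SD (n−1 denominator), min, max. A
  single observation gets SD 0 with an explicit `degenerate` flag rather
  than an undefined value, keeping pipelines total without hiding the
  degeneracy.
* **Percent rounding** is half-away-from-zero (14.545% → 15% at 0
  decimals), the convention that reproduces clinical tables; Python's
  built-in banker's rounding does not.
* **Pearson correlation** comes from `scipy.stats.pearsonr`: exact
  two-sided p (equivalent to the t statistic with n−2 df) and a Fisher-z
  confidence interval. The exact p is reported; "p < 0.01"-style
  statements are a rendering concern.
* **Cohen's kappa** is delegated to
  `statsmodels.stats.inter_rater.cohens_kappa` (unweighted, linear =
  Cicchetti–Allison, quadratic = Fleiss–Cohen), with the delta-method
  asymptotic CI by default and a seeded percentile bootstrap behind a
  flag (the CI method used in any given published calibration is rarely
  stated). Kappa is only defined on a shared label set: comparing a
  4-category instrument with a 3-category one requires an explicit
  `collapse_categories` map; none is applied silently.
* **Sample size for a correlation** uses the Fisher-z approximation with
  the finite-sample mean correction E[z] ≈ atanh(ρ) + ρ/(2(n−1)),
  returning the smallest n whose approximate power reaches the target.
  This reproduces the classic design-table values (n = 13 for ρ = 0.7,
  n = 29 for ρ = 0.5 at α = 0.05, power 0.80) and agrees with
  Monte-Carlo power within ±1 subject for ρ ∈ {0.3, 0.5, 0.7}; the
  uncorrected formula is systematically one subject conservative.
* No multiple-testing correction is applied anywhere: the comparison
  design has one pre-specified correlation.

## The synthetic cohort generator

The generator emulates a two-instrument pediatric comparison study for
which no raw data are deposited. Per child, a latent risk factor
L ~ N(0,1) drives everything:

* **Items**: Uⱼ = λⱼL + √(1−λⱼ²)·εⱼ thresholded at probit cuts from each
  item's cumulative marginal — a one-factor Gaussian copula. Default
  marginals are the observed per-item level distributions of a 55-child
  cohort (entered as counts/55). This is the minimal dependence
  structure that can match both the marginals and a single observed
  inter-instrument correlation; the true inter-item correlation
  structure of any real cohort is unreported, so the one-factor form is
  a modelling choice, not an inference.
* **Loading default λ = 0.75** (uniform, per-item configurable). The
  discreteness of the items and the loadings cap the achievable
  score–risk correlation; measured ceilings are ≈0.84 at λ = 0.6, ≈0.91
  at λ = 0.75. A default of 0.75 is the smallest round loading that
  supports the default calibration target of 0.88 with headroom while
  keeping the simulated score SD (≈4.5) and Cariogram risk SD (≈28.9)
  near values reported for real cohorts (4.0 and 28.0).
* **Cariogram**: chance = 100·Φ(−(s·L + σ·η)). With σ defaulting to
  √(1−s²), the marginal chance is approximately uniform on (0,100)
  (mean 50, SD 28.9). The coupling s is calibrated by bisection on
  [0, 1] at n = 100,000 with common random numbers (so the achieved
  correlation is a deterministic, monotone function of s and bisection is
  safe) until corr(ICR total, risk) is within 0.005 of the target;
  an unattainable target raises an error reporting the measured ceiling.
  The Cariogram algorithm is *not* simulated — only the observable
  coupling is.
* **Demographics**: age uniform on 6–12 years, sex balanced by
  permutation. They are cosmetic — no analysis stratifies on them.
* **Dropout**: either an exact count (default 14 of 69 enrolled, leaving
  55 analyzed, matching the reference study's attrition) or i.i.d.
  Bernoulli(14/69) for scaled cohorts.
* **Randomness**: one root seed; each stage (latent, items, Cariogram,
  age, sex, dropout) uses its own `SeedSequence` child stream, so adding
  a stage never perturbs earlier draws and every output is reproducible
  from the seed. Cohort CSVs embed the seed and a config hash in a
  comment header.

What passing simulator-based tests shows: the scoring, categorization and
concordance machinery is correct on cohorts whose marginals and coupling
match the configured targets. What it does not show: that real pediatric
cohorts follow a one-factor Gaussian copula, that item marginals
generalize across populations, or that the ICR predicts caries outcomes —
the instrument is a prediction model only, and outcome validation needs a
prospective study.

## Numerical and interface choices

* Simulation sizes in tests: marginal recovery at n = 10,000 (TV
  tolerance 0.02 ≈ 4 binomial SEs), calibration self-consistency at
  n = 100,000 (±0.02), Monte-Carlo power at 20,000 replicates — sizes at
  which sampling error is well below the asserted tolerances and the
  whole suite runs in seconds.
* Probit cuts for zero-probability levels are ±∞; such levels are simply
  never drawn (e.g. the two empty fluoride levels).
* CSV dialect: comma-separated, UTF-8, header required, `""` for
  missing, decimal point. Exit codes: 0 success, 1 validation failure,
  2 usage error. Invalid rows are collected with row numbers and
  reported together, never silently dropped.
* Scoring scheme, simulator config and statistics bundles round-trip
  through YAML/JSON so a full run is reconstructible from its artifacts.

## Known limitations

* The default 0–3 points map is a stand-in for the instrument's
  unpublished per-item weights; absolute score distributions (e.g. the
  simulated mean ICR ≈ 12.4 under the default marginals vs 9.3 reported
  for the real instrument) depend on it, while category reconciliation,
  correlation calibration and all statistical machinery do not.
* The simulator's latent-factor structure is symmetric across items;
  real items almost certainly load unevenly.
* Cariogram values are coupled to the latent factor phenomenologically;
  nothing about the Cariogram's internal sector weighting is modelled.
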
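# Methods

## The audit model

Every quantity in the pipeline derives from the Wald (normal-theory)
treatment of a standardized mean difference estimate δ̂ with standard
error SE: the test statistic is z = δ̂/SE, two-sided significance at
level α means |z| > z₁₋α/₂, and the power of that test under an assumed
true effect δ\* is

    power(δ*, SE; α) = Φ(δ*/SE − z₁₋α/₂) + Φ(−δ*/SE − z₁₋α/₂).

This is deliberately normal-based rather than t-based: the inputs are
extracted meta-analytic estimates for which only an SE (or a 95% CI,
from which SE = width / (2·z₀.₉₇₅) is reconstructed) is available, not
raw group data with degrees of freedom. The same convention carries
through the one-sample equivalence tests. Power is exactly α at δ\* = 0,
symmetric in the sign of δ\*, increasing in |δ\*| and decreasing in SE.

Three aggregation rules keep multi-outcome and shared studies from
being double-counted:

* a study reporting several outcomes contributes the **median** of its
  per-outcome powers (and, in the excess-significance count, is judged
  significant by the median of its outcome |z| values; an "any outcome
  significant" rule is available by configuration);
* a study appearing in several meta-analyses is one registry entry; in
  unique-study summaries its per-meta powers (each evaluated at that
  meta-analysis' summary estimate) are again collapsed by the median;
* corpus power summaries are reported in percent, rounded half away
  from zero to one decimal.

## Equivalence testing

The one-sample TOST at SESOI Δ tests H₀: θ ≥ +Δ with
p_upper = Φ((δ̂ − Δ)/SE) and H₀: θ ≤ −Δ with p_lower = 1 − Φ((δ̂ + Δ)/SE);
the TOST p-value is the larger of the two, and equivalence at level α
(default 0.05) is declared when p_tost ≤ α — a closed boundary, so a tie
at exactly α counts as equivalent. This decision is provably identical
to the (1 − 2α) confidence interval lying strictly inside (−Δ, +Δ); the
test suite verifies the duality on 10⁴ random configurations.
"Non-significant meta-analysis" is defined by the same z-criterion on
(δ̂, SE), not by the source publication's own label, so the screen is
reproducible from the data alone.

Moderator contrasts work from group summary statistics (n, mean, SD of
per-study power): Welch's t with Satterthwaite degrees of freedom, and a
two-sample TOST whose Cohen's-d bound is converted to the raw scale by
d·√((SD₁² + SD₂²)/2) — the root-mean-square convention for unequal
variances — with both one-sided tests on the Welch df.

## Test of Excess Significance

For a univariate meta-analysis with n deduplicated studies, O observed
significant studies and E = Σᵢ powerᵢ(θ_ref) expected, the default form
is the chi-square statistic A = (O−E)²/E + (O−E)²/(n−E) on 1 df, with
the two-sided tail halved and assigned to the excess direction; a
meta-analysis is flagged when p < 0.05 **and** O > E. The reference
effect θ_ref defaults to the meta-analysis' own summary estimate (the
same convention as the headline power figures) and can be fixed to any
value. The exact alternative evaluates the Poisson-binomial tail
P(X ≥ O) with the per-study powers as success probabilities
(`scipy.stats.poisson_binom`); it is also the automatic fallback when E
is degenerate (0 or n), where A is undefined. No continuity correction
is applied. Multivariate meta-analyses are excluded from the screen
because their constituent estimates are not independent draws of one
outcome.

Using the estimated summary as θ_ref makes the test conservative on
unbiased corpora: in the validation suite the exact form flags well
under 5% of 500 unbiased synthetic meta-analyses, and substantially more
when the generator censors 90% of non-significant studies.

## Temporal trend

Year-by-year tables give the median unique-study power per publication
year over a δ\* grid (default 0.1–1.0 in steps of 0.1). The trend test
is a classical one-way fixed-effects ANOVA of per-study power (at the
observed summary effect by default) on publication year, with years as
given — no binning. Degenerate inputs are explicit: identical group
means return F = 0, p = 1; zero within-group variance with unequal
means returns an infinite F flagged as degenerate rather than an
exception.

## The synthetic generator

`GeneratorConfig` describes a corpus-generating process, not a dataset:

| parameter | default | meaning |
|---|---|---|
| `n_metas` | 35 | meta-analyses per corpus |
| `studies_per_meta` | (2, 6) | member studies, uniform inclusive |
| `mu` | 0.15 | grand mean true SMD |
| `tau` | 0.15 | between-meta SD of true effects |
| `within_tau` | 0.10 | between-study SD within a meta |
| `n_per_group` | (10, 40) | per-group sample size, uniform |
| `censor_prob` | 0.0 | P(drop a non-significant study) |
| `multi_outcome_prob` | 0.25 | P(study reports 2–3 outcomes) |
| `year_range` | (2010, 2017) | publication years |
| `clinical_prob` | 0.64 | P(clinical population) |
| `multiple_dose_prob` | 0.44 | P(multiple-dose design) |
| `univariate_prob` | 0.5 | P(meta labelled univariate) |
| `study_reuse_prob` | 0.12 | P(slot filled by an existing study) |

The defaults are the study conditions of the oxytocin-style corpus the
package targets: three dozen meta-analyses of a hundred-odd unique
small-sample studies whose summary effects centre near 0.15 with
roughly half the spread coming from between-meta heterogeneity, and
per-group samples of 10–40 — the regime in which median power against
the observed summary effects lands in single digits and no summary is
equivalent at Δ = 0.1. Sample sizes are the generator's only free
calibration: the literature being emulated reports powers, not n, so
the n range was chosen once to imply SEs of the observed magnitude and
is configuration-exposed rather than asserted.

Sampling details worth knowing:

* The SMD sampling SE uses the large-sample two-equal-group form
  √(2/n + d²/(4n)). The observed estimate is drawn with the SE
  evaluated at the study's true effect, and the *emitted* SE is then
  re-evaluated at the observed d — mirroring how real meta-analyses
  estimate the variance from the observed effect. Emitted SEs therefore
  satisfy the formula exactly given (d, n), which the tests assert.
* Censoring drops non-significant studies (median-|z| rule) with
  probability `censor_prob` and redraws; a meta-analysis that cannot
  fill its study count within a retry cap raises rather than silently
  shrinking.
* The summary estimate is the fixed-effect inverse-variance average of
  the surviving member outcomes with SE = √(1/Σw). The audited
  literature's own models are unknown, and fixed-effect keeps the
  summary an exact, test-checkable function of the members; a
  DerSimonian–Laird random-effects option (`summary_model="dl"`) exists
  for sensitivity work but is off by default.
* Reproducibility: one `SeedSequence` per corpus spawns one substream
  per meta-analysis, so corpora are byte-stable under a fixed config
  and partial regeneration does not disturb other meta-analyses.

What the generator does **not** emulate: correlated outcomes within a
study, effect-size flavor differences (Hedges' g vs Cohen's d small-n
corrections), unequal group sizes, rounding of published values, or any
pharmacological structure behind the population/dosing labels. Passing
tests on synthetic corpora therefore validate the statistical machinery
and its calibration, not conclusions about any real literature; real
corpora enter through the same two-table schema and are audited
identically.

## Numerical and I/O choices

* Normal quantiles come from `scipy.stats.norm.ppf` (z₀.₉₇₅ ≈ 1.959964);
  no tabulated constants.
* Report tables are written with 6-significant-digit fixed formatting
  and `\n` line endings so repeated runs are byte-identical; fixture
  files use 17 significant digits and are re-read with round-trip float
  parsing, making audit(written fixture) exactly equal
  audit(in-memory corpus).
* Sign reversal (for sources that coded benefit as negative) negates
  the summary and member outcomes and swaps CI bounds once, tracked by
  an applied flag; a study shared between reversed and non-reversed
  meta-analyses follows the reversed convention and is warned about,
  since no single convention can satisfy both parents.
* Unknown population/dosing labels are allowed and drop out of the
  corresponding subgroup contrast only.
* Scientific findings never change the process exit status; only
  malformed inputs raise, with the failing pipeline stage named.

## Validation scale

The statistical validation suite uses 10⁵-replicate Monte-Carlo checks
of the power formula (20 random configurations, 3-binomial-SE bands),
10⁴ random triples for the TOST/CI duality, exhaustive Poisson-binomial
enumeration up to n = 12, 500 synthetic meta-analyses for
excess-significance calibration, 100 replicate corpora for parameter
recovery of μ = 0.14, and 10⁴ null replicates for ANOVA type-I
calibration. These sizes give sub-percent standard errors on every
asserted rate while keeping the full suite under a minute of compute
for the statistical tests.

## Known limitations

* Power and one-sample equivalence are normal-theory; with the very
  small samples common in this literature a t-based calculation would
  give slightly lower power, so the audit's (already low) power figures
  are mildly optimistic.
* No funnel-plot or regression-based small-study-bias tests are
  included; the excess-significance test is the only publication-bias
  instrument.
* Effect-size flavors are pooled on one SMD scale without conversion;
  the flavor column is provenance only.
* Study deduplication is by the supplied `study_id` — identifying that
  two rows are the same study is treated as an editorial decision, not
  a computational one.
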
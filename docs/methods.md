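# Methods

## The two designs

Both designs estimate the prevalence *d* of a sensitive behaviour without
any respondent ever answering the sensitive question directly.

**Single Sample Count (SSC).** The sensitive yes/no item is embedded
among *m* innocuous yes/no items whose population affirmative
probabilities *p₁…p_m* are known (ideally 1/2 each, e.g. "my birthday is
in the first half of the year"). Each respondent reports only the *total*
number of affirmative answers, an integer in 0…m+1. The sample-wide
affirmative count λ is then a sum of independent binomials,
Σᵢ Binomial(n, pᵢ) + Binomial(n, d), and the excess of the sample mean
over the benchmark Σᵢ pᵢ estimates the prevalence:

    d̂ = λ/n − Σᵢ pᵢ.

Approximating each binomial by its matching normal and summing gives
λ ~ N(n(Σpᵢ + d), n(Σpᵢ(1−pᵢ) + d(1−d))), from which the Wald interval on
the count scale is formed and mapped back to the *d* scale. The *simple*
algorithm is the equal-probability case pᵢ = 1/2 (benchmark m/2,
innocuous variance contribution m/4); the *general* algorithm takes the
per-question probabilities. With all pᵢ = 1/2 the two are identical
bit-for-bit.

**Forced Response (FR).** A chance device (here: two dice, totals 2–4
force 'yes', 11–12 force 'no', 5–10 require an honest answer; π₁ = 1/6,
π_no = 1/12, π₂ = 3/4) masks individual answers. The observed 'yes'
proportion has expectation λ = π₁ + π₂·d, inverted as

    d̂ = (λ̂ − π₁)/π₂,   SE(d̂) = √(λ̂(1−λ̂)/n)/π₂.

The forced-no probability is validated (the three probabilities must form
a simplex) but does not enter the estimator; it matters only to the
simulator.

## Numerical choices

* **Variance plug-in for d(1−d).** A negative or >1 point estimate makes
  the d(1−d) plug-in ambiguous. Default (`variance_plugin="clamped"`)
  evaluates it at d̂ clipped to [0, 1] — zero for out-of-range estimates,
  never a negative variance contribution. `"raw"` plugs d̂ in unchanged;
  it is offered because the generalized-algorithm interval in the
  original pilot analysis used the raw plug-in (its clamped counterpart
  differs in the third decimal). Both modes are exposed on both
  estimators so the equal-probability reduction stays exact per mode.
* **Critical values** come from `scipy.stats.norm.ppf` at the requested
  α (1.959964 two-sided at α = 0.05; 1.645 one-sided), never hard-coded.
* **Truncation is presentation only.** `d_raw` and `ci_raw` may leave
  [0, 1]; `d_truncated`/`ci_truncated` are clipped copies. All downstream
  math uses the raw values. A negative estimate sets a
  `negative_estimate` diagnostic flag rather than being hidden.
* **Normal-approximation diagnostics.** The estimate carries a
  `sensitive_normal_ok` flag implementing the n·d > 5 and n(1−d) > 5 rule
  of thumb for the sensitive component (evaluated at the truncated
  estimate); the pilot data fail it, consistent with its interval being
  driven by the innocuous noise.
* **No rounding inside computations**; reports serialise full doubles and
  the CLI formats tables to a fixed number of decimals at output time.
* **Benchmark t-test.** One-sample two-sided t-test of the mean reported
  total against Σpᵢ, with Cohen's d defined as |mean − benchmark|/sd.
  Zero-variance samples are an error.

## Answer distributions and exposure

A respondent with every innocuous answer affirmative plus the sensitive
behaviour must report the top category m+1, which is fully revealing.
`answer_pmf` gives the exact category PMF by convolving the m+1 Bernoulli
components, under three scenarios: `honest`; `merge_top_bottom` (answer
boxes 0 and m+1 are shared, so the top category's mass moves to 0); and
`any_other` (respondents who would report m+1 choose uniformly among
0…m). For the equal 4+1 design these reduce to simple closed forms, e.g.
honest P(0) = 1/16 − d/16 and P(5) = d/16; the any-other form for
category 3 is 1/4 + 11d/80 — the uniform redistribution can only add
mass, and the column sums to 1 only with the plus sign.

Divergence between scenarios is summarised by the Kolmogorov–Smirnov
maximum CDF difference over the common support 0…m+1 (a merged category
contributes its whole mass at position 0) and by the root-mean-square of
per-category PMF differences. At d = 0.2 both mitigations sit KS = d/16 =
0.0125 from honest answering. RMS here is defined on PMF differences; no
alternative definition we examined reproduces any other published
summary, so only the KS figures are treated as reference values.

Exposure risk is closed-form: the probability that all innocuous answers
are affirmative is ∏pᵢ (0.5^m for equal designs) and the probability of a
forced fully revealing report is d·∏pᵢ; `exposure_table` tabulates both
in percent across m = 1…8 and a d grid.

## Planning

* `ssc_ci_table` — with all pᵢ = 1/2 the innocuous count over the whole
  sample is Binomial(m·n, 1/2); the table reports its exact α/2 and
  1−α/2 quantiles (smallest integer whose CDF reaches the level — the
  `scipy.stats.binom.ppf` convention on both tails) divided by n. This is
  the d = 0 sampling band the observed mean must clear.
* `ssc_min_sample_size` — inverts the one-sided test of the mean total
  against the benchmark: n = (t·s/Δ)² with t the one-sided normal
  critical value at α and s the per-respondent SD of the total. s comes
  from the closed form √(m/4 + d(1−d)) by default, or from a seeded
  simulation of reported totals (10,000 draws by default) to mirror
  simulation-based planning; the two agree within Monte-Carlo error.
  Rounding is ceiling by default (conservative); `"trunc"` reproduces
  worked examples that drop the fraction (1839 rather than 1840 at
  Δ = 0.04, s = 1.043).
* `fr_min_sample_size` — inverts the FR standard error at the
  variance-maximising worst case λ = 1/2:
  n = ⌈λ(1−λ)/(SE²·π₂²)⌉ (178 at SE = 0.05 with π₂ = 3/4; 4445 at 0.01).
  A tiny pre-ceiling rounding guard (9 decimals) prevents binary float
  noise from bumping an exactly attained n.

## Simulator

`simulate_ssc` draws each respondent's m Bernoulli(pᵢ) innocuous answers
and one Bernoulli(d) sensitive answer, reports the total, then applies
the scenario transform (top category → 0, or → uniform choice in 0…m).
`simulate_fr` forces 'yes'/'no' with the device probabilities and
otherwise answers Bernoulli(d). A seed is mandatory; replicated studies
(`run_recovery_study`) derive one independent child stream per
replication from `numpy.random.SeedSequence(seed)`, so a whole study is
reproducible from one integer and replications are independent and
parallelisable.

The generator emulates perfectly compliant respondents with exactly known
innocuous probabilities and independent answers. It does not model
self-protective 'no'-saying or other noncompliance, misremembered
innocuous facts, correlation between innocuous items, or item
nonresponse — so passing recovery/coverage tests demonstrate the
estimators' correctness under the design's own assumptions, not
robustness to cheating (which is known to bias all such designs
downward).

## Test problem sizes

The suite checks unbiasedness (≥ 500 replications) and ~95% CI coverage
(2000 replications, ±2 points) at n = 2000 for d ∈ {0.05, 0.2, 0.5};
distributional convergence of the simulator at n up to 2×10⁵ against the
exact PMFs; the analytic/simulated SD bridge with 50 replications of
10,000 draws; and enumeration-oracle equivalence of every PMF for m ≤ 6
over all 2^(m+1) answer patterns. These sizes give Monte-Carlo standard
errors comfortably below the tolerances asserted (3 MC SEs throughout).

## Known limitations

* The Wald/normal intervals undercover for small n or d near the
  boundary; the exact-binomial planning table is the honest guide there.
* The pilot dataset's published general-algorithm interval is only
  reproducible with the raw variance plug-in (see above); the package
  default remains clamped, and the choice is always recorded in the
  estimate's diagnostics.
* Aggregate FR input collapses to (n_yes, n); per-respondent covariates
  are out of scope, as are noncompliance-corrected estimators and
  multi-item scale variants.
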
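# Methods

## Effect-size normalization

Corpora mix three metrics: Pearson's *r* (individual differences, one
sample of total size *n*), and Cohen's *d* / Hedges' *g* (two groups of
sizes *n*₁, *n*₂). Because the analysis concerns the distribution of
effect *magnitudes*, normalization replaces every value by its absolute
value and converts each *d* to Hedges' *g* with the small-sample bias
correction

    g = d · (1 − 3 / (4·(n1 + n2) − 9)),

whose factor lies in (0, 1), increases with total *N*, and tends to 1, so
|g| ≤ |d| with the sign preserved. Records already recorded as *g* pass
through conversion untouched (the correction is applied exactly once),
which also makes normalization idempotent. Correlation rows store the
total *n* in `n1` with `n2` unset. A missing category defaults to
`unclassified` rather than erroring, since topic categorization is a
manual, optional labeling. No deduplication across overlapping
meta-analyses is attempted: the source corpora do not identify shared
primary studies, so any heuristic would be speculative.

## Benchmarks

Small/medium/large benchmarks are the 25th/50th/75th percentiles of the
normalized magnitudes, per metric and optionally per category subgroup.
The quantile convention is linear interpolation of order statistics
(h = (N−1)p + 1; R's type 7 and numpy's default) — benchmark values are
only comparable across implementations under a fixed convention.
Guideline rounding maps a benchmark to the nearest multiple of 0.05 with
ties rounding up (0.38 → 0.40, 0.76 → 0.75, 0.125 → 0.15).

Shape summaries report moment-based skewness m₃/m₂^{3/2} and kurtosis in
*both* conventions, raw m₄/m₂² and excess (raw − 3), because published
kurtosis values often omit which one was used; callers pick the field
they need. Density prep uses a Gaussian kernel with Silverman's rule by
default; it is a visualization aid, and nothing downstream depends on the
bandwidth.

## Power

**Two-sample t-test (exact).** With true standardized mean difference *d*
and groups *n*₁, *n*₂, the test statistic is noncentral *t* with
df = *n*₁ + *n*₂ − 2 and noncentrality δ = *d*·√(*n*₁*n*₂/(*n*₁+*n*₂)).
Two-sided power at level α is

    1 − F_nct(t*; df, δ) + F_nct(−t*; df, δ),   t* = t_{1−α/2, df};

one-sided drops the lower-tail term and uses t\*_{1−α}. The noncentral-t
CDF is scipy's; in the extreme df/ncp ranges where scipy's series returns
NaN (df in the tens of thousands), a normal approximation with variance
1 + δ²/(2·df) substitutes — there the two agree to within ~1e−4, far
inside any reported precision. At *d* = 0 the distribution degenerates to
the central *t* and two-sided power equals α exactly; the equal-group
case is the δ = *d*·√(n/2) special case of the same formula.

**Correlation test (Fisher-z approximation).** The test of H₀: ρ = 0 via
t = r·√((n−2)/(1−r²)) is approximated on the atanh scale (the
computation used by `pwr.r.test`): the critical correlation
r_c = √(t*²/(t*² + df)) with df = n − 2 is mapped to z_c = atanh(r_c),
the population value to z_r = atanh(r) + r/(2(n−1)) (the mean-bias
adjustment of the z transform), and power is
Φ((z_r − z_c)√(n−3)) + Φ((−z_r − z_c)√(n−3)), the second term dropped for
one-sided tests. The approximation's size is within .01 of α for
moderate n but overshoots at the minimal df (its n = 4 value can exceed
the n = 8 one for small r), so monotonicity in n holds from roughly n ≥ 8
rather than the domain boundary n = 4. It requires n ≥ 4 (√(n−3)).

**Sample-size solvers** return the smallest integer n (per group, or
total for correlations) whose power meets the target: power is treated as
a continuous, increasing function of n, a bracket is found by doubling
from the minimum design size (hard cap 10⁷, beyond which the target is
declared unreachable — this replaces blind bisection over a fixed huge
interval, where the noncentral-t evaluation is not numerically reliable),
Brent's method finds the root, and the ceiling is taken with an
integer-step check on both sides so the minimality contract
(power(n) ≥ target > power(n−1)) holds exactly. Rounding up guarantees
the target power; conventions that round to nearest can differ by one
participant when the continuous root sits just above an integer.

Defaults everywhere: α = .05, two-tailed. Effects are treated as known
population parameters, which is what "a priori power analysis" means;
no sampling uncertainty is propagated from the corpus to the power
statement.

`corpus_power_summary` evaluates each record's design at a per-metric
reference effect and reports the fraction reaching a power threshold
(default .80) plus median sample sizes.

## Funnel regions

Each record is placed in (effect, SE) space: group effects as-is with

    SE_g = sqrt((n1 + n2)/(n1·n2) + g²/(2·(n1 + n2))),

correlations on the Fisher-z scale (effect = atanh r, SE = 1/√(n−3)),
standard meta-analytic practice for funnel geometry. The two-sided
normal p-value p = 2(1 − Φ(effect/SE)) assigns regions: gray p < .01,
red .01 ≤ p < .05, orange .05 ≤ p < .10, white p ≥ .10 — boundary ties
deliberately land in the less significant region so the partition is
deterministic. p-values are floored at the smallest normal double so
that extreme effect/SE ratios (which underflow to 0) still classify.
Classification depends only on the ratio effect/SE, hence is invariant
to a common rescaling of both. A record-level `se` column, when present
in the CSV, takes precedence over the recomputed value; otherwise SEs
are derived from the sample sizes, and records without usable sizes are
skipped with a count. Plot prep emits the points plus the contour loci
effect = z_q·SE for z_q ∈ {1.645, 1.960, 2.576}, with SE increasing
downward and effects on the positive axis (one-directional display,
consistent with absolute-value normalization).

## Synthetic corpora

The generator emulates the statistical structure the pipeline assumes,
not any particular real corpus:

- a meta-analysis is correlational with probability 1108/4049, otherwise
  group-difference (assigned biomedical with probability 614/2941, else
  psychosocial); its study count is Poisson(46) truncated at 1, and its
  studies share one true effect (within-meta clustering);
- true group effects are Gamma(0.483621, scale 1.029848); true
  correlations are Gamma(2.638502, scale 0.086244) on the Fisher-z scale
  (r = tanh z). A Gamma is the minimal right-skewed positive
  two-parameter family matching the heavy right tail of published effect
  distributions;
- sample sizes are rounded lognormals floored at the design minimum:
  group sizes lognormal(ln 30, 0.6) and (ln 19, 0.6) — medians at the
  field's typical case/control sizes, σ = 0.6 giving the roughly
  half-order-of-magnitude IQR spread typical of published studies — and
  correlational n lognormal(ln 129, 0.7);
- the observed effect is the true effect plus N(0, SE²) noise using the
  same SE formulas as the funnel module (Fisher-z scale for
  correlations), then absolute-valued;
- with `bias_strength` > 0, a drawn record whose two-sided normal p-value
  is ≥ .05 is discarded and redrawn with that probability (capped at 1000
  redraws), a minimal publication-bias filter that inflates the
  orange/red funnel shares.

The Gamma parameters were fixed once by numerical quantile matching: the
observed-effect CDF F(x) = E[Φ((x−t)/SE) − Φ((−x−t)/SE)] is computed by
midpoint quadrature over quantile grids of the true-effect Gamma and the
sample-size lognormals (`theoretical_observed_cdf`), inverted by Brent
root-finding, and the two Gamma parameters optimized (Nelder–Mead) so the
theoretical observed quartiles match g = 0.16/0.38/0.76 and
r = .12/.20/.32. The achieved theoretical quartiles are
(0.165, 0.374, 0.764) and (0.114, 0.207, 0.315). These constants are part
of the generator's definition, not tuning knobs.

What passing tests show — and don't. Parameter-recovery tests draw
5×10⁴-record corpora with one effect per meta-analysis (removing cluster
variance so sample quantiles converge at the i.i.d. rate) and check the
sample quartiles against the quadrature theory within ±0.02; under the
default clustered design the large-effect quartile fluctuates more
between seeds, as it would in a real field. The generator reproduces
marginal skew, sample-size scales, SE-consistent noise, and a retention
form of publication bias; it does not model metric-dependent effect
heterogeneity, correlated effects beyond a shared meta-level mean,
selective reporting within studies, or p-hacking, so agreement on
synthetic corpora does not certify behavior on real extracted data.

## Numerical and interface choices

- Quantiles: numpy's linear method, matching the convention above.
- Solver tolerance: brentq xtol 1e−8 on n, with explicit integer
  verification of minimality afterward (the ±1e−9 ceiling nudge only
  protects against root-tolerance wobble).
- CSV: comma-delimited UTF-8 with header
  `meta_id,study_id,metric,value,n1,n2,category[,se]`; invalid rows are
  reported together, each with its row index.
- CLI prints power to 2 decimals, sample sizes as integers; tables are
  also written as CSV so nothing downstream parses figures. Exit codes:
  0 success, 1 usage error, 2 data error. Figures render to PNG and SVG.
- The reported empirical quantities in this document (achieved
  theoretical quartiles, power values) are exactly those the test suite
  and acceptance script recompute.

## Known limitations

- The correlation power formula is an approximation; its error is largest
  for n near 4 and r near 1.
- Funnel-region percentages of a real corpus depend on the per-study SEs;
  when the CSV lacks an `se` column the large-sample formulas above are a
  reconstruction, not the deposited values.
- The generator's defaults describe one field-wide configuration; per-
  subfield calibration (e.g. separate biomedical/psychosocial effect
  distributions) is not implemented — categories affect labels only.
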
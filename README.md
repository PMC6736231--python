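# effectbench

Empirical effect-size benchmarks and statistical power analysis for
meta-research corpora, with a focus on the designs common in gerontology
and adjacent behavioral/biomedical fields.

Cohen's conventional thresholds (Pearson's *r* = .10/.30/.50; *d* =
0.20/0.50/0.80 for small/medium/large) overestimate typical effects in
many fields. The alternative is to benchmark against the field itself:
collect published effect sizes, take the 25th/50th/75th percentiles of
their magnitudes as the field's small/medium/large effects, and feed those
into a priori power analysis. `effectbench` implements that pipeline:

- **corpus** — read/validate/write flat CSV corpora of extracted effects
  (*r*, *d*, *g* with sample sizes); normalize to magnitudes and convert
  Cohen's *d* to Hedges' *g* via the small-sample bias correction
  *g* = *d*·(1 − 3/(4*N* − 9)).
- **distribution** — percentile-grid benchmarks (linear-interpolation
  quantiles), threshold proportions, skewness/kurtosis, histogram and
  KDE prep, and rounding of benchmarks to guideline values (nearest 0.05).
- **power** — exact noncentral-*t* power for two-sample *t*-tests with
  equal or unequal groups (df = *n*₁+*n*₂−2, δ = *d*·√(*n*₁*n*₂/(*n*₁+*n*₂))),
  Fisher-z approximate power for the test of a correlation (the
  computation behind `pwr.r.test`), and smallest-integer sample-size
  solvers for both.
- **funnel** — contour-enhanced funnel geometry: standard errors, normal
  two-sided p-values, and classification into the white/orange/red/gray
  significance regions (p ≥ .10 / .10–.05 / .05–.01 / < .01) whose orange
  and red shares flag inflation bias.
- **synthetic_data** — a seeded generator of corpora with right-skewed
  (Gamma) true effects, lognormal sample sizes, SE-consistent sampling
  noise, and an optional publication-bias retention filter, calibrated so
  observed quartiles land near *g* = 0.16/0.38/0.76 and *r* = .12/.20/.32
  with median group sizes 30/19 and median correlational n of 129.
- **cli** — `effectbench` with subcommands `simulate`, `benchmarks`,
  `power`, `samplesize`, `powertable`, `funnel`, `achieved`.

## Worked example

```sh
$ effectbench simulate --seed 7 --out synth.csv
# wrote 4172 records to synth.csv

$ effectbench power --test t2n --effect 0.76 --n1 30 --n2 19
power=0.72 df=47 ncp=2.5921 crit=2.0117

$ effectbench samplesize --test r --effect 0.32 --power 0.8
n=74 (total sample)

$ effectbench benchmarks --input synth.csv --metric g | tail -3
benchmarks (small/medium/large): 0.16 0.38 0.82
rounded guideline:               0.15 0.40 0.80
Cohen guideline:                 0.20 0.50 0.80

$ effectbench funnel --input synth.csv
region  count  percent
 white   2203     52.8
orange    278      6.7
   red    426     10.2
  gray   1265     30.3
```

Reading the numbers: a typical unequal-group design (30 vs 19
participants) has only .72 power even at the field's *large*
group-difference benchmark (g = 0.76) — and far less at the medium one —
while detecting a large correlation (.32) at 80% power needs 74
participants. The simulated corpus recovers quartile benchmarks close to
its calibration targets (the large-effect quartile fluctuates most, since
it sits in the distribution's heavy right tail), and its funnel regions
show no excess of just-significant results when the bias knob is off.

The same operations are available as library calls
(`effectbench.power_two_sample_t`, `effectbench.benchmark`, ...); see the
module docstrings and `docs/methods.md`.

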
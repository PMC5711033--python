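# causaldir

Orienting the causal relationship between two traits using genetic
instruments, with explicit sensitivity to measurement error.

## The problem

When a SNP `g` is robustly associated with two correlated traits — say a DNA
methylation probe and the expression of a nearby gene — which trait does the
SNP influence first?  Answering this orients the causal arrow between the
traits themselves.  Two families of methods exist:

* **MR Steiger**: under the causal chain `g → x → y` the instrument must be
  more strongly correlated with the exposure than with the outcome, since
  ρ_gy = ρ_gx·ρ_xy.  Testing H₀: ρ_gx = ρ_gy with Steiger's Z for correlated
  correlations (one sample) or the Fisher-z test of independent correlations
  (two samples, unequal sizes allowed) gives a direction (sign of Z) and a
  confidence (p_Steiger).  Combined with a Mendelian-randomisation causal
  test (Wald ratio on summary data, 2SLS on individual data), a directional
  call requires both p_MR < α and p_Steiger < α.  Only summary statistics
  (effect, SE, p, N) are needed: |r| is recovered from (p, N) by inverting
  the slope t-test.
* **CIT** (causal inference test): a mediation approach — four regression
  conditions whose least-extreme p-value forms an omnibus p, run in both
  orientations.  Its fourth condition (SNP ⟂ outcome | exposure) is an
  equivalence test implemented here by permutation against nulls carrying a
  margin-level unmediated SNP effect.

Both are fallible under non-differential measurement error.  Noise on the
observed exposure `x_o` leaves a residual instrument–outcome covariance
`β_my·β_g·β_x·var(g)·(1 − D)` after adjustment, where
`D = β_mx²·var(x)/(β_mx²·var(x) + var(ε_mx))` is the attenuation factor —
so mediation tests reject true mediation, ever more confidently as n grows.
The Steiger comparison fails exactly where the statistic
`d = ρ_x,xo − ρ_xy·ρ_y,yo` is negative.  The package therefore ships a
sensitivity analysis: integrating the predicted direction over every
admissible measurement-error value yields a reliability ratio `R` (volume of
error space supporting the inferred direction over the volume opposing it;
R = 1 means maximally sensitive).

## Worked example

```bash
python examples/sensitivity_to_measurement_error.py
```

```
observed correlations: r_gx = 0.1000, r_gy = 0.0316
inferred direction: x_causes_y
volume supporting the inference: 0.07728
volume opposing  the inference: 0.01757
reliability ratio R = 4.40
```

An instrument explaining 1% of the exposure's variance, with the exposure
explaining 10% of the outcome's variance, yields R = 4.40: across all
admissible amounts of measurement error in the two traits, 4.4 times as much
of the space supports the inferred exposure → outcome direction as opposes
it.  The two-sample pipeline looks like:

```bash
python examples/direction_from_summary_stats.py
```

```
instrument-exposure correlation |r_gx| = 0.3219
instrument-outcome  correlation |r_gy| = 0.1533
Steiger Z = 8.96  (p = 3.24e-19)
Wald ratio beta = 0.475 +/- 0.043  (p = 5.36e-28)
direction call: x_causes_y
```

Here both tables were simulated cohorts (n = 5000 each) with the instrument
explaining 10% of exposure variance and a causal effect explaining 20% of
outcome variance; the Steiger Z is positive and significant, so the exposure
is called causally upstream, and the Wald ratio 0.475 estimates the causal
effect per exposure unit (population value √0.2 ≈ 0.447).

The other examples show the one-sample analysis and CIT comparison
(`one_sample_cit_vs_mr.py`), the attenuation algebra
(`attenuation_bias.py`), and a scaled-down method-comparison experiment
(`method_comparison_grid.py`).  A thin CLI mirrors the library:
`causaldir steiger|mr|cit|sensitivity|simulate|fixtures --help`.

## Layout

- `src/causaldir/summary_io.py` — summary-stat tables, correlation recovery
- `src/causaldir/steiger.py` — Fisher z, Steiger tests, decision rule
- `src/causaldir/mr.py` — Wald ratio and 2SLS
- `src/causaldir/cit.py` — four-condition CIT, bidirectional wrapper
- `src/causaldir/sensitivity.py` — attenuation D, d statistic, reliability R
- `src/causaldir/simulate.py` — causal/confounded generators, experiment grid
- `docs/methods.md` — models, conventions and limitations in detail
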
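# Methods

## Model

For one analyte in one group, let `y_ij` be the normalised concentration
of subject `i` at time `t_ij` (absolute hours; samples after midnight are
unwrapped to [24, 48), so periodicity is a property of the kernel, never
of folded data). The hierarchy is

```
y_ij = g(t_ij) + f_i(t_ij) + eps_ij
g   ~ GP(0, k_per),   k_per(t,t') = sigma2_p exp(-2 sin^2(pi (t-t')/T) / ell_p^2)
f_i ~ GP(0, k_mat),   k_mat(r)    = sigma2_m (1 + sqrt3 r/ell_m) exp(-sqrt3 r/ell_m)
eps ~ N(0, sigma2_n)
```

with `T = 24` h fixed. The joint covariance of the stacked observation
vector couples different subjects only through `k_per`; without the shared
component the matrix is block-diagonal by subject plus a noise diagonal.
Everything is Gaussian, so the marginal likelihood is available in closed
form via one Cholesky factorisation per evaluation.

The exp-sine-squared form is the canonical "periodic kernel"; other exactly
periodic covariances exist (e.g. the periodic part of a Matern
construction), and the choice is a documented design decision, not a
claim of uniqueness. The period is **not** estimated: five samples per
subject cannot identify a free period, and the scientific hypothesis is
24 h rhythmicity specifically.

## Parameters

| parameter  | meaning                           | units      | bounds        | default treatment |
|------------|-----------------------------------|------------|---------------|-------------------|
| `sigma2_p` | shared periodic variance          | normalised | [1e-6, 1e3]   | free (rhythmic model), absent (null) |
| `ell_p`    | periodic lengthscale (sine warp)  | unitless   | [0.05, 50]    | free (rhythmic model) |
| `sigma2_m` | subject-deviation variance        | normalised | [1e-6, 1e3]   | free |
| `ell_m`    | subject-deviation lengthscale     | hours      | [0.05, 50]    | free |
| `sigma2_n` | noise variance                    | normalised | [1e-6, 1e3]   | free |
| `T`        | period                            | hours      | fixed         | 24 |

Optimisation is in log-parameter space (L-BFGS-B, analytic gradients
`d lml/d theta = tr((alpha alpha' - K^-1) dK/dtheta)/2`), from a fixed
lattice of five restarts spanning the plausible range of the normalised
data scale. The rhythmic model gets one extra warm start: the fitted null
parameters augmented with `sigma2_p = 1e-4`, which guarantees the
likelihood-ratio statistic is never materially negative (the rhythmic
model nests the null up to the variance lower bound). A relative jitter of
`1e-8 * mean(diag K)` precedes every factorisation; at unit data scale
this perturbs log likelihoods far below any decision threshold. A fit in
which every restart fails is reported as inconclusive, never dropped.

## Testing and classification

* **LR test**: `Lambda = 2(l_rhythmic - l_null)` clipped at 0, referred to
  chi-squared with df = 2 (the two extra hyperparameters), rhythmic when
  `p <= alpha` with `alpha = 0.05` and no multiplicity correction by
  default; Benjamini–Hochberg across analytes is available via config.
  Under the null the true `sigma2_p` sits on the boundary of the parameter
  space, so the chi-squared reference is conservative (Wilks' regularity
  fails in the direction of under-rejection); the empirical size measured
  by `scripts/acceptance.py` is ~1% at the nominal 5%. For users who want
  an exact-size p-value, a within-subject time-permutation calibration
  (seeded, default 999 permutations, expensive) is available behind the
  `permutation` flag.
* **Acrophase**: argmax of the posterior mean of `g` on a 0.1 h grid over
  [0, 24), earliest hour on ties; undefined (error) for a flat curve.
  Acrophase accuracy is a property of the posterior-mean estimator and is
  assessed on the rhythmic fit of every simulated replicate, irrespective
  of the significance call (significance is calibrated separately by the
  size and power checks).
* **Gain of rhythm**: the four-way classification is a pure function of
  the two within-group indicators `(p_healthy <= alpha, p_disease <= alpha)`
  — two within-group tests, deliberately not a single interaction test.
* **Class summaries**: ceramides are grouped by structural class
  (NS/NDS/AS/ADS from the `CER[X(a)Y(b)]` label); everything else is
  "other". Counts conserve totals by construction.

## Pipeline order and plumbing

Stage order is **impute → normalise → fit**, recorded in the emitted
config. Imputation is deterministic per-(subject, analyte) linear
interpolation in time with boundary carry — a single, reproducible
imputation chosen over stochastic multiple imputation because the expected
missingness burden is sporadic (single lost vials), and every imputed cell
is flagged. Normalisation is per participant and per lipid to mean 0 and
sample SD 1 (n−1 denominator); zero-variance strata cannot be normalised
and are excluded with a logged warning rather than jittered. Both steps
are idempotent/deterministic and exact to 1e-10.

## JTK-style detector

For balanced, evenly sampled designs the package provides a simplified
JTK detector: Kendall tau between the data and cosine templates
`cos(2 pi (t - phi)/period)` on a phase grid (default step = the sampling
interval), one-sided concordance p per template — exact when there are no
ties, a seeded vectorised permutation null when replicates create ties —
Bonferroni-corrected over the number of *distinct* templates, best phase
by minimum p with earliest-phase tie-break. This is intentionally not a
bit-exact clone of the original JTK_CYCLE (no Harding tau distribution,
no asymmetric waveforms); it is an independent, conservative detector used
to cross-check the GP calls, and the two agree on essentially all
strong-signal series. "Adjusted p" means Benjamini–Hochberg across
analytes (statsmodels implementation).

## Synthetic data

The generator emulates the clinical design: two groups of 10 subjects,
five samples at 6-hourly intervals from 18:00 (so absolute times 18, 24,
30, 36, 42 h), 116 analytes named with valid ceramide /
eicosanoid-style labels, shared rhythmic component per analyte and group,
per-subject Matern 3/2 deviations (SD 0.5, lengthscale 12 h), unit
Gaussian noise and 1% missingness by default. Default rhythmic fractions
are 0.2 (healthy) and 0.4 (RA), reflecting a disease group that gains
rhythmic species. In `cosinor` mode the shared signal is
`amplitude * sqrt(2) * cos(2 pi (t - acrophase)/24)` — temporal SD equal to
`amplitude`, known phase for recovery tests; in `gp` mode it is a draw
from the periodic-kernel GP, matching the model exactly but with random
phase. One global seed drives everything; per-analyte substreams derive
from `(seed, analyte index)`, so datasets are bit-reproducible and
analytes are independent.

What the generator does **not** emulate: LC-MS/MS measurement artefacts
(batch effects, limits of detection, heteroscedastic concentration-scale
noise), non-sinusoidal waveforms, correlation between lipids sharing a
synthesis pathway, and informative missingness. Passing tests therefore
demonstrate correctness of the inference under the model's own
assumptions — calibration, power ordering, phase recovery — not robustness
to those real-data departures.

## Problem sizes and numerical choices

The calibration and recovery experiments use the study-scale design
(50 stacked points per series: 10 subjects × 5 times), at which one
null-plus-rhythmic fit pair costs ~0.2 s: 500-replicate size runs and
50-replicate-per-amplitude power grids complete in minutes on one CPU.
Ties in the acrophase argmax break to the earliest hour; constant series
yield pinned variance estimates at the lower bound (null) or an NA call
(JTK); chi-squared p-values use the survival function directly. All
Monte-Carlo acceptance bands are binomial 3-SE bounds at the stated
replicate counts.

## Known limitations

* The LR test is conservative; at very small effect sizes this costs
  power. The permutation option trades CPU for exactness.
* Per-group independent fitting (healthy and RA fits share nothing) is a
  design choice; a joint model with group offsets could borrow strength
  but would entangle the two within-group hypotheses.
* The acrophase grid (0.1 h) bounds phase resolution; with 6-hourly
  sampling the practical phase uncertainty (~1 h at amplitude/noise = 1)
  dominates the grid error.
* `normalize` assumes ≥ 2 distinct observed values per stratum; heavier
  missingness than the design anticipates (entire lost visits) drops
  subjects, with warnings.
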
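# lipidrhythm

Detection of 24-hour (circadian) rhythmicity in sparse, multi-subject serum
lipidomics — the setting of a two-group clinical time-course study in which
rheumatoid-arthritis (RA) patients and healthy controls are sampled a
handful of times over one day, and the question is which lipid species
oscillate, at what peak time, and which species *gain* a rhythm in disease.

With ~5 samples per subject, per-subject rhythm fitting is hopeless and
pooling subjects naively ignores strong between-subject correlation. The
package instead fits a **hierarchical Gaussian-process model** per analyte
and group: each (normalised) concentration is

```
y_ij(t) = g(t) + f_i(t) + eps_ij
```

* `g ~ GP(0, k_per)` — a rhythmic component **shared by all subjects**,
  with an exp-sine-squared kernel
  `k_per(t,t') = sigma2_p * exp(-2 sin^2(pi (t-t')/24) / ell_p^2)`
  of fixed 24 h period;
* `f_i ~ GP(0, k_mat)` — an independent smooth deviation per subject `i`,
  with a Matern 3/2 kernel
  `k_mat(r) = sigma2_m (1 + sqrt(3) r / ell_m) exp(-sqrt(3) r / ell_m)`;
* `eps ~ N(0, sigma2_n)` — observation noise.

All components are Gaussian, so they marginalise analytically; the
hyperparameters are estimated by maximum marginal likelihood (L-BFGS-B in
log space, analytic gradients, fixed restart lattice). Rhythmicity is a
Wilks likelihood-ratio test of the shared component,

```
Lambda = 2 (l_rhythmic - l_null),   p = P(chi2_2 >= Lambda),
```

with df = 2 for the two extra hyperparameters (`sigma2_p`, `ell_p`); the
null pins `sigma2_p` on the parameter-space boundary, which makes the
chi-squared reference conservative. The peak time (acrophase) of each
significant species is the argmax of the posterior mean of `g` on a 0.1 h
grid, and comparing the two within-group calls classifies every analyte as
rhythmic in both groups, **gained in RA**, lost in RA, or not rhythmic.

Also included:

* a generative **synthetic-data module** with exactly the model's
  structure (shared cosine or GP draw, per-subject Matern deviations,
  noise, sporadic missingness) plus ground-truth side-channel metadata;
* per-participant-per-lipid **normalisation**, deterministic time-linear
  **imputation**, and **ceramide nomenclature** parsing
  (`CER[N(18)DS(24)]` → non-hydroxy fatty acid, 18 C, dihydrosphingosine
  base, 24 C, class NDS);
* a simplified **JTK-style detector** (phase-shifted cosine templates +
  Kendall tau + Bonferroni over distinct templates) for balanced, evenly
  sampled designs such as mouse serum time courses — an independent
  cross-check on the GP calls;
* a scikit-learn-compatible estimator surface
  (`HierarchicalGPRhythmModel`, `JTKCycle`) and a CLI.

## Worked example

Simulate a 30-analyte, 10-subjects-per-group study (five 6-hourly samples
from 18:00; by default 20% of analytes rhythmic in controls, 40% in RA,
amplitude 1.5, 2% missing values) and analyse it:

```sh
lipidrhythm simulate --n-subjects 10 --n-analytes 30 --amplitude 1.5 \
    --missing-rate 0.02 --seed 42 --out study.csv --truth-out truth.csv
lipidrhythm run --input study.csv --seed 42 --out results/
```

which prints (abridged):

```json
{
  "rhythmic_per_group": {"healthy": 6, "RA": 13},
  "gain_of_rhythm_counts": {
    "gained_in_RA": 11, "lost_in_RA": 4,
    "not_rhythmic": 13, "rhythmic_in_both": 2
  },
  "n_analytes_input": 30, "n_inconclusive_fits": 0
}
```

The simulated RA group carries twice as many rhythmic analytes as the
control group, and the pipeline recovers that asymmetry: 13 vs 6 species
called rhythmic at the 5% level, 11 classified as newly rhythmic in RA.
Per-analyte detail lands in `results/results.csv`, e.g.

```
analyte,group,lr_stat,p_value,rhythmic,acrophase_h,converged
11-HETE,RA,64.39,1.04e-14,True,22.0,True
11-HETE,healthy,46.92,6.47e-11,True,21.0,True
```

— the likelihood-ratio statistic, its chi-squared(2) p-value, the call at
alpha = 0.05, and the estimated peak hour. `results/summary.json` adds
per-ceramide-class counts and acrophase lists;
`results/posterior_curves.json` holds the posterior mean ± SD curve of the
shared component for every significant analyte.

The same analysis is available from Python:

```python
from lipidrhythm import (SimulationConfig, RunConfig, run_pipeline)

cfg = RunConfig(simulation=SimulationConfig(n_analytes=30, seed=42), seed=42)
result = run_pipeline(cfg)
print(result.summary["gain_of_rhythm_counts"])
```

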
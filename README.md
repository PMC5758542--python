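# modgain

Does the modular organization of a person's resting-state brain network
predict how much they will benefit from an intervention? `modgain` is a
tested Python pipeline for that question in aging/exercise cohorts: it
turns per-subject ROI time series into functional-connectivity graphs,
quantifies network **modularity** and **segregation**, scores a
multi-test cognitive battery into construct composites and standardized
gain scores, applies motion-based quality control, and fits the
moderated regression that links baseline modularity to
executive-function (EF) gain. A synthetic-cohort generator with planted
effects gives every stage a parameter-recovery test.

## The model

For each subject, pairwise Pearson correlations between regional
time series are Fisher z-transformed and binarized at proportional
density thresholds ("costs" of 2–10% of all node pairs). On each binary
graph, the modularity of a partition into modules is

```
Q = Σ_i (e_ii − a_i²)
```

where `e_ii` is the fraction of edges inside module *i* and `a_i` the
fraction of edge endpoints attached to module *i*. Q is maximized per
subject with a spectral (leading-eigenvector) algorithm with
Kernighan–Lin refinement, and also evaluated under a fixed canonical
node-to-system partition. The weighted companion metric, module
segregation, is `(Zw − Zb)/Zw` on the full z-matrix.

Cognitive tests are cleaned (3-SD exclusion, then winsorization),
standardized, and averaged into four construct composites (vocabulary,
perceptual speed, episodic memory, EF); per-test gain is
`(post − pre)/SD_pre` with the pre-test SD pooled across groups. The
headline inference is an OLS regression per intervention group,

```
EF_gain ~ age + meanFD + EF_base + Q + EF_base × Q
```

with case-resampling BCa bootstrap confidence intervals (default 5000
resamples) on every coefficient; the interaction asks whether the
modularity–gain slope is stronger in low- or high-performing subjects.

## Worked example

Simulate a compact cohort with a planted modularity → EF-gain slope,
run the full pipeline (motion QC → connectivity → spectral Q → battery
scoring), and fit the moderated regression:

```python
from modgain.simulate import SimulationConfig, simulate_cohort
from modgain.pipeline import measure_cohort, fit_group_models
from modgain.stats import BootstrapSpec

cfg = SimulationConfig(
    n_subjects=32, n_rois=60, n_volumes=120,
    partition_spec={"dmn": 15, "fp": 15, "vis": 15, "sm": 15},
    q_sd=0.08, beta_modularity=1.8, beta_interaction=-2.4,
    groups={"walk": {"ef": 0.16, "crf": 0.55}},
    seed=11,
)
cohort = simulate_cohort(cfg)
table = measure_cohort(cohort, cost=0.06)
res = fit_group_models(table, spec=BootstrapSpec(n_boot=2000, seed=0))["walk"]
print(res.table[["B", "ci_lo", "ci_hi", "p"]].round(3))
```

Output:

```
                          B  ci_lo  ci_hi      p
term
intercept             1.228 -0.340  2.892  0.111
age                  -0.012 -0.033  0.008  0.259
mean_fd              -1.905 -5.408  4.146  0.390
ef_base              -0.126 -0.281  0.026  0.044
modularity            2.949  1.669  4.518  0.000
ef_base_x_modularity -2.825 -4.770 -1.215  0.000
```

The fitted model (n = 32, R² = 0.687) recovers the planted structure:
a positive modularity slope whose BCa 95% CI excludes zero, and a
negative EF × modularity interaction — subjects with lower baseline EF
show the stronger modularity–gain relationship. The coefficient is on
the scale of *measured* spectral Q, which is correlated with but not
identical to the generator's latent target, so its magnitude is a
rescaled version of the planted 1.8.

A command-line front end wraps each stage
(`modgain simulate | connectome | metrics | qc | behavior | analyze`);
run `modgain --help` for usage.

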
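# recumbency

Automated detection of **group recumbency** — the moments when every pig
in a pen is lying down — from camera-derived group velocity.

Group recumbency in weaned piglets signals thermal comfort and group
health, but per-animal posture detection fails exactly when it matters:
small pigs overlap when they lie together.  This package implements the
alternative of classifying a whole pen at once from a single signal, the
cumulative group velocity recorded by an overhead tracking camera:

    v = Δp / Δt

the summed frame-to-frame displacement of all animals detected as
standing, divided by the frame interval, averaged over 5-minute windows.
A window is coded recumbent (0) when `v ≤ θ` for a fitted cutoff θ, and
active (1) otherwise.  The cutoff is fitted by maximizing training
accuracy over every decision boundary of the observed velocities and is
evaluated by seeded 10-fold cross-validation with sensitivity
TP/(TP+FN), specificity TN/(TN+FP) and accuracy (TP+TN)/N, where the
positive class is "some animal standing".

The package is aimed at precision-livestock researchers and engineers who
need a tested, reproducible reference for this measurement-to-decision
chain.  Because farm tracking data is rarely distributable, a first-class
synthetic generator produces tracked trajectories, ground-truth ethograms,
two-observer label tables and images with controllable blur that have the
statistical structure the analysis assumes.

Stages (each is a module and a CLI subcommand):

| stage | module | what it does |
|---|---|---|
| simulate | `recumbency.synthetic` | trajectories, ethograms, coder tables, images |
| blur QC | `recumbency.blur` | Laplacian-variance sharpness score, cutoff filter |
| velocity | `recumbency.velocity` | pair velocities, 5-min windows, image↔window link |
| coding | `recumbency.coding` | intercoder agreement, consensus labels, composition |
| fit | `recumbency.threshold` | exhaustive, stepwise-loop and mean+SD cutoff fitters |
| evaluate | `recumbency.evaluation` | confusion metrics, k-fold CV, Welch t-test |
| run | `recumbency.pipeline` | end-to-end orchestration with a deterministic manifest |

## Worked example

```python
from recumbency import (
    sample_velocity_dataset, fit_exhaustive, cross_validate, velocity_ttest,
)

# 4000 window velocities: ~10% recumbent windows carrying only detection
# jitter |N(0, 2e-4)| m/s, ~90% active windows at N(5e-3, 1.2e-3) m/s.
samples = sample_velocity_dataset(4000, seed=1)

model = fit_exhaustive(samples["v_mps"], samples["code"])
print(f"fitted threshold: {model.threshold_mps:.10f} m/s")

report = cross_validate(samples, k=10, seed=1)
avg = report.averages
print(f"10-fold CV: accuracy {avg['accuracy_pct']:.2f}%  "
      f"sensitivity {avg['sensitivity_pct']:.2f}%  "
      f"specificity {avg['specificity_pct']:.2f}%")

t = velocity_ttest(samples)
print(f"Welch t-test: t = {t.t_statistic:.1f}, p = {t.p_value:.3g}")
```

prints

```
fitted threshold: 0.0005868763 m/s
10-fold CV: accuracy 99.92%  sensitivity 99.95%  specificity 99.79%
Welch t-test: t = 235.7, p = 0
```

The fitted cutoff lands a little below 6e-4 m/s — between the recumbent
jitter tail and the slowest active windows, the same order of magnitude a
real rearing dataset yields — and cross-validated accuracy sits within a
tenth of a point of the mixture's analytic optimum
(`recumbency.bayes_accuracy()` ≈ 99.98%).  The t-test confirms the two
classes are separable in velocity.  On real farm data the classes overlap
far more (camera soiling, imperfect tracking), which is why the blur-QC
stage exists and why field accuracy is substantially lower than on clean
synthetic mixtures.

The full chain from camera frames to a metric report:

```sh
recumbency run --config config.yml     # see RunConfig for the keys
```

writes `trajectories.csv`, `blur_manifest.csv`, `windows.csv`,
`linked.csv`, `model.json`, `report.json` and a `manifest.json` whose
hashes, counts and metrics are byte-identical across runs with the same
config and seed.

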
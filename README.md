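# occlusim

Simulation and analysis toolkit for a curved-trajectory extrapolation
task: a dot moves along a circular arc, disappears behind a half-disk
occluder, and the observer must predict which of 20 angular bins on
the occluder's far edge it will reemerge into.

The package is built for computational cognitive scientists studying
when decision makers rely on an internal **predictive model** of the
world versus a learned **stimulus-response mapping**.  It provides:

* **Exact task geometry** — a trajectory with curvature κ (inverse
  pixels) and launch orientation θ emerges at
  φ = θ − sign(κ)·arcsin(|κ|R/2), partitioned into 20 bins of 9°.
* **A model-based observer** — a constant-acceleration Kalman filter
  (state x = (p, v, a) per axis, x' = Fx + w, z = Hx + v) that tracks
  the visible dot and extrapolates blindly through occlusion.  Its
  internal model does not contain circular motion, so it carries a
  curvature-dependent extrapolation bias by design.
* **A model-free agent** — tabular Q-learning,
  Q(s,a) ← Q(s,a) + α(r − Q(s,a)), over noisily perceived (θ, κ)
  states identified by nearest-prototype matching.
* **The set-size sweep** — train both strategies on 4–20 trajectories
  for 2000 trials and compare percent correct via
  ln(mapping/predictive), locating the regime each strategy wins.
* **Choice-likelihood models and Bayes factors** — a full 20-category
  extrapolation model vs a restricted (trained-bins-only) classifier,
  with grid-marginalized model evidence
  log BF = log ML(classifier) − log ML(full) for classifying
  individual subjects' strategies, plus fixed-bin vs
  radius-consistent classifier variants for multi-radius sessions.
* **Schedule generators, behavioral metrics, synthetic subjects** and
  a CLI, so the entire analysis runs end to end with no external
  data.

## Worked example

Calibrate both observers to the behavioral pre-test accuracy level
(~25% correct, 5× chance) and run the training-set-size sweep:

```python
import numpy as np
from occlusim.stimuli import ExperimentConfig, sample_test_set
from occlusim.kalman import calibrate_predictive_noise
from occlusim.qpolicy import calibrate_policy_noise
from occlusim.sweep import simulate_sweep

exp = ExperimentConfig.exp1()
pretest = sample_test_set(exp, 80, np.random.default_rng(1))     # 320 trials
kcfg, kacc, kdist = calibrate_predictive_noise(0.25, pretest, seed=1)
pcfg, pacc = calibrate_policy_noise(kacc, pretest, seed=1)
sweep = simulate_sweep(exp, kcfg, pcfg, seeds=tuple(range(1, 11)))
for m, pm, pp in zip(sweep.set_sizes,
                     sweep.percent_correct_mapping.mean(axis=1),
                     sweep.percent_correct_predictive.mean(axis=1)):
    print(f"set size {m:2d}: mapping {pm:5.1f}%  predictive {pp:5.1f}%")
```

Output:

```
set size  4: mapping  96.2%  predictive  29.3%
set size  8: mapping  71.8%  predictive  29.9%
set size 12: mapping  53.0%  predictive  28.4%
set size 16: mapping  43.0%  predictive  28.1%
set size 20: mapping  34.9%  predictive  28.0%
```

Reading the numbers: the predictive observer, calibrated so its
pre-test accuracy matches the behavioral ~25% level, performs at
≈28-30% regardless of how many trajectories are trained — it does not
learn.  The mapping agent is near ceiling with 4 well-separated
trajectories (≈100 repetitions each) and degrades steeply as the
training set grows and its states become perceptually confusable.
Under this input-matched calibration the mapping strategy retains an
advantage across the whole grid; see `docs/methods.md` for why, and
for the noise regime in which the advantage would instead be confined
to small training sets.

Classifying a synthetic subject's strategy from its choices:

```python
from occlusim.choice_models import CategoryPartition, bayes_factor
from occlusim.subjects import StrategySpec, simulate_subject

part = CategoryPartition.restricted(exp.trained_bins)      # bins 1,7,13,17
spec = StrategySpec(kind="restricted_classifier", sigma=9.0, lapse=0.05,
                    partition=part)
subject = simulate_subject(pretest, spec, np.random.default_rng(2))
ev = bayes_factor(subject, exp.trained_bins)
print(f"log BF = {ev.log_bayes_factor:.1f} -> {ev.label}")
# log BF = 500.2 -> mapping
```

Positive log Bayes factors favor the restricted classifier (the
"mapping" strategy), negative ones the full 20-category extrapolation
model; |log BF| > 3 counts as strong evidence.

The same operations are available from the shell:

```bash
occlusim gen-stimuli --experiment 1 --group 4traj --seed 0 --out session.csv
occlusim simulate --schedule session.csv --strategy full_model --seed 1 --out choices.csv
occlusim metrics --choices choices.csv --out summary.csv
occlusim fit --choices choices.csv --out evidence.csv
occlusim run-all --seed 0 --out-dir results
```

## Layout

```
src/occlusim/
  geometry.py       arcs, occluder, bins, emergence angle
  stimuli.py        experiment configs and schedule generators
  kalman.py         predictive (model-based) observer + calibration
  qpolicy.py        Q-learning (model-free) agent + calibration
  sweep.py          set-size sweep and crossover analysis
  choice_models.py  choice likelihoods, marginal likelihoods, Bayes factors
  metrics.py        percent correct, bin distances, confusability, KS
  subjects.py       synthetic subjects, cohorts, recovery experiments
  io.py, pipeline.py, cli.py   CSV/YAML harness and command line
docs/methods.md     modelling assumptions, parameters, limitations
```
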
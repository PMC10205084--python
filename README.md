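# dsschoice

Strategy inference for **discrete-sample-stimulus (DSS)** choice tasks:
did the subject *integrate* the evidence stream, or did it rely on a
non-integration shortcut?

In a DSS task each trial presents a short sequence of stimulus samples
(motion pulses, oriented gratings, sound frames), sample *i* of trial
*t* carrying a signed evidence value *S<sub>ti</sub>*, and the subject
ends the trial with a binary choice. Because the experimenter controls
every sample, the full evidence-to-choice mapping can be modeled. This
package implements three competing observer models and the analyses
that tell them apart, for experimentalists and modelers working with
monkey-, rat- or human-style DSS data:

- **Temporal integration** — a (bilinear) logistic read-out of the
  weighted evidence sum, *p(r<sub>t</sub>) = σ(β₀ + γ<sub>t</sub>
  Σᵢ βᵢ S<sub>ti</sub>)*, with per-session gains γ; fitted by penalized
  ML with a Laplace posterior approximation.
- **Snapshot** — a mixture model in which each trial's choice depends on
  a single attended sample (or K-sample window) drawn from a multinomial
  attention policy (π₁…πₙ, π_L, π_R), with deterministic or logistic
  response rules and lapses; fitted by safeguarded EM.
- **Extrema detection** — commit to the first sample whose noisy
  evidence crosses ±θ, with a closed-form first-passage likelihood,
  random-guess or last-sample default rules, lapses and a
  varying-threshold variant; fitted by bounded multi-start MLE.

Around the models: AIC comparison, psychophysical kernels, quantile
psychometric curves, boundary (best-case) performance of the
non-integration families, **integration maps** (smoothed choice
probability over early vs late evidence — straight diagonal isolines
are the signature of summation), conditional psychometric fits,
disagree-trial analysis (largest sample vs total evidence) with
parametric-bootstrap CIs, subjective evidence weighting (odd transfer
function, discrete levels or GP prior), Poisson-GLM spike-count
analysis with neural integration maps, and synthetic generators for all
three species' stimulus designs so the whole pipeline runs on known
ground truth.

## Worked example

Simulate a two-session monkey-style experiment from an integrating
observer, then ask which strategy the data support:

```python
import numpy as np
import dsschoice as d

# generate a monkey-style session set and simulate an integrating observer
design = d.MonkeyDesign(n_sessions=2, trials_per_session=5000)
trials = d.gen_monkey_stimuli(design, seed=7)
kernel = np.array([0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3])
observer = d.IntegrationParams(beta0=0.1, beta=kernel,
                               gamma=trials.meta["session_gains"])
trials.choice = d.simulate_choices(observer, trials, seed=8)

# fit all three strategy models
fit_int = d.fit_integration(trials, use_session_gain=True)
fit_snap = d.em_fit_snapshot(trials, rule="deterministic",
                             lapse_mode="fixed", seed=0)
fit_ed = d.fit_extrema(trials, seed=0)
print(d.compare_models([fit_int, fit_snap, fit_ed]).to_string(index=False))

# psychophysical kernel of the fitted data
k = d.psychophysical_kernel(trials)
print("kernel:", np.round(k.weights, 2))

# disagree trials: does the total evidence or the largest sample win?
rep = d.disagree_alignment(trials, models=[fit_int], n_boot=100, seed=9)
print(f"disagree trials: {rep.indices.size}, "
      f"observed alignment {rep.observed_alignment:.3f}, "
      f"integration CI {rep.model_ci[fit_int.variant]}")
```

Output:

```
      model                               variant  n_params       loglik         aic  delta_aic_best  delta_aic_vs_integration
integration              integration.session_gain         9 -2339.111307 4696.222613        0.000000                  0.000000
   snapshot snapshot.deterministic.K1.fixed_lapse         6 -3417.706139 6847.412277     2151.189664               2151.189664
    extrema                  extrema.random_guess         4 -2832.676958 5673.353916      977.131303                977.131303
kernel: [0.9  0.75 0.67 0.57 0.48 0.42 0.31]
disagree trials: 158, observed alignment 0.665, integration CI (0.6329113924050633, 0.7691455696202532)
```

The integration model wins the AIC comparison by a wide margin (ΔAIC >
900 against both alternatives), the recovered kernel matches the
generating weights, and on the 158 trials where the largest sample
contradicts the total evidence the observer follows the total 66% of
the time — inside the integration model's bootstrap CI and far from the
below-chance alignment an extrema detector would produce.

A decreasing kernel, a ΔAIC this lopsided and above-chance disagree
alignment are exactly the signatures reported for real subjects; on
real data you would load trials with `d.read_trials("trials.csv")`
instead of generating them.

## Command line

```bash
dss simulate --species monkey --model integration --n-trials 5000 --seed 7 -o trials.csv
dss fit integration trials.csv -o fit.json
dss fit extrema trials.csv -o fit_ed.json
dss compare fit.json fit_ed.json
dss map trials.csv fit.json -o map.json
dss disagree trials.csv --fits fit.json
```

`dss validate`, `dss info`, `dss kernels` and `dss subjective` cover the
remaining analyses; every command is a thin wrapper over the library.

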
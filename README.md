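# astromem

Hybrid short-term-memory models for visual change detection, built around a
mean-field depressing synapse with astrocytic modulation of release
probability. The package provides:

- **`astromem.synapse`** — the depressing-synapse + astrocyte ODE system
  (resources `x`, gliotransmitter `y`, release probability `u`) integrated
  with the explicit Euler method, plus closed-form equilibrium helpers.
- **`astromem.task`** — a simulator for the visual change-detection task:
  250 ms image flashes separated by 500 ms gray screens, one Go
  (image change) or Catch (sham change) event per session, and 5%
  flash omissions that never precede the event.
- **`astromem.encoder`** — a small NumPy convolutional encoder (two conv +
  maxpool stages, FC stage, rectified 64-unit feature layer, softmax
  classifier) and a synthetic sparse feature-bank generator that fully
  substitutes for it, so nothing requires an image dataset.
- **`astromem.models`** — three comparable 64-16-1 heads: depression +
  astrocyte (`astro`), depression only (`depression`), and a recurrent
  baseline (`rnn`), with hand-written gradients, an Adam optimizer, and a
  training loop whose early stopping is driven by the d-prime metric
  (threshold/patience rule).
- **`astromem.metrics`** — the behavioral statistics: logistic squash,
  Bernoulli response sampling, hit/false-alarm rates, the d-prime
  detectability index, the 8×8 response-transition matrix, and the
  symmetric/antisymmetric matrix asymmetry index.
- **`astromem.experiment`** — end-to-end orchestration: per-model training
  repetitions, paired evaluation sessions, mean±std comparison reports,
  and diagnostic figures.

Everything is plain NumPy/SciPy; runs are exactly reproducible from a seed.

## CLI

```sh
astromem make-features --n-images 8 --out bank.csv
astromem simulate-synapse --steps 60 --out trajectory.csv
astromem train-head --model astro --features bank.csv --weights-out head.npz
astromem evaluate --model astro --weights head.npz --features bank.csv
astromem compare --seed 1 --n-runs 5 --out-dir results/compare
astromem plot --trajectory trajectory.csv --out-dir figures/
```

`compare` accepts a YAML config (see `ExperimentConfig.from_yaml`) nesting
task, synapse, head, and training settings.

## Notes on conventions

- One simulation step equals one 250 ms flash; sessions are 200 steps.
- d-prime defaults to the pooled convention: (hit − false-alarm rate)
  divided by the standard deviation of the pooled binary responses
  (bounded by 2 for balanced classes). Block-wise and fixed-sigma variants
  are available.
- The asymmetry index centers the response matrix by its grand mean and
  reports `(‖antisym‖ − ‖sym‖) / (‖sym‖ + ‖antisym‖)`; the convention is
  recorded in every result.
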
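# ordpat

Ordinal-pattern statistics for time-series classification: permutation
entropy, motif-frequency feature vectors, a forbidden-transition-aware
Markov generator of synthetic series, and a deterministic clustering
pipeline that contrasts the two feature choices.

## The problem

Permutation entropy (PE) summarises the dynamics of a series
`x = x_0, …, x_{N−1}` by sliding a window of `m` samples, encoding each
window as its *ordinal pattern* (the permutation sorting the window —
`m! = 6` patterns for the usual `m = 3`), and taking the Shannon entropy of
the pattern histogram `p̂`:

```
PE(x, m, N) = − Σ_{j : p̂(Π_j) > 0}  p̂(Π_j) log p̂(Π_j)
```

Collapsing the `m!`-bin histogram into one scalar is a many-to-one mapping:
two signal classes whose histograms have the *same bin amplitudes at
different patterns* ("histogram compensation") get identical PE and become
indistinguishable to any PE-threshold classifier, even though they are
trivially separable from `p̂` itself.  `ordpat` is a toolkit for studying
exactly this effect — for people working with signal-complexity features
(physiological records, nonlinear dynamics, symbolic time-series
analysis) who want to know when the raw frequency vector should replace
the scalar entropy.

The package provides:

- **`ordpat.ordinal`** — motif extraction, the motif alphabet, relative
  frequencies, PE, and the window-overlap rule that makes most consecutive
  motif pairs *forbidden transitions* (each motif admits only `m`
  successors; 18 of 36 ordered pairs for `m = 3`).
- **`ordpat.hmm`** — a six-state Markov chain in which each state emits one
  motif and forbidden transitions carry probability zero.  Given a
  probability triple per state it generates real-valued series whose motif
  sequence follows the chain *exactly* (the round trip motif-sequence ↔
  state-sequence is an identity), so the motif law of a synthetic class is
  fully controlled.
- **`ordpat.cluster`** — deterministic 2-means (Euclidean metric, max–min
  initialisation from the first record, fixed 10 iterations), best-mapping
  accuracy scoring, an optimal-threshold scorer for scalar features, and a
  leave-one-out protocol with nearest-centroid classification.
- **`ordpat.experiments`** — the full synthetic experiment grids, plus a
  packaged table of motif frequencies for 30 real body-temperature records
  (16 healthy controls, 14 febrile patients).

## Worked example

Generate a biased class, inspect its histogram, then reproduce the
compensation effect end to end:

```python
import numpy as np
from ordpat import (ExperimentSpec, build_matrix_from_triple, generate_series,
                    permutation_entropy, relative_frequencies,
                    run_experiment_modes, stationary_distribution)

A = build_matrix_from_triple((0.1, 0.1, 0.8))      # strongly biased chain
series = generate_series(A, 1000, np.random.default_rng(7))
fv = relative_frequencies(series.amplitudes)
print("p_hat =", np.round(fv.p, 3))
print("PE    =", round(permutation_entropy(fv), 4), "nats")
print("stationary =", np.round(stationary_distribution(A), 3))

res = run_experiment_modes(ExperimentSpec(triple_a=(0.5, 0, 0.5),
                                          triple_b=(0, 0.5, 0.5), seed=42))
print(f"PE mode:     {res['pe'].accuracy_mean:.1f} +/- {res['pe'].accuracy_sd:.2f} %")
print(f"vector mode: {res['vector'].accuracy_mean:.1f} +/- {res['vector'].accuracy_sd:.2f} %")
```

prints

```
p_hat = [0.053 0.054 0.399 0.05  0.049 0.395]
PE    = 1.3452 nats
stationary = [0.05 0.05 0.4  0.05 0.05 0.4 ]
PE mode:     55.4 +/- 1.42 %
vector mode: 100.0 +/- 0.00 %
```

The sampled histogram of one 1000-sample series matches the chain's
stationary law to sampling error.  The second block is the headline
phenomenon: the triples `(1/2, 0, 1/2)` and `(0, 1/2, 1/2)` generate
mirrored histograms with identical bin amplitudes, so the scalar PE stays
at the ~55% chance floor of best-mapping accuracy while clustering the raw
frequency vectors separates the 200 series perfectly, realisation after
realisation.

The same machinery is exposed on the command line:

```bash
ordpat simulate --triple-a 1/3,1/3,1/3 --triple-b 1/10,1/10,8/10 \
        --n-per-class 100 --length 1000 --seed 1 --out-dir sim/
ordpat features --input sim/manifest.csv --out features.csv
ordpat cluster --features features.csv --out-prefix run1
ordpat temperature --feature-mode vector --out temp.json
ordpat grid --builtin pe-biased --out grid.csv
```

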
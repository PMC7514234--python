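# Methods

## Ordinal patterns and permutation entropy

A univariate series `x = x_0, …, x_{N−1}` is symbolised by sliding a window
of `m` consecutive samples (stride 1, fully overlapping, `N − m + 1`
windows).  Each window is mapped to its *motif*: the permutation of window
positions listed in ascending amplitude order, i.e. the stable argsort of
the window.  For `m = 3` the six motifs are indexed in the canonical state
order

```
q0 = (0,1,2)  q1 = (0,2,1)  q2 = (1,0,2)  q3 = (1,2,0)  q4 = (2,1,0)  q5 = (2,0,1)
```

(for `m ≠ 3` the alphabet is lexicographic).  The normalised motif
histogram is the relative-frequency vector `p̂` (components sum to 1 and are
multiples of `1/(N−m+1)`), and the permutation entropy is its Shannon
entropy over strictly positive components,

```
PE = − Σ_{p̂_j > 0} p̂_j log p̂_j .
```

Natural logarithms are the default; base 2 and normalisation by `log m!`
are options.  Classification results are invariant to both choices because
they rescale every record's feature identically.  Ties inside a window are
broken stably (the earlier sample ranks lower) and flagged with a
`TieWarning`; tie handling only matters for quantised real data, since the
generator below is tie-free almost surely.

## Admissible and forbidden motif transitions

Consecutive windows share `m − 1` samples, so the rank order of the shared
samples constrains the successor motif: motif `b` may follow motif `a`
exactly when the order pattern of `b`'s first `m − 1` positions equals the
order pattern of `a`'s last `m − 1` positions.  Every motif therefore has
exactly `m` admissible successors (the new sample can fall in any of the
`m` rank regions defined by the `m − 1` carried samples); for `m = 3` that
is 18 admissible ordered pairs out of 36.  The implementation derives
admissibility from this overlap rule alone, and the unit tests verify it
against a brute-force region-enumeration oracle for `m ∈ {2, 3, 4}`.

## The motif-emitting Markov generator

Synthetic series are produced by a six-state ergodic Markov chain in which
each state deterministically emits one motif and all forbidden transitions
carry probability zero.  A full 6×6 transition matrix can be supplied; the
common configuration is a single probability triple `(α1, α2, α3)` shared
by all states, spread over each state's three admissible successors.

**Successor order for triple assignment.**  Two orderings of the admissible
successors are defensible a priori (ascending state index, or the row order
of the admissibility table).  The package fixes the latter:
ascending-overlap states assign `(α1, α2, α3)` to `(q0, q1, q5)` and
descending-overlap states to `(q3, q4, q2)` (`TRIPLE_TARGET_ORDER`).  This
convention has a characterising symmetry: negating the amplitudes of the
process (which maps q0↔q4, q1↔q3, q2↔q5) is equivalent to swapping the
first two entries of the triple.  Consequently `(1/2, 0, 1/2)` and
`(0, 1/2, 1/2)` generate *exactly* mirrored motif histograms — stationary
laws `(1/3, 0, 1/6, 1/6, 0, 1/3)` and `(0, 1/6, 1/3, 0, 1/3, 1/6)` — the
histogram-compensated pair whose identical bin amplitudes defeat any
scalar, permutation-invariant summary such as PE while remaining trivially
separable in frequency space.  Under the ascending-index alternative this
compensation does not occur (the pair's stationary entropies differ by
0.057 nats and mirrored triples of the `(12/20, 5/20, 3/20)` type become
entropy-identical instead), which contradicts the phenomenon this tool
exists to exhibit; the table-order convention is therefore the package's
fixed choice, not an option.

**State emission.**  The initial state is uniform over all six states (or
supplied explicitly); each subsequent state is drawn from the source row.
The unbiased triple `(1/3, 1/3, 1/3)` makes the matrix doubly stochastic,
so its stationary law is uniform and long-run motif frequencies converge
to 1/6.

**Amplitude synthesis.**  The first `m` amplitudes are i.i.d. uniform(0,1)
draws sorted into the initial motif's order.  Every later sample must fall
in the open amplitude region that gives the new window its emitted motif:
the motif dictates the new sample's rank among the `m − 1` carried
samples, so the region is either an interval between two known amplitudes
(sampled uniformly) or an unbounded tail (sampled uniformly on a width-`Δ`
extension beyond the boundary, `Δ = 1` by default).  Only ranks matter to
every ordinal statistic, so the in-region law and `Δ` are free choices;
this is enforced by the round-trip invariant (the motif sequence of the
synthesised amplitudes equals the emitted state sequence exactly, for
every seed and every `Δ > 0`), which the test suite checks.  Dominantly
ascending or descending chains drift without bound by construction; no
detrending is applied.

Datasets draw one independent RNG substream per series
(`numpy.random.Generator.spawn`), so generation is reproducible and
order-independent.

## Classification pipelines

Records are classified unsupervised from one of two feature sets computed
per series: the full `m!`-dimensional frequency vector, or the scalar PE.

**Frequency vectors — deterministic 2-means.**  Euclidean metric, `k = 2`.
Initialisation is max–min: the first record in dataset order seeds one
centroid and the record farthest from it seeds the other (ties to the
lowest index).  Exactly 10 assign/update rounds follow (centroids replaced
by arithmetic member means; an empty cluster keeps its previous centroid;
assignment ties go to the lower-index centroid), closed by a final
assignment pass so the reported partition is consistent with the reported
centroids.  The procedure has no random element: identical inputs in
identical order give bit-identical results, and the within-cluster sum of
squares is non-increasing over rounds.  Accuracy is scored as the better
of the two cluster→class bijections, in percent; with exchangeable classes
this best-mapping rule floors slightly above 50%, which is why chance
levels report as ≈51–56% rather than 50%.

**Scalar PE — optimal threshold.**  A single feature is classified by one
cut point on its axis; the package reports the resubstitution accuracy of
the best cut over all cut positions and both orientations.  This is the
standard way a scalar complexity index is used as a lone discriminator,
and it was chosen over running 2-means on the 1-d feature after a direct
comparison: across the full-scale synthetic grid the threshold reproduces
the expected accuracies of mildly biased pairs (≈96% for unbiased vs
`(3/10, 3/10, 4/10)`), whereas 1-d 2-means systematically undershoots them
by 6–8 points because its two means straddle the overlap region
suboptimally.  `kmeans` still accepts 1-d input for anyone who wants the
clustering variant.

**Leave-one-out.**  Each realisation omits one record per class (drawn
uniformly, with replacement across realisations), refits 2-means on the
remaining records in their original order, labels the final centroids by
member majority (ties and empty clusters fall back to the
first-appearing class), and classifies the omitted records by nearest
centroid.  Reported: global held-out accuracy over `2 × realisations`
classifications, per-class accuracies, and per-class error counts; the
default is 100 realisations.

## Synthetic experiment protocol

An experiment is two generated classes (default 100 series of 1000 samples
each per class), reduced to features, classified, and repeated over 10
fully re-randomised realisations (fresh initial states, transitions and
amplitudes per realisation); accuracy is reported as mean ± sample
standard deviation.  When both feature modes are evaluated they share each
realisation's generated data, so mode comparisons are paired.  These sizes
are the package's standard study conditions and are what
`scripts/acceptance.py` runs.

## The body-temperature feature table

The packaged fixture holds the motif relative-frequency vectors of 30
body-temperature records — 16 healthy controls monitored during daily
activity and 14 febrile in-patients — as a 30×6 table (rows sum to 1
within printed rounding; loading validates the schema).  The raw
temperature signals are not part of the package; PE for these records is
computed from the frequency vectors directly, which is exact because PE is
a function of the histogram alone.  Dataset order is Control00–15 then
Pathological00–13, which fixes the max–min initialisation (the first
record is a Control).

Two caveats a user should know.  First, the two classes overlap strongly
in frequency space: the dominant variance direction (the `(0,1,2)`
component ranges from 0.22 to 0.54) does not align with the class
difference, the table contains a Control/Pathological pair of
near-duplicate vectors and a duplicated Control row, so unsupervised
2-means splits along variance rather than class (the packaged analysis
reports 56.7% vector-mode accuracy and 63.3% for the PE threshold).
Second, published analyses of this dataset report substantially higher
clustering accuracy; no configuration of the documented pipeline
(initialisation sweeps, feature transforms, online updates) reproduces
that from this table, and the package deliberately reports only what the
documented algorithms compute.

## Defaults and tunables

| parameter | default | meaning |
| --- | --- | --- |
| `m` | 3 | embedding dimension; alphabet size `m!` |
| `n_samples` | 1000 | series length (998 motifs at `m = 3`) |
| `n_per_class` | 100 | series per class per realisation |
| `realisations` | 10 | independent repeats of an experiment |
| `Δ` (`delta`) | 1.0 | width of the unbounded-region extension |
| `iterations` | 10 | k-means assign/update rounds |
| LOO `realisations` | 100 | held-out repeats |

Numerical tolerances: frequency vectors must sum to 1 within 1e−9;
transition rows within 1e−9; stationary distributions are solved to a
residual below 1e−8 (eigen-solve plus a linear-system refinement), with
reducible chains flagged by `ReducibleChainWarning` (e.g. the compensated
triples make two states transient).

## What the generator does and does not emulate

The generator controls the motif law exactly, which is the point: it
produces classes whose *ordinal* statistics are prescribed, letting the
feature comparison (scalar PE vs frequency vector) be studied with known
ground truth.  It does not emulate amplitude distributions, trends,
seasonality, measurement noise or quantisation of real physiological
signals — its amplitudes are an arbitrary tie-free realisation of the rank
constraints.  Passing synthetic tests therefore demonstrates properties of
the ordinal machinery, not end-to-end performance on any particular
recording modality; the temperature table is the package's only real-data
anchor, with the caveats above.
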
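# Methods

This note documents the models and procedures implemented in `pgk`,
the assumptions behind them, the defaults that matter, and what the
synthetic benchmark does and does not demonstrate.

## Perceptual encoding

Raw trait measurements x_i arrive in heterogeneous units (pixel counts,
index values, sensor readings). Each trait is mapped to a perceptual
intensity by min–max normalisation over a reference cohort,
p_i = (x_i − min_i)/(max_i − min_i), clamped to [0, 1] for out-of-range
values. A degenerate trait (cohort max = min) carries no contrast and
maps to the neutral 0.5. Inside cross-validation the extrema are fitted
on the training folds only, so held-out plants are clamped rather than
allowed to stretch the scale — a small but real leakage channel
otherwise.

Intensities are optionally discretised into low/medium/high states at
fixed cuts (1/3, 2/3), lower bounds inclusive; per-trait empirical
tertiles are available (`empirical_thresholds`) when the cohort is
large enough to estimate them. The canonical trait order
(LC, LA, TU, VP, ES, WI) is fixed package-wide because it defines the
coordinates of the interaction embedding; every serialisation carries
it explicitly. The trait registry is configurable for other trait sets,
but the six-trait set is the default everywhere.

### Already-perceptual inputs

The deviation representation below is invariant to the global inversion
p → 1 − p. This has a practical consequence: if data that already live
on the perceptual scale (e.g. the synthetic generator's output) are
pushed through min–max normalisation again, a symmetric class layout
can be stretched so that the two extreme classes become mirror images —
and then their deviation graphs *coincide exactly*. Functions that
consume trait tables (`cv_classify`, `stage_zones`) therefore take
`assume_perceptual=True` to use such values directly; the default
(False) is correct for raw measurement tables.

## Deviation graphs

A plant's graph has one node per trait (carrying intensity and state)
and edge weights w_ij = |p_i − p_j| computed on the complete graph,
after which edges with w_ij < ε are removed (default ε = 0.05; ε = 0
keeps the complete graph). Pruned edges are absent from the edge set,
not stored as zeros; the embedding reinserts zeros at their fixed
coordinates. Because |·| is a metric on [0, 1], weights satisfy the
triangle inequality, and edge count is non-increasing in ε.

An alternative construction wires edges from the absolute Pearson
correlation of trait pairs across a training cohort (|r| ≥ r_min,
default 0.3, or a two-sided test at α = 0.05 behind a flag), giving a
shared topology with per-plant node attributes. The deviation mode is
the default; the correlation mode exists because trait–trait
correlation networks are the established alternative in systems-level
phenotyping. Graphs serialise to GraphML and a JSON dialect;
round-trips are lossless to 1e-12.

## Kernels

The interaction embedding Φ(G) reads the 15 edge weights in the
canonical pair order (LC–LA, LC–TU, …, ES–WI); an augmented mode
appends the 6 node intensities. Since every graph shares the node set,
Φ is a fixed-dimensional vector and

* **PGK-rbf** exp(−‖ΔΦ‖²/2σ²) is a Gaussian kernel on that embedding,
* **PGK-linear** ⟨Φ_i, Φ_j⟩ is an explicit inner product,

so both are Mercer kernels by construction, as is the normalised form
K̃_ij = K_ij/√(K_ii K_jj). Every Gram matrix records its smallest
eigenvalue as a PSD certificate (tolerance −1e-8); `check_psd` verifies
arbitrary matrices. The default σ is the median heuristic (median
pairwise ‖ΔΦ‖ over the training cohort, falling back to 1.0 when all
embeddings coincide), overridable by grid search.

The **Weisfeiler–Lehman** subtree kernel runs on the perceptual state
labels and the pruned topology, counting compressed
(label, sorted neighbour multiset) pairs over iterations 0..h. It runs
on the *pruned* graph deliberately: on the unpruned complete graph
every node sees all others, neighbourhood multisets are determined by
the global label histogram, and WL collapses to the h = 0 histogram
kernel (a property the test suite asserts). The **shortest-path**
kernel bins Floyd–Warshall distances on edge weights (bin width 0.1)
keyed by unordered endpoint-state pairs, skipping unreachable pairs;
it too is an explicit feature-count inner product. Both baselines are
normalised to unit diagonal before entering the SVM, since raw count
kernels scale with pruning density.

## Classification and zone staging

`cv_classify` runs stratified k-fold (default k = 5) with an SVM on the
precomputed kernel. Hyperparameters — C ∈ {0.1, 1, 10, 100} and, per
kernel, σ ∈ {0.1, 0.25, 0.5, 1.0, median} or h ∈ {0, 1, 2} — are chosen
by inner stratified 3-fold search on the training folds only; ties
break toward smaller C, then the earlier grid entry. Everything
data-dependent (normalisation extrema, median-heuristic σ) is fitted
per outer fold on training data. Metrics come from the confusion
matrix: accuracy = trace/total; precision, recall and F1 one-vs-rest
per class with macro averaging (classes never predicted contribute 0),
reported per fold and as mean ± sd.

Zone staging computes the mean pairwise PGK similarity among a zone's
plants and thresholds it at (0.80, 0.60), boundaries inclusive, into
Healthy / Mild Stress / Severe Stress. The (0.80, 0.60) pair is the
unique round-value threshold pair consistent with the reference staging
table. The default staging bandwidth σ = 0.7 is a package calibration:
with the default generator it places within-zone similarities near
0.91 / 0.76 / 0.41 for the three conditions. `compare_methods` runs
paired two-sided tests (Wilcoxon signed-rank by default, paired t-test
optional) over per-seed accuracies of methods evaluated on identical
seed partitions, flagging fewer than 6 pairs as low-power.

## Synthetic field generator

The generator emulates a 3 acres × 10 zones × 3 plants trial
(90 plants). Healthy and Severe class means are the reference trait
intensities of healthy and severely stressed plants
((0.92, 0.88, 0.90, 0.85, 0.87, 0.12) and
(0.45, 0.41, 0.39, 0.72, 0.36, 0.91) in canonical order); Mild means
are per-trait midpoints. Plant vectors are class means plus iid
Gaussian noise clipped to [0, 1], with sd 0.05 / 0.10 / 0.16 by
severity — noise grows with stress so that within-zone similarity falls
as severity rises. Zone conditions default to 60/20/20
Healthy/Mild/Severe per acre; `balanced_field_design()` provides an
exactly balanced assignment (10 zones, 30 plants per condition) used by
the benchmark so that the chance level of a permuted-label control is
exactly 1/3. Everything is reproducible from a single seed.

The leaf-image renderer draws an ellipse of known area, colour and
additive noise (optionally with darker radial "veins") and returns the
exact mask and analytic trait values, giving the image pipeline a
ground truth to test against.

## Image trait extraction

Preprocessing: downscale to a 512-px long side (smaller images are left
untouched), Gaussian smoothing (σ = 1 px), then segmentation by the
excess-green index ExG = 2g − r − b on chromatic coordinates with an
Otsu threshold, keeping the largest connected component; an HSV
hue-band segmenter is available. The six extractors are explicit
proxies, each monotone in the property it names and swappable via the
`TRAIT_EXTRACTORS` registry: LC = mean foreground ExG rescaled from
[−1, 2]; LA = foreground fraction; TU = 1 − normalised GLCM entropy
(8 grey levels, distance 1, four symmetric directions averaged,
background excluded via a reserved level); VP = Sato ridge-response
density; ES = mean Sobel gradient along the mask boundary;
WI = 1 − solidity. No operational formulas exist in the literature for
VP/ES/WI at this granularity; these definitions are this package's own.

## Benchmark sizes and numerical choices

The test suite and the acceptance script use 90-plant fields, 20
generator seeds for averaged claims, 100 random graphs for the Mercer
suite and ≤ 2000-plant draws for law-of-large-numbers checks — sizes at
which every result is stable yet the whole suite runs in about a minute
on one CPU. Kernel symmetry is enforced by averaging K with Kᵀ (removes
BLAS-order float asymmetry); PSD tolerance is −1e-8; graph round-trip
tolerance 1e-12; discretisation bounds are lower-inclusive; SP distance
bins are left-closed with a 1e-12 guard against float boundary error.

## What the synthetic benchmark does and does not show

Passing the benchmark shows that the full pipeline — encoding, graph
construction, embedding, kernel, leakage-free model selection —
recovers condition labels at high accuracy under the stated noise
model, and that staging reproduces the expected spatial pattern. It
does **not** show field realism: the generator draws independent
truncated-Gaussian noise per trait, with no trait–trait correlation
within a class, no spatial autocorrelation between zones, no
acquisition artefacts, and no label noise.

One measured consequence deserves emphasis: under this exactly-Gaussian
noise, a plain linear kernel on the continuous intensity vectors is
near Bayes-sufficient, and the graph representations — which are
invariant to adding a constant to all intensities and to global
inversion, and (for WL) discard magnitudes entirely — pay for those
invariances. At doubled noise the PGK trails the continuous-trait
linear kernel by ≈4 accuracy points and WL by ≈9 (20-seed paired
means). Claims that perceptual state encoding *improves* robustness
concern noise structures (outliers, quantisation-absorbable jitter)
that this generator deliberately does not emulate; the corresponding
directional test in the acceptance suite documents this gap rather than
hiding it.

## Known limitations

* Φ's inversion invariance means two plants with mirrored intensity
  profiles are indistinguishable to the edge-only embedding; the
  augmented mode (appending node intensities) removes this at the cost
  of mixing node and edge scales.
* ε-pruning interacts with noise: near-threshold edges flicker between
  present and absent, adding embedding variance at high noise.
* The correlation-template mode estimates 15 correlations; below ~30
  training plants the template is unstable and the p-value screen is
  underpowered.
* VP/ES extractors are resolution-sensitive; compare only traits
  extracted at the same working size.
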
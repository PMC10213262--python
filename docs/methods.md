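# Methods

## Model

The classifier is a multilayer perceptron with an input layer of panel
genes, exactly two hidden neurons, and four output neurons. Each hidden
neuron computes `tanh(w·x + b)` on the reference-normalized expression
vector `x`; the output layer applies softmax to an affine map of the two
hidden activations, producing probabilities over the subtypes in fixed
alphabetical order (A, IA, ID, IS). The called subtype is the argmax
with no minimum probability; ties (measure-zero on continuous data)
break to the first class in order. Training minimizes the mean
multi-class cross-entropy plus an L2 penalty `α/(2n)·(‖W₁‖² + ‖W₂‖²)`
using L-BFGS with an analytic gradient.

The two-neuron bottleneck is the model's substantive assumption: the
panel's information relevant to subtype is two-dimensional. It doubles
as the interpretability device — the hidden activations are a latent
plane whose axes empirically correspond to the panel's immune and
angiogenesis biology — and as regularization against overfitting a
~124-gene input on cohorts of a few hundred samples.

### Training hyperparameters

| parameter | default | meaning |
|---|---|---|
| `tol` | 1e-4 | minimum per-iteration loss improvement counted as progress |
| `patience` | 10 | consecutive no-progress iterations before stopping |
| `max_iter` | 1000 | hard iteration cap |
| `alpha` | 1e-4 | L2 strength (dimensionless, on normalized features) |
| `init_scale` | 1.0 | weight init is N(0, init_scale/√fan-in), seeded |
| `cv_folds` / `cv_repeats` | 10 / 3 | repeated stratified k-fold layout |
| `alpha_grid` | (1e-4, 1e-2, 1.0) | CV grid; ties go to the smallest α |

The stopping rule is implemented as a callback on the L-BFGS iterates:
the loss is evaluated at each iterate and training stops once it has
failed to improve on the best value by at least `tol` for `patience`
consecutive iterations. The solver's own tolerances are set far below
`tol` so the plateau rule (or the iteration cap) governs. If the solver
ever returns a point worse than the initialization (pathological), the
initialization is kept; a test asserts final loss ≤ initial loss.

Weight initialization uses a seeded generator with 1/√fan-in scaling,
making training bit-deterministic for a given seed and data. A tanh
network has an exact sign symmetry (negating a hidden neuron's input
weights and its output row leaves the function unchanged), so the
orientation of each neuron is arbitrary across seeds; everything
downstream that interprets weights accounts for this.

## Training labels: population-dependent z-score model

Training labels come from the preliminary population-dependent model:
every *weighted* panel gene is z-scored across the cohort (SD with
n−1), each sample's axis score is the mean z over that axis's weighted
genes, and the label is the quadrant of the (immune, angio) pair at
thresholds (0, 0) with "high" strictly above threshold (boundary ties
are assigned low — deterministic, and irrelevant on continuous data).
Unweighted panel genes remain classifier features but do not enter axis
scores; this is the reading we adopt of a panel in which "a subset of
genes is not weighted", and it keeps the labels interpretable.
Zero-variance genes are excluded from scoring with a warning; an axis
left without usable genes is an error, as is a single-sample cohort.

These labels depend on cohort composition — that is the point of the
trained classifier, which replaces them with a frozen, population-
independent decision rule. A test asserts this sensitivity exists
(adding extreme samples changes some labels).

## Frozen-reference normalization

At fit time the panel-restricted training matrix is frozen as (i) the
pooled sorted vector of all its values and (ii) per-gene mean and SD
(n−1). Genes with zero training variance are rejected by name. At
mapping time each new value is replaced by the reference quantile at
its empirical CDF position (midranks; linear interpolation between
pooled values at plotting positions (i+0.5)/M; clamped at the
extremes), then z-scaled per gene with the frozen statistics.

CDF positions are computed from the pooled values of the whole new
dataset by default (`mode="dataset"`). This makes mapping the training
data onto its own reference *exactly* idempotent and makes the map
invariant under any strictly increasing transformation of the new
data's values, while remaining monotone within every sample. A
per-sample mode (`mode="sample"`) uses only within-sample ranks so a
single profile can be normalized alone; its output is quantized to
panel-size atoms, which is the price of sample-independence. Both modes
re-estimate nothing from the training data, matching the frozen-model
design; batch-correction methods that refit on the new cohort are
deliberately out of scope.

## Feature transferability

Within each dataset, each candidate gene receives the normalized rank
(in [0, 1]) of its median expression among the candidate genes; the
transferability score is `1 − mean over dataset pairs |rank
difference|`. The score is symmetric in dataset order, invariant to
per-dataset monotone transformations (exactly so when per-gene medians
are single order statistics, i.e. odd sample counts), and never lowered
by duplicating a dataset. Genes absent from a dataset, or whose median
absolute deviation falls below a dispersion floor in any dataset, are
flagged and scored 0.

The floor is *relative*: MAD < 0.1 × the dataset's median panel MAD.
A quantile-based floor (e.g. flagging the bottom decile) removes a
fixed fraction of genes even when every gene is healthy, and with
several datasets the union of per-dataset deciles prunes well over 10%
of a clean panel; the relative floor flags nothing when dispersions are
homogeneous and still catches constant or absent probes, which is its
purpose. Filtering keeps genes with score ≥ 0.7 (default) and the flag
unset, preserves axis annotations, and errors if the panel empties or
an entire axis is eliminated. The score is a package-defined surrogate
for cross-platform consistency; it is rank-based precisely so that
platform-wide monotone distortions do not move it.

## Biomarker logic and evaluation

A mechanism-of-action rule names the positive subtypes (anti-angiogenic
→ A+IS, immunotherapy → IA+IS, TLR9-agonist combination → IS). In
combined mode a sample is B+ when its summed probability over the
positive subtypes is ≥ 0.5; the boundary case is positive, consistent
with the signed score `2·P(B+) − 1` treating y ≥ 0 as B+ (sources
describing such assays state both "> 50%" and "y ≥ 0 is B+"; we follow
the signed-score convention and note the discrepancy). Single-high mode
calls B+ when one designated subtype's probability reaches a threshold
(e.g. IA ≥ 0.90), a precision-oriented variant.

Evaluation treats B+ as "predicted responder" against RECIST best
objective response (responders = CR+PR; SD/PD non-responders; NE
excluded from all metrics with an audit count — the RECIST-standard
handling, adopted because unevaluable responses carry no outcome
information). All rates are stored as exact fractions of integer
counts; presentation rounding is half-up to 2 decimals (1 for fold
enrichment), matching the printed precision of published cohort tables.
(One published cell, PPV 5/8, prints 0.62 where half-up gives 0.63 —
a round-half-even tie-break there; we keep half-up throughout.)
AUROC uses the Mann–Whitney rank form with midrank ties; all-tied
scores return 0.5 with a warning. The no-biomarker reference is the
prior-probability null classifier with prediction probability equal to
prevalence p, giving closed forms sensitivity = PPV = F1 = p,
specificity = NPV = 1 − p, accuracy = p² + (1−p)²; the Monte-Carlo mode
averages metrics over simulated prediction vectors, skipping replicates
where a denominator vanishes.

## Interpretability: neuron–axis alignment

For each of the two neuron↔axis assignments and each neuron sign
orientation, the alignment of an axis is the fraction of (own-axis
gene, other-axis gene) pairs in which the own-axis gene carries the
larger oriented weight on the assigned neuron (ties half) — a rank
separation statistic: 1.0 when the axis's genes all outweigh the rest,
0.5 when weights carry no axis structure. The best assignment is
reported along with raw positive-weight fractions per neuron × axis,
and an `interpretable` flag (both axes ≥ 0.8).

A plain "fraction of own-axis genes with positive weight" is also
informative (~0.99 on trained synthetic models) but its permutation
null is inflated: trained neurons have a global sign imbalance (all
own-axis genes coherently signed), so a random gene subset is far more
than 50% positive after orientation. The rank-separation form has a
permutation null of ~0.5 by construction and the same trained behavior,
so it is the reported statistic. On data simulated with independent
axes, cross-axis weight signs are genuinely uninformative (they retain
initialization noise once the classes separate); coherent negative
cross-axis weights, as described for models trained on real tumors,
require immune–angiogenesis co-expression structure the generator does
not plant.

## Synthetic cohorts

The generator emulates the statistical setting the panel assumes, not
RNA-seq data realism. Each sample has latent immune and angiogenesis
activities; the true subtype is the quadrant of the latent pair. In the
default discrete mode activities are a two-component ±1 mixture, making
quadrant truth unambiguous; continuous mode adds N(0, `latent_sd`)
around the centers for boundary-behavior studies. A gene on an axis is
shifted by `loading_effect × (activity+1)/2` (so a fully active axis
adds the full loading) around a gene baseline ~ N(7, 1) on a log2-like
scale, with N(0, `noise_sd`) residuals; noise genes are baseline plus
residual only. Responses are Bernoulli with subtype-dependent rates;
the default response model is the immune-checkpoint setting (34.4% in
IA/IS vs 4.9% in A/ID, ~7-fold). Defaults — 298 samples, 62 genes per
axis, loading 2, noise SD 1 — mirror the training conditions the panel
was designed for.

Multi-dataset simulation shares the gene model and draws fresh samples
per dataset, adding a per-dataset global location shift (SD 1.0),
per-gene location jitter (SD 0.3), and a global scale factor
(log-normal, SD 0.2). Genes designated *unstable* emulate probes that
fail to transfer between platforms: their apparent baseline saturates
alternately low/high across datasets (baseline ± 2, alternating
deterministically so any two datasets disagree, plus jitter) and their
loading sign flips with the same pattern. This is the ground truth
against which the transferability filter is scored.

What passing tests on these cohorts do **not** show: robustness to
count-level (negative binomial) noise, tumor purity or copy-number
confounding, correlated gene–gene structure beyond the two axes, or
axis–axis correlation. The generator's independence of the two axes is
also why emergent cross-axis weight structure is not expected (above).

## Numerical choices

- Class order (A, IA, ID, IS) is fixed alphabetically everywhere,
  including argmax tie-breaks.
- Softmax is computed with max-subtraction; cross-entropy clamps
  probabilities at 1e-12.
- Model JSON stores parameters at full float precision; save→load→
  predict round-trips to 1e-12.
- Quantile interpolation is linear with clamping at the pooled extremes.
- Missing expression values: token NA/empty; genes over 20% missing are
  dropped with a warning, the rest median-imputed per gene (the
  classifier needs complete vectors).
- The latent distance↔confidence correlation (distance of a sample from
  the latent origin vs its max probability) is demonstrated on a
  continuous-latent cohort (`latent_sd` 1.0) trained with α = 1e-2: in
  a fully separated discrete cohort every sample saturates at the tanh
  corners and the rank correlation drowns in tie noise.

## Problem sizes

Synthetic studies use cohorts of 120–400 samples (10,000 where a
small-probability arm must be estimated, e.g. ORR fold enrichment at a
4.9% negative-arm rate), 124-gene panels, 20 seeds for the alignment
study, and 100,000 Monte-Carlo replicates for the null model. The full
test suite and the acceptance script each run in seconds on one CPU.

## Limitations

- The transferability score and the reference-mapping function are
  package-defined concretizations of published-in-spirit but
  unpublished procedures; they satisfy the documented invariants but
  are not the proprietary originals, and the production 124-gene list
  and trained weights are likewise not reproduced.
- The baseline accuracy closed form can differ in the second decimal
  from some published baseline rows (which appear Monte-Carlo or
  truncated); we report the analytic forms and provide the Monte-Carlo
  mode for comparison.
- Survival/prognostic analysis, GSEA/GSVA activation scoring, and
  upstream microarray/RNA-seq preprocessing are out of scope.
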
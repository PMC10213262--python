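# stromatype

Tumor-microenvironment (TME) subtype classification from bulk gene
expression, with mechanism-of-action biomarker logic and predictive
enrichment evaluation.

## The problem

Response to TME-targeted cancer therapies — anti-angiogenic agents and
immune checkpoint inhibitors — depends on the biological state of the
tumor's stroma more than on any single analyte. Two dominant biologies,
pathological **angiogenesis** and **immune** infiltration/activation,
span a plane whose quadrants define four stromal phenotypes:

| subtype | immune | angiogenesis | character |
|---|---|---|---|
| A (Angiogenic) | low | high | dense pathological vasculature, little immune infiltrate |
| IA (Immune Active) | high | low | activated lymphocytes, M1 macrophages |
| ID (Immune Desert) | low | low | quiescent stroma |
| IS (Immune Suppressed) | high | high | suppressive immune milieu plus A-like vasculature |

`stromatype` classifies expression profiles into these subtypes with a
deliberately shallow neural network — an input layer of panel genes, a
**two-neuron tanh hidden layer**, and a four-class softmax output:

    h_i = tanh(w_i · x + b_i),  i = 1, 2
    p   = softmax(W h + c),     p ∈ Δ³ over (A, IA, ID, IS)

trained by minimizing multi-class cross-entropy with L-BFGS, stopping
when the loss improves by less than 1e-4 for 10 consecutive iterations
(at most 1000). Two hidden neurons force the panel onto a 2-D latent
space that empirically aligns with the immune and angiogenesis axes,
making the model directly interpretable.

Around the classifier the package provides the full workflow:

- **`simulate`** — synthetic cohorts with a two-axis latent structure,
  quadrant-true subtypes, RECIST responses whose rates depend on
  subtype × therapy mechanism, and multi-platform replicates with
  designated non-transferable genes.
- **`transferability`** — a rank-based cross-dataset consistency score
  per gene, used to prune panel genes that do not transfer between
  expression platforms.
- **`normalize`** — a frozen reference distribution (pooled training
  quantiles + per-gene z-statistics); new cohorts are quantile-mapped
  onto it so the trained model never needs recomputation.
- **`labeling`** — the preliminary population-dependent model: per-gene
  z-scores, per-axis mean scores, quadrant → subtype training labels.
- **`biomarker`** — mechanism-of-action rules (anti-angio → A+IS,
  immunotherapy → IA+IS, TLR9 combination → IS); B+ ⇔ combined subtype
  probability ≥ 0.5; signed biomarker score 2·P(B+) − 1.
- **`evaluation`** — confusion metrics, Mann–Whitney AUROC, per-arm ORR
  and fold enrichment, and the prior-probability null classifier
  (analytic closed forms + Monte-Carlo mode).
- **`viz`** — latent-space plots with probability-gradient contours and
  biomarker-score distribution plots.

## Worked example

```python
import stromatype as st

cfg = st.SimConfig(n_samples=300, seed=11)
expr, clinical, truth = st.simulate_cohort(cfg)
model, labels = st.train_from_raw(expr, cfg.panel(), st.TrainConfig(seed=11))
print("training:", model.metadata["stopping_reason"],
      f"after {model.metadata['n_iterations']} iterations")

held = st.SimConfig(n_samples=300, seed=99)
h_expr, h_clin, h_truth = st.simulate_cohort(held)
calls = st.classify_raw(model, h_expr)
print("held-out subtype accuracy:",
      round(float((calls.subtype == h_truth.subtypes).mean()), 3))

bm = st.biomarker_call(calls, st.BiomarkerRule.standard("immune"))
orr_p, orr_n, fold = st.orr_enrichment(bm, h_clin)
print(f"ORR: {orr_p:.1%} in B+ vs {orr_n:.1%} in B-  ({fold:.1f}-fold)")
align = st.neuron_axis_alignment(model, cfg.panel())
print("neuron-axis alignment:", {k: round(v, 2) for k, v in align.alignment.items()})
```

prints

```
training: loss plateau (<0.0001 improvement for 10 iterations) after 24 iterations
held-out subtype accuracy: 1.0
ORR: 33.3% in B+ vs 5.9% in B-  (5.7-fold)
neuron-axis alignment: {'immune': 0.97, 'angiogenesis': 0.98}
```

The cohort was generated with immune-checkpoint-style response rates
(34.4% in the immune-high subtypes IA+IS vs 4.9% elsewhere), so the
recovered ~5.7-fold enrichment on 300 held-out patients shows the
classifier's B+/B− partition retrieving the planted therapy–mechanism
association; the alignment values say each hidden neuron ranks its own
axis's genes above the other axis's in weight almost perfectly.

The same workflow is available as CLI subcommands
(`stromatype simulate | curate | normalize | label | train | classify |
callbm | evaluate | plot`).

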
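# dualscreen

Multitask text models for joint depression and anxiety screening.

Mental-health screening instruments — the PHQ-9 (depression, 0–27
points) and the GAD-7 (anxiety, 0–21 points) — are self-reports, and
adolescents in particular under-report through stigma and somatization.
An alternative is to estimate both scores directly from spontaneous
free-text expression. Because depression and anxiety are strongly
comorbid, `dualscreen` models them *jointly*: a shared transformer trunk
reads the text and four heads predict, for each scale, both a continuous
score y&#770; and a three-level severity class (mild 0–4, moderate 5–9,
severe ≥ 10), trained under the weighted objective

    L = α·L_reg + β·L_cls + γ·‖θ‖²₂,   α = 0.3, β = 6.0, γ = 0.01

with L_reg the summed squared score errors, L_cls a label-smoothed
cross-entropy with inverse-frequency class weights w_c = N/(N_c·C), and
the β ≫ α asymmetry prioritising severity categorisation. Screening is
thresholded at the clinical cutoff (score ≥ 10).

The package is fully self-contained for experimentation: it ships

* a **synthetic corpus generator** (Gaussian-copula correlated scores,
  severity-correlated emotional/somatic vocabulary with expression
  noise, severe-class under-representation),
* the **multitask network** (encoder → extra self-attention →
  dual-feature fusion of pooled [CLS] and mean token states → MLP →
  four heads) on a small numpy autodiff core — no GPU or deep-learning
  framework required,
* a **conditional text VAE** (BiLSTM encoder, GRU decoder conditioned on
  the severity pair, 128-d latent) with four generation-quality filters
  for minority-stratum augmentation,
* the full **training protocol** (AdamW, cosine annealing 1e-5 → 1e-6,
  dropout, stochastic depth, label smoothing, gradient noise, EMA,
  early stopping on validation F1, seed ensembles),
* an **evaluation suite** (regression metrics, screening
  sensitivity/specificity/AUC, severity-stratified analysis) and an
  **ablation harness** with component toggles.

See `docs/methods.md` for the model, assumptions and design decisions.

## Worked example

```python
from dualscreen import (GeneratorConfig, generate_corpus,
                        stratified_split, MultitaskTextModel, TrainConfig)

corpus = generate_corpus(GeneratorConfig.strong_signal(n_records=600, seed=1))
split = stratified_split(corpus, seed=1)          # stratified 8:1:1
model = MultitaskTextModel(split)                  # tiny from-scratch encoder
results = model.fit(TrainConfig.desk_scale(seed=0))
print(results.summary())
```

prints

```
Multitask text screening model
==================================================================
encoder: tiny_random (2 layers, d=32)
parameters: 200,744   tasks: both
epochs run: 7   best epoch: 3
------------------------------------------------------------------
metric                       PHQ-9       GAD-7
mse                         19.201       7.157
rmse                         4.382       2.675
mae                          3.098       2.011
pearson_r                    0.746       0.904
r2                           0.503       0.810
auc                          0.892       0.988
accuracy                     0.833       0.933
f1_positive                  0.643       0.846
==================================================================
```

Training stopped early at epoch 7 (best validation F1 at epoch 3; the
checkpoint returned is the best one). On this strong-signal synthetic
corpus the model recovers the scores well — Pearson r of 0.75/0.90
between predicted and true PHQ-9/GAD-7, screening AUC of 0.89/0.99 at
the ≥ 10 cutoff, and positive-class F1 of 0.64/0.85. Numbers on
synthetic text characterise the pipeline, not clinical performance.

The same pipeline is scriptable from the shell:

```bash
dualscreen generate --n 1275 --rho 0.7 --seed 1 --out corpus.jsonl
dualscreen train --corpus corpus.jsonl --out-dir run/ --seed 1
dualscreen augment --corpus corpus.jsonl --out augmented.jsonl --multiplier 2.0
dualscreen ablate --corpus corpus.jsonl --toggles multitask --seeds 3 --out ablation.csv
```

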
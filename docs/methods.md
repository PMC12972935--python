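# Methods

`dualscreen` implements a multitask text model that jointly predicts two
correlated ordinal clinical scores — PHQ-9 (depression, 0–27) and GAD-7
(anxiety, 0–21) — from short free-text responses, together with the data
machinery around it: corpus handling, a conditional text VAE for
minority-class augmentation, the full training protocol, an evaluation
suite and an ablation harness. This note records the model, its
assumptions, the tunable parameters that matter, and the design choices
made where the design was genuinely open.

## The prediction model

A record's text is tokenized (whitespace or character tokenizer; any
segmenter that inserts spaces, e.g. jieba for Chinese, can feed the
whitespace tokenizer) and truncated to 96 tokens. The network is

1. **Encoder** — token + learned position embeddings into `n_layers`
   post-LN transformer blocks (`h` heads, hidden size `d`, feed-forward
   width `4d`). The default *tiny* configuration (2 layers, 2 heads,
   `d = 32`) trains from scratch in seconds on a CPU; a `pretrained` spec
   mirrors the standard 12-layer/12-head/`d = 768` base configuration for
   use with real pretrained weights (not bundled).
2. **Extra self-attention** — one additional multihead self-attention
   block (residual + layer norm, no feed-forward sublayer) over the final
   hidden states. Count configurable; placement after the encoder was an
   open choice, fixed here because it lets the block specialise on
   pooling-relevant long-range structure without re-entering the encoder
   stack.
3. **Dual-feature fusion** — `f_combined = concat(f_pooled, f_global)`,
   where `f_pooled` is the [CLS] state (the raw state for tiny encoders;
   an encoder-supplied tanh pooler would be used when present) and
   `f_global` the mean of token states over *non-padding* positions.
4. **MLP enhancement** — two affine layers with ReLU at both outputs,
   widths `2d → 512 → 256`, dropout between layers in training mode.
5. **Four heads** — linear score regressions for PHQ-9 and GAD-7
   (unbounded during training; clamped to scale range only for
   reporting) and two 3-way softmax severity classifiers over the bins
   mild 0–4 / moderate 5–9 / severe ≥ 10.

Parameters partition into a shared trunk (encoder, fusion, MLP) and
task-specific heads; the trunk is the vehicle of inductive transfer
between the comorbid tasks.

## Objective

`L = α·L_reg + β·L_cls + γ·L_l2`, defaults `α = 0.3`, `β = 6.0`,
`γ = 0.01`. `L_reg` is the per-sample sum of the two squared score
errors, averaged over the batch. `L_cls` is label-smoothed (s = 0.1),
class-weighted cross-entropy summed over the two severity tasks, with
inverse-frequency weights `w_c = N/(N_c·C)` so that `Σ N_c w_c = N`
exactly; smoothing and class weights compose multiplicatively (the weight
scales every smoothed term of its class). `β ≫ α` deliberately biases the
shared representation toward severity categorisation over exact score
regression. Per-task weights `λ_D`, `λ_A` (default 1) scale each task's
contribution inside both `L_reg` and `L_cls`; setting one to zero yields
the single-task reduction used by the ablation harness.

The explicit L2 term (`λ = 0.01`) is restricted by default to the fusion
MLP and heads, while the optimizer's decoupled weight decay (0.03) covers
everything — both knobs coexist in the protocol and applying both to the
encoder would double-penalise it. Both scopes are configurable.

**Class-weight provenance.** When training on a VAE-augmented corpus, the
class weights are computed from the *raw* (pre-augmentation) training
distribution. Synthetic oversampling already equalises class exposure;
recomputing inverse-frequency weights on the rebalanced set strips the
minority emphasis the original data calls for, and in our experiments
measurably reduced severe-stratum recall.

## Training protocol

AdamW with per-epoch cosine annealing
`lr(t) = lr_min + ½(lr_max − lr_min)(1 + cos(tπ/T))`, dropout in MLP and
attention, stochastic depth over the encoder's residual sub-blocks
(skip probability 0.1, training only), label smoothing 0.1, Gaussian
gradient noise (σ = 1e-5, added after backprop, before the optimizer
step), early stopping on the validation mean screening F1 with
patience 3 (the binary screen thresholds the *regression* output at the
clinical cutoff of 10; the monitored metric is switchable), and a
per-step EMA of all parameters (`θ_EMA ← βθ_EMA + (1−β)θ`). A weighted-
average ensemble over seed-varied members is provided
(`train_ensemble` / `ensemble_predict`); members differ by seed because
no other member-construction rule is canonical.

Two parameter regimes ship as presets:

| preset | epochs | batch | lr_max → lr_min | dropout | EMA β | intended for |
|---|---|---|---|---|---|---|
| default | 35 | 58 | 1e-5 → 1e-6 | 0.5 | 0.999 | fine-tuning a large pretrained encoder |
| `desk_scale()` | 15 | 32 | 2e-3 → 2e-4 | 0.1 | 0.95 | from-scratch tiny encoders |

The default constants are meaningless for a from-scratch 32-dimensional
encoder (nothing learns at lr 1e-5 in 35 epochs); the desk preset keeps
the protocol — schedule shape, regularization bundle, early stopping,
EMA — and re-centres only the optimisation constants. All tests and the
acceptance pipeline use the desk preset. Every random stream (init,
batching, dropout, depth, noise) derives from the single run seed, so
runs are bit-reproducible single-threaded.

## Conditional text VAE

Encoder: bidirectional LSTM over token embeddings; two affine heads give
`μ(x)` and `log σ²(x)` (log-variance clamped to ±8) of a diagonal
Gaussian posterior in a latent space of dimension 128 (reduced in desk
runs). Decoder: GRU whose every step consumes the previous token
embedding, the latent code and an embedding of the condition — the
(PHQ severity, GAD severity) pair on the 3×3 grid. Token emission is
per-position categorical (a Bernoulli likelihood is not well defined
over a vocabulary; the categorical reading is the standard one).

Training objective: ELBO with closed-form diagonal-Gaussian KL, linear
KL annealing from 0 to 1 over the first third of training, and a
**free-bits floor of 1.0 nat per latent dimension** — without it the
posterior collapses on symbolic short-text corpora (posterior means
shrank to σ ≈ 0.03 across inputs) and reconstructions carry no
source-specific content. Training batches are sampled with
inverse-frequency stratum weights so minority strata are reconstructed
as well as majority ones — a prerequisite for conditional minority
generation.

Generation for augmentation draws `z = μ + 0.7·σ·ε` from a *source
record's* posterior and decodes at temperature 0.7. Both constants were
chosen for distributional fidelity: colder sampling produced synthetic
"severe" texts with systematically higher distress-token density than
real severe texts (0.69 vs 0.59), which shifts the severe decision
boundary upward and *hurts* recall on borderline real cases; at 0.7/0.7
the density (0.52) brackets the real value from below.

Candidates pass four filters: (1) semantic similarity to the source
strictly above 0.7 — the default similarity is cosine over synonym-class
stems (production use would plug in a sentence-embedding model);
(2) label consistency under a bag-of-words severity classifier fitted on
the original corpus (pluggable; `"auto"` by default); (3) diversity — a
minimum normalised edit distance (0.05) to the source and previously
accepted samples; (4) a fluency floor (token count and type/token ratio
for symbolic corpora). A filter whose model is absent reports "skipped"
and is excluded. Accepted samples inherit the source's labels, carry
`synthetic: true` and provenance, and are appended — originals are never
modified. New-sample quotas waterfill the smallest occupied strata
toward uniformity; the candidate budget is 12× the quota.

"Class balance" is the normalised entropy `H(p)/log K` of the joint
severity-stratum distribution over the `K` occupied strata (the metric
itself had no printed definition; normalised entropy is the natural
choice on [0, 1]). Leakage rules: the VAE trains on the training split
only; augmented records never enter validation; expanding an evaluation
set is a separate, explicitly labeled operation that warns when used.

## Synthetic corpus generator

The generator is the package's substitute for clinical data and defines
the study conditions of every model-level test. It emulates:

* **Comorbidity** — (PHQ-9, GAD-7) pairs from a Gaussian copula with
  target Pearson correlation (default 0.7), marginals mapped through
  severity-targeted quantile tables; severity proportions default to
  mild 0.45 / moderate 0.35 / severe 0.20 (severe rarest, as in clinical
  screening corpora). With bins fixed at 0–4/5–9/≥10, a severe-rare mix
  caps the achievable mean score near 8 points, so the generator matches
  the imbalance structure rather than any particular reported mean —
  the imbalance is what the method's machinery (weighted CE, minority
  augmentation) actually exercises.
* **Severity-correlated vocabulary with expression noise** — each token
  slot emits an emotional-distress, somatic-complaint or neutral token.
  The emotional family's emission rate follows a *driver* =
  0.7·PHQ + 0.3·GAD (normalised scores) plus Gaussian expression noise
  (σ = 0.12); the somatic family mirrors it with GAD dominant. Text is
  thus a shared, imperfect proxy of both clinical severities — the
  regime in which joint training of correlated tasks genuinely helps.
  With noiseless, task-exclusive vocabulary (our first design) a
  single-task model is information-theoretically at least as good and
  the multitask comparison is vacuous.
* **Sparse distributed signal** — every concept stem surfaces as 5
  interchangeable variant tokens (`sad_0 … sad_4`), so individual tokens
  are rare and the signal is spread over ~250 weak features, as in real
  vocabularies. This makes representation estimation the bottleneck at
  n ≈ 600, which is where shared-trunk transfer shows.
* **`strong_signal()` preset** — concentrated vocabulary (one variant
  per stem), widely separated rates, near-zero expression noise: a
  linear bag-of-words probe reaches > 0.9 mild-vs-severe accuracy,
  guaranteeing learnable signal for end-to-end smoke benchmarks.

What the generator does **not** emulate: grammar, discourse, topic
structure, code-switching, annotator disagreement beyond i.i.d.
expression noise, subject-level longitudinal correlation (an optional
texts-per-subject mode shares scores within a subject but texts are
conditionally independent). Passing tests therefore demonstrate that the
pipeline's machinery behaves as specified under controlled conditions —
not that any particular accuracy transfers to clinical text.

## Splitting conventions

The 8:1:1 split stratifies on the joint 3×3 severity grid (raw 28×22
score pairs would leave singleton strata). Global part sizes follow
train = round(0.8·N), validation = ceil of the remainder's half — the
convention that yields 1,020/128/127 at N = 1,275. Within strata,
allocation uses floors plus largest-remainder assignment under the
global targets, so each part's per-stratum count deviates from exact
proportionality by at most one. Strata with fewer than 3 units go to the
training set with a warning. The split is record-level by default; a
subject-grouped mode keeps all of a subject's texts in one part (which
of the two a given study used is generally unstated; both are
supported).

## Evaluation

Regression: MSE, RMSE, MAE, Pearson r, R²; undefined cases (constant
truths) are flagged, not zeroed. Binary screening at the clinical cutoff
(≥ 10 on both scales): accuracy, precision, recall/sensitivity,
specificity, positive-class F1 and macro F1 from 2×2 matrices in the
orientation [[TN, FP], [FN, TP]] — the orientation under which the
published GAD-7 matrix reproduces its stated sensitivity/specificity.
Reported "macro F1" values in the source tables numerically equal the
positive-class F1 of the printed matrices, so the report emits both and
the headline check uses the positive-class value. AUC is rank-based
(ties ½), fed by the continuous regression output against the
thresholded label. Severity-stratified metrics are one-vs-rest per
stratum from the 3×3 confusion matrix.

The ablation harness retrains variants under identical data and seeds:
removing multitask learning (two single-task models), removing
augmentation (raw training set), or toggling architectural components
(currently the extra attention block), reporting ΔF1/ΔMSE mean ± sd
against the always-zero full-model reference row. A somatization-
specific mechanism is deliberately not invented; the toggle interface is
generic.

## Numerical and engineering choices

The neural components run on a small in-package reverse-mode autodiff
core over float64 numpy arrays (tensor ops, broadcasting-aware
gradients, iterative topological backward pass safe for RNN-depth
graphs). Softmax/log-softmax subtract a detached max; cross-entropy
clips probabilities at 1e-12 with a warning; the VAE log-variance is
clamped straight-through to ±8; layer norm uses ε = 1e-5. Gradient
correctness is tested against central differences, and attention,
multihead attention, the losses, AUC and the confusion metrics are each
tested against independent brute-force oracles (1e-6; 1e-9 for losses).

Problem sizes in tests and the acceptance pipeline are the package's
desk-scale study conditions: corpora of 600–1,275 records, 2-layer
`d = 32` encoders, 15-epoch budgets, VAE latent 8–16 with hidden 16–64,
5 seeds for stochastic comparisons, and a 2,000-record generator-drawn
corpus for precise severe-stratum recall estimates (recall is
conditional on the true stratum, so a small test split measures it in
steps of ~1/8).

## Known limitations

* The tiny encoder is a functional stand-in for a pretrained
  Chinese-language encoder; absolute metric levels on synthetic corpora
  say nothing about clinical performance.
* VAE generation quality at desk scale is modest: similarity-filter
  acceptance rates are ~10–30% and cross strata (e.g. mild PHQ with
  severe GAD) often exhaust their candidate budget.
* The stochastic desk-scale comparisons (multitask benefit, severe-
  recall preservation) are directional means over 5 seeds with
  seed-level noise of similar magnitude to the effects; single-seed
  outcomes vary.
* Scores are treated as exact labels; annotator uncertainty is not
  modelled.
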